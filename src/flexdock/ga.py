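"""Clustering genetic algorithm with Solis-Wets local search.

Each generation the scored population is sorted and its top individuals
(within an energy window of the best) are greedily clustered by ligand
RMSD.  The best member of every cluster is copied into the next generation
(adaptive elitism) and, together with all unclustered individuals, forms
the mating population.  Offspring are produced by crossover (80% of
matings) or direct mutation of the parents, mutated, and quick-minimized;
offspring that beat the best score seen so far get an aggressive
minimization and become the new reference.  When the cluster set is
unchanged for three consecutive generations the whole population is
aggressively minimized; five unchanged generations terminate the run.  A
docking performs many independent runs, pools the per-run best solutions,
clusters those within 1 kcal/mol of the overall best and reports cluster
bests as a ranked solution list.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .conformation import (Genome, Individual, MutationScales, PhenotypeBuilder,
                           RotamerLibrary, crossover, initialize_population,
                           load_default_rotamers, mutate, population_size)
from .forcefield import Scorer, ScoreBreakdown, set_receptor_weight
from .geom import wrap_angle
from .io_formats import LigandTopology, ReceptorModel, AffinityMapSet, TranslationalPointSet

__all__ = [
    "GAConfig", "ClusterSet", "Solution", "DockingResult", "ScoringObjective",
    "cluster_population", "select_parents", "solis_wets", "GeneticAlgorithm",
    "run_docking", "index_rmsd",
]


@dataclass
class GAConfig:
    population_size: int | None = None       # None -> 50 + 10 * L_v heuristic
    p_crossover: float = 0.8
    mutation_rate: float = 0.3
    cluster_energy_window: float = 2.0       # kcal/mol
    cluster_rmsd_cutoff: float = 2.0         # A
    stall_minimize: int = 3                  # generations
    stall_stop: int = 5
    cluster_energy_tol: float = 1e-3         # kcal/mol
    max_generations: int = 200
    max_evaluations: int = 2_500_000
    n_runs: int = 50
    final_energy_window: float = 1.0         # kcal/mol
    seed: int = 0
    quick_steps: int = 30
    aggressive_steps: int = 300
    rho_min_quick: float = 0.1
    rho_min_aggressive: float = 0.01
    expand_after: int = 4
    contract_after: int = 4
    mutation_scales: MutationScales = field(default_factory=MutationScales)

    def __post_init__(self):
        if not 0.0 <= self.p_crossover <= 1.0:
            raise ValueError("crossover probability must lie in [0, 1]")
        if self.stall_minimize >= self.stall_stop:
            raise ValueError("stall-to-minimize must be smaller than stall-to-stop")


def index_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain index-matched RMSD (fast; used for per-generation clustering)."""
    d = np.asarray(coords_a) - np.asarray(coords_b)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


@dataclass
class ClusterSet:
    clusters: list[tuple[Individual, list[Individual]]]   # (seed, members incl. seed)
    unclustered: list[Individual]

    @property
    def seeds(self) -> list[Individual]:
        return [seed for seed, _ in self.clusters]

    def signature(self) -> np.ndarray:
        return np.array([seed.total for seed, _ in self.clusters])


def cluster_population(individuals: list[Individual], energy_window: float,
                       rmsd_cutoff: float, rmsd_fn=None) -> ClusterSet:
    """Greedy energy-ordered clustering of the top of a scored population.

    Only individuals within `energy_window` of the lowest energy are
    clustered; the lowest-energy not-yet-clustered individual seeds each
    cluster and collects everything within `rmsd_cutoff` of it.  Individuals
    outside the window stay unclustered.
    """
    if not individuals:
        return ClusterSet([], [])
    if rmsd_fn is None:
        def rmsd_fn(a, b):
            return index_rmsd(a.phenotype[0], b.phenotype[0])
    ordered = sorted(individuals, key=lambda ind: ind.total)
    best = ordered[0].total
    in_window = [ind for ind in ordered if ind.total <= best + energy_window]
    outside = [ind for ind in ordered if ind.total > best + energy_window]
    clusters: list[tuple[Individual, list[Individual]]] = []
    remaining = list(in_window)
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        rest = []
        for ind in remaining:
            if rmsd_fn(seed, ind) < rmsd_cutoff:
                members.append(ind)
            else:
                rest.append(ind)
        clusters.append((seed, members))
        remaining = rest
    return ClusterSet(clusters, outside)


def rank_select_one(mating: list[Individual], rng: np.random.Generator) -> int:
    """Linear rank selection on ascending energy: the rank-r individual
    (r = 0 best) is drawn with weight N - r."""
    n = len(mating)
    order = np.argsort([ind.total for ind in mating], kind="stable")
    weights = np.arange(n, 0, -1, dtype=float)
    pos = int(rng.choice(n, p=weights / weights.sum()))
    return int(order[pos])


def select_parents(mating: list[Individual], rng: np.random.Generator
                   ) -> tuple[Individual, Individual]:
    """Pick two mating partners by linear rank weighting on ascending energy,
    a scale-free realization of score-proportional mating for energies where
    lower is better.  Parents are distinct whenever the population allows."""
    n = len(mating)
    if n == 0:
        raise ValueError("empty mating population")
    if n == 1:
        return mating[0], mating[0]
    ia = rank_select_one(mating, rng)
    ib = ia
    while ib == ia:
        ib = rank_select_one(mating, rng)
    return mating[ia], mating[ib]


# ---------------------------------------------------------------------------
# Objective and local search

class ScoringObjective:
    """Adapter from genotypes to scores: builds the phenotype, evaluates the
    scorer, caches both on the individual."""

    def __init__(self, scorer: Scorer, builder: PhenotypeBuilder):
        self.scorer = scorer
        self.builder = builder

    @property
    def genome(self) -> Genome:
        return self.builder.genome

    @property
    def evaluations(self) -> int:
        return self.scorer.evaluations

    def evaluate(self, ind: Individual) -> float:
        if ind.score is None:
            lig, fr = self.builder.build(ind)
            ind.score = self.scorer.score(lig, fr)
        return ind.total


def _gene_scales(genome: Genome) -> np.ndarray:
    s = np.empty(genome.n_vars)
    s[genome.translation] = 1.0      # A
    s[genome.quaternion] = 0.2
    s[genome.torsions] = 30.0        # degrees
    for k in range(len(genome.chi_counts)):
        s[genome.chi_block(k)] = 30.0
    return s


def _repair(genome: Genome, g: np.ndarray) -> np.ndarray:
    q = g[genome.quaternion]
    n = np.linalg.norm(q)
    if n > 1e-12:
        g[genome.quaternion] = q / n
    if genome.n_torsions:
        g[genome.torsions] = wrap_angle(g[genome.torsions])
    for k in range(len(genome.chi_counts)):
        sl = genome.chi_block(k)
        g[sl] = wrap_angle(g[sl])
    return g


def solis_wets(ind: Individual, objective: ScoringObjective, rng: np.random.Generator,
               max_steps: int, rho_min: float, expand_after: int = 4,
               contract_after: int = 4, rho0: float = 1.0) -> Individual:
    """Solis-Wets adaptive random local search.

    All genes are perturbed by a Gaussian step of width rho (in gene-scaled
    units); an unsuccessful step is retried mirrored; the width expands
    after `expand_after` consecutive successes and contracts after
    `contract_after` consecutive failures.  The returned individual never
    scores worse than the input.
    """
    genome = objective.genome
    scales = _gene_scales(genome)
    best = ind if ind.score is not None else None
    if best is None:
        objective.evaluate(ind)
        best = ind
    rho = rho0
    successes = failures = 0
    for _ in range(max_steps):
        if rho < rho_min:
            break
        step = rng.normal(size=genome.n_vars) * rho * scales
        cand = Individual(_repair(genome, best.genotype + step))
        objective.evaluate(cand)
        if cand.total < best.total:
            best = cand
            successes += 1
            failures = 0
        else:
            cand = Individual(_repair(genome, best.genotype - step))
            objective.evaluate(cand)
            if cand.total < best.total:
                best = cand
                successes += 1
                failures = 0
            else:
                failures += 1
                successes = 0
        if successes >= expand_after:
            rho *= 2.0
            successes = 0
        elif failures >= contract_after:
            rho *= 0.5
            failures = 0
    return best


# ---------------------------------------------------------------------------
# The GA proper

@dataclass
class GARunResult:
    best: Individual
    generations: int
    evaluations: int
    reason: str
    log: list[dict]


class GeneticAlgorithm:
    def __init__(self, objective: ScoringObjective, config: GAConfig,
                 rotlib: RotamerLibrary | None = None):
        self.objective = objective
        self.config = config
        self.rotlib = rotlib if rotlib is not None else load_default_rotamers()
        self.n_matings = 0
        self.n_crossovers = 0

    def mate(self, parent_a: Individual, parent_b: Individual,
             rng: np.random.Generator) -> tuple[list[Individual], bool]:
        """One mating event: crossover with probability p_crossover (else the
        parents are taken directly), then mutation of both offspring."""
        cfg = self.config
        genome = self.objective.genome
        self.n_matings += 1
        crossed = rng.random() < cfg.p_crossover
        if crossed:
            self.n_crossovers += 1
            ca, cb = crossover(parent_a, parent_b, genome, rng)
        else:
            ca, cb = parent_a.copy(), parent_b.copy()
        ca = mutate(ca, genome, self.rotlib, rng, cfg.mutation_rate, cfg.mutation_scales)
        cb = mutate(cb, genome, self.rotlib, rng, cfg.mutation_rate, cfg.mutation_scales)
        return [ca, cb], crossed

    def _quick(self, ind: Individual, rng) -> Individual:
        cfg = self.config
        return solis_wets(ind, self.objective, rng, cfg.quick_steps, cfg.rho_min_quick,
                          cfg.expand_after, cfg.contract_after)

    def _aggressive(self, ind: Individual, rng) -> Individual:
        cfg = self.config
        return solis_wets(ind, self.objective, rng, cfg.aggressive_steps,
                          cfg.rho_min_aggressive, cfg.expand_after, cfg.contract_after)

    def evolve(self, population: list[Individual], rng: np.random.Generator) -> GARunResult:
        cfg = self.config
        obj = self.objective
        popsize = len(population)
        for ind in population:
            obj.evaluate(ind)
        reference = min(ind.total for ind in population)
        best_ever = min(population, key=lambda i: i.total)
        prev_sig: np.ndarray | None = None
        stall = 0
        log: list[dict] = []
        reason = "max_generations"
        gen = 0

        for gen in range(1, cfg.max_generations + 1):
            cs = cluster_population(population, cfg.cluster_energy_window,
                                    cfg.cluster_rmsd_cutoff)
            sig = cs.signature()
            if prev_sig is not None and len(sig) == len(prev_sig) and \
                    np.all(np.abs(sig - prev_sig) <= cfg.cluster_energy_tol):
                stall += 1
            else:
                stall = 0
            prev_sig = sig

            log.append({"generation": gen, "best": float(best_ever.total),
                        "clusters": len(cs.clusters), "stall": stall,
                        "evaluations": obj.evaluations})

            if stall >= cfg.stall_stop:
                reason = "converged"
                break
            if obj.evaluations >= cfg.max_evaluations:
                reason = "max_evaluations"
                break

            elites = [seed for seed, _ in cs.clusters]
            mating = elites + cs.unclustered
            next_gen: list[Individual] = list(elites)
            offspring: list[Individual] = []
            while len(next_gen) < popsize:
                pa, pb = select_parents(mating, rng)
                kids, _ = self.mate(pa, pb, rng)
                for kid in kids:
                    kid = self._quick(kid, rng)
                    if kid.total < reference:
                        kid = self._aggressive(kid, rng)
                        reference = kid.total
                    offspring.append(kid)
                    if len(next_gen) < popsize:
                        next_gen.append(kid)
                if obj.evaluations >= cfg.max_evaluations:
                    break

            # best two individuals of this mating procedure join the next
            # generation unless an identical genotype is already present
            for cand in sorted(offspring, key=lambda i: i.total)[:2]:
                present = any(np.allclose(cand.genotype, o.genotype, atol=1e-6)
                              for o in next_gen)
                if not present:
                    worst = max(range(len(next_gen)), key=lambda k: next_gen[k].total)
                    if next_gen[worst].total > cand.total:
                        next_gen[worst] = cand

            if stall == cfg.stall_minimize:
                next_gen = [self._aggressive(ind, rng) for ind in next_gen]

            population = next_gen
            gen_best = min(population, key=lambda i: i.total)
            if gen_best.total < best_ever.total:
                best_ever = gen_best
            if obj.evaluations >= cfg.max_evaluations:
                reason = "max_evaluations"
                break

        return GARunResult(best_ever, gen, obj.evaluations, reason, log)


# ---------------------------------------------------------------------------
# Multi-run docking

@dataclass
class Solution:
    individual: Individual
    score: ScoreBreakdown
    phenotype: tuple[np.ndarray, np.ndarray | None]
    cluster_size: int
    run_index: int
    evaluations: int


@dataclass
class DockingResult:
    solutions: list[Solution]
    runs: list[dict]
    config: GAConfig
    w_rec: float
    seed: int
    wall_time: float = 0.0

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["mutation_scales"] = asdict(self.config.mutation_scales)
        return {
            "seed": self.seed,
            "w_rec": self.w_rec,
            "config": cfg,
            "runs": self.runs,
            "solutions": [
                {"rank": r + 1,
                 "total": round(s.score.total, 6),
                 "terms": {"e_ll": round(s.score.e_ll, 6),
                           "e_lrr": round(s.score.e_lrr, 6),
                           "e_lfr": round(s.score.e_lfr, 6),
                           "e_frfr": round(s.score.e_frfr, 6),
                           "e_frrr": round(s.score.e_frrr, 6)},
                 "cluster_size": s.cluster_size,
                 "run": s.run_index,
                 "genotype": [round(v, 9) for v in s.individual.genotype.tolist()]}
                for r, s in enumerate(self.solutions)],
            "wall_time": self.wall_time,
        }


def run_docking(ligand: LigandTopology, receptor: ReceptorModel,
                mapset: AffinityMapSet, tpoints: TranslationalPointSet,
                config: GAConfig, params=None, w_rec: float | None = None,
                rotlib: RotamerLibrary | None = None,
                rmsd_final=None) -> DockingResult:
    """Full docking: independent GA runs (seeds = base seed + run index),
    pooling of per-run bests, final clustering within the report window, and
    a ranked solution list."""
    t0 = time.perf_counter()
    builder = PhenotypeBuilder(ligand, receptor)
    genome = builder.genome
    popsize = config.population_size or population_size(genome.n_torsions)
    weight = set_receptor_weight(receptor.n_flexible, w_rec)

    bests: list[tuple[Individual, int, int]] = []
    runs: list[dict] = []
    for r in range(config.n_runs):
        run_seed = config.seed + r
        rng = np.random.default_rng(run_seed)
        scorer = Scorer(ligand, receptor, mapset, params=params, w_rec=weight)
        objective = ScoringObjective(scorer, builder)
        ga = GeneticAlgorithm(objective, config, rotlib)
        try:
            pop = initialize_population(builder, tpoints, popsize, rng)
            res = ga.evolve(pop, rng)
        except Exception as exc:   # a failed run is recorded, not fatal
            runs.append({"run": r, "seed": run_seed, "error": repr(exc)})
            continue
        runs.append({"run": r, "seed": run_seed, "best": round(res.best.total, 6),
                     "generations": res.generations, "evaluations": res.evaluations,
                     "reason": res.reason})
        bests.append((res.best, r, res.evaluations))

    if not bests:
        raise RuntimeError("all GA runs failed")

    lig_types = ligand.ad_types
    if rmsd_final is None:
        from .analysis import hungarian_rmsd

        def rmsd_final(a: Individual, b: Individual) -> float:
            return hungarian_rmsd(a.phenotype[0], lig_types, b.phenotype[0], lig_types)

    pool = [b for b, _, _ in bests]
    origin = {id(b): (run, ev) for b, run, ev in bests}
    cs = cluster_population(pool, config.final_energy_window,
                            config.cluster_rmsd_cutoff, rmsd_fn=rmsd_final)
    solutions = []
    for seed, members in cs.clusters:
        run, ev = origin[id(seed)]
        solutions.append(Solution(seed, seed.score, seed.phenotype,
                                  len(members), run, ev))
    solutions.sort(key=lambda s: s.score.total)
    return DockingResult(solutions, runs, config, weight, config.seed,
                         time.perf_counter() - t0)
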