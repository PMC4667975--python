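"""Genome definition, gene operators and phenotype construction.

A docking solution is a genotype: ligand translation (3), rigid rotation
(unit quaternion, 4), one torsion per rotatable ligand bond, then one chi
block per flexible receptor side chain.  The phenotype is the Cartesian
coordinates this genotype produces for the ligand and the movable receptor
atoms.  All angles are degrees in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .geom import (dihedral, quaternion_matrix, random_unit_quaternion,
                   rotate_about_axis, wrap_angle)
from .io_formats import LigandTopology, ReceptorModel, TranslationalPointSet

__all__ = [
    "Genome", "Individual", "RotamerLibrary", "MutationScales",
    "population_size", "PhenotypeBuilder", "initialize_population",
    "mutate", "crossover", "randomize_ligand_pose", "load_default_rotamers",
]


def population_size(n_lrb: int) -> int:
    """GA population heuristic 50 + 10 * L_v with L_v = 7 + N_LRB."""
    if n_lrb < 0:
        raise ValueError("number of rotatable bonds must be non-negative")
    return 50 + 10 * (7 + n_lrb)


@dataclass(frozen=True)
class Genome:
    """Structure of the variable vector; values live in Individual.genotype."""
    n_torsions: int
    chi_counts: tuple[int, ...] = ()
    chi_residues: tuple[str, ...] = ()      # residue type per chi block

    def __post_init__(self):
        if len(self.chi_counts) != len(self.chi_residues):
            raise ValueError("chi_counts and chi_residues must align")

    @property
    def n_vars(self) -> int:
        return 7 + self.n_torsions + sum(self.chi_counts)

    @property
    def l_v(self) -> int:
        """Ligand variable count used by the population heuristic."""
        return 7 + self.n_torsions

    @property
    def translation(self) -> slice:
        return slice(0, 3)

    @property
    def quaternion(self) -> slice:
        return slice(3, 7)

    @property
    def torsions(self) -> slice:
        return slice(7, 7 + self.n_torsions)

    def chi_block(self, k: int) -> slice:
        start = 7 + self.n_torsions + sum(self.chi_counts[:k])
        return slice(start, start + self.chi_counts[k])

    def genes(self) -> list[tuple[str, slice]]:
        """Gene descriptors in fixed order: translation, rotation, each
        torsion, each chi block (swapped atomically in crossover)."""
        out = [("translation", self.translation), ("rotation", self.quaternion)]
        out += [("torsion", slice(7 + t, 8 + t)) for t in range(self.n_torsions)]
        out += [(f"chi:{self.chi_residues[k]}", self.chi_block(k))
                for k in range(len(self.chi_counts))]
        return out


@dataclass
class Individual:
    genotype: np.ndarray
    score: "ScoreBreakdown | None" = None            # noqa: F821
    phenotype: tuple[np.ndarray, np.ndarray | None] | None = None

    def __post_init__(self):
        self.genotype = np.asarray(self.genotype, dtype=float)

    def copy(self) -> "Individual":
        return Individual(self.genotype.copy())

    @property
    def total(self) -> float:
        if self.score is None:
            raise ValueError("individual not yet scored")
        return self.score.total


@dataclass
class RotamerLibrary:
    """Per residue type: modal chi combinations, their spreads and priors."""
    rows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # priors, means, sds

    def __post_init__(self):
        for res, (priors, means, sds) in self.rows.items():
            if len(priors) == 0:
                raise ValueError(f"residue {res} has no rotamer rows")
            s = float(np.sum(priors))
            if not np.isclose(s, 1.0, atol=1e-6):
                self.rows[res] = (np.asarray(priors) / s, means, sds)

    def sample(self, resname: str, rng: np.random.Generator,
               n_chi: int | None = None) -> np.ndarray:
        """Draw a soft rotamer: a library row by prior probability, each chi
        perturbed by a Gaussian with that row's standard deviation."""
        priors, means, sds = self.rows[resname]
        k = rng.choice(len(priors), p=priors)
        chi = means[k] + rng.normal(size=means.shape[1]) * sds[k]
        if n_chi is not None:
            chi = chi[:n_chi]
        return wrap_angle(chi)

    def pick_row(self, resname: str, rng: np.random.Generator) -> int:
        priors, _, _ = self.rows[resname]
        return int(rng.choice(len(priors), p=priors))


def load_default_rotamers() -> RotamerLibrary:
    text = resources.files("flexdock").joinpath("data/rotamers.dat").read_text()
    acc: dict[str, list[tuple[float, list[float], list[float]]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        res, prior = parts[0], float(parts[1])
        vals = [float(v) for v in parts[2:]]
        means, sds = vals[0::2], vals[1::2]
        acc.setdefault(res, []).append((prior, means, sds))
    rows = {}
    for res, entries in acc.items():
        priors = np.array([e[0] for e in entries])
        means = np.array([e[1] for e in entries])
        sds = np.array([e[2] for e in entries])
        rows[res] = (priors, means, sds)
    return RotamerLibrary(rows)


# ---------------------------------------------------------------------------
# Phenotype

class PhenotypeBuilder:
    """Deterministic genotype -> coordinates mapping.

    Ligand: input coordinates, torsion-tree rotations applied from the root
    outward (each rotation moves exactly the branch's moved-set), then the
    rigid rotation about the root atom and translation placing the root atom
    at the translation gene.  Receptor: per flexible residue, chi rotations
    applied chi1..chiN about the current axis positions.
    """

    def __init__(self, ligand: LigandTopology, receptor: ReceptorModel | None = None):
        self.ligand = ligand
        self.receptor = receptor
        self.input_coords = ligand.coords
        self.root = ligand.root_atom
        self.quads = ligand.torsion_quadruples()
        self.moved_sets = [np.array(sorted(b.moved), dtype=int) for b in ligand.branches]
        flex = receptor.flexible_residues if receptor is not None else []
        self.genome = Genome(
            n_torsions=ligand.n_rotatable_bonds,
            chi_counts=tuple(fr.n_chi for fr in flex),
            chi_residues=tuple(fr.residue_name for fr in flex),
        )
        if receptor is not None:
            self._rec_coords = np.array([a.position for a in receptor.atoms])
            self._movable_global = receptor.movable_indices

    def initial_genotype(self) -> np.ndarray:
        """Identity genotype: input pose, input torsions and chi angles."""
        g = np.zeros(self.genome.n_vars)
        g[self.genome.translation] = self.input_coords[self.root]
        g[self.genome.quaternion] = (0.0, 0.0, 0.0, 1.0)   # identity (x,y,z,w)
        coords = self.input_coords
        for t, q in enumerate(self.quads):
            g[7 + t] = dihedral(*coords[list(q)])
        off = 7 + self.genome.n_torsions
        if self.receptor is not None:
            for fr in self.receptor.flexible_residues:
                g[off:off + fr.n_chi] = fr.chi0
                off += fr.n_chi
        return g

    def ligand_coords(self, genotype: np.ndarray) -> np.ndarray:
        coords = self.input_coords.copy()
        gen = self.genome
        for t, (quad, moved) in enumerate(zip(self.quads, self.moved_sets)):
            target = genotype[7 + t]
            current = dihedral(*coords[list(quad)])
            delta = target - current
            if abs(wrap_angle(delta)) > 1e-12:
                # right-handed rotation about atom2->atom3 advances the
                # dihedral by the same angle
                coords[moved] = rotate_about_axis(coords[moved], coords[quad[1]],
                                                  coords[quad[2]], wrap_angle(delta))
        q = np.asarray(genotype[gen.quaternion], dtype=float)
        norm = np.sqrt(np.dot(q, q))
        if norm < 1e-12:
            raise ValueError("degenerate quaternion")
        R = quaternion_matrix(q / norm)
        coords = (coords - coords[self.root]) @ R.T
        return coords + genotype[gen.translation]

    def receptor_coords(self, genotype: np.ndarray) -> np.ndarray | None:
        """Coordinates of the movable receptor atoms, in receptor order."""
        if self.receptor is None or not self.receptor.n_flexible:
            return None
        coords = self._rec_coords.copy()
        for k, fr in enumerate(self.receptor.flexible_residues):
            block = genotype[self.genome.chi_block(k)]
            for c, (quad, moved) in enumerate(zip(fr.chi_quads, fr.chi_moved)):
                current = dihedral(*coords[list(quad)])
                delta = wrap_angle(block[c] - current)
                if abs(delta) > 1e-12:
                    idx = np.array(sorted(moved), dtype=int)
                    coords[idx] = rotate_about_axis(coords[idx], coords[quad[1]],
                                                    coords[quad[2]], delta)
        return coords[self._movable_global]

    def build(self, individual: Individual) -> tuple[np.ndarray, np.ndarray | None]:
        lig = self.ligand_coords(individual.genotype)
        fr = self.receptor_coords(individual.genotype)
        individual.phenotype = (lig, fr)
        return lig, fr

    def measure_internal(self, lig_coords: np.ndarray,
                         fr_coords: np.ndarray | None = None) -> dict:
        """Measure genome-visible internal coordinates from a phenotype:
        root position, ligand torsions and chi angles (for round-trip checks)."""
        out = {"translation": lig_coords[self.root].copy(),
               "torsions": np.array([dihedral(*lig_coords[list(q)]) for q in self.quads])}
        chis = []
        if self.receptor is not None and fr_coords is not None:
            coords = self._rec_coords.copy()
            coords[self._movable_global] = fr_coords
            for fr in self.receptor.flexible_residues:
                chis.append(np.array([dihedral(*coords[list(q)]) for q in fr.chi_quads]))
        out["chis"] = chis
        return out


# ---------------------------------------------------------------------------
# Gene operators

@dataclass(frozen=True)
class MutationScales:
    """Gaussian mutation step sizes (distribution shapes are fixed; scales
    are tunable defaults)."""
    translation_sigma: float = 0.5   # A per axis
    rotation_sigma: float = 10.0     # degrees, small random rotation
    torsion_sigma: float = 30.0      # degrees


def initialize_population(builder: PhenotypeBuilder, tpoints: TranslationalPointSet,
                          size: int, rng: np.random.Generator) -> list[Individual]:
    """Initial population: translations drawn uniformly from translational
    points, uniform random rotations, uniform random torsions, and chi genes
    set to the input-structure angles for every individual (flexible side
    chains start from the input receptor conformation)."""
    if size < 2:
        raise ValueError("population size must be >= 2")
    if len(tpoints) == 0:
        raise ValueError("translational point set is empty")
    gen = builder.genome
    base = builder.initial_genotype()
    pop = []
    for _ in range(size):
        g = base.copy()
        g[gen.translation] = tpoints.points[rng.integers(len(tpoints))]
        g[gen.quaternion] = random_unit_quaternion(rng)
        if gen.n_torsions:
            g[gen.torsions] = wrap_angle(rng.uniform(-180.0, 180.0, size=gen.n_torsions))
        pop.append(Individual(g))
    return pop


def mutate(ind: Individual, genome: Genome, rotlib: RotamerLibrary | None,
           rng: np.random.Generator, rate: float = 0.3,
           scales: MutationScales = MutationScales()) -> Individual:
    """Per-gene mutation: Gaussian moves for translation/rotation/torsions,
    soft-rotamer replacement for chi blocks; unmutated genes unchanged."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    child = ind.copy()
    g = child.genotype
    for name, sl in genome.genes():
        if rng.random() >= rate:
            continue
        if name == "translation":
            g[sl] += rng.normal(size=3) * scales.translation_sigma
        elif name == "rotation":
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.radians(rng.normal() * scales.rotation_sigma)
            dq = Rotation.from_rotvec(angle * axis)
            q = Rotation.from_quat(g[sl] / np.linalg.norm(g[sl]))
            g[sl] = (dq * q).as_quat()
        elif name == "torsion":
            g[sl] = wrap_angle(g[sl] + rng.normal() * scales.torsion_sigma)
        else:                          # chi block: soft rotamer
            resname = name.split(":", 1)[1]
            n_chi = sl.stop - sl.start
            if rotlib is not None and resname in rotlib.rows:
                g[sl] = rotlib.sample(resname, rng, n_chi=n_chi)
            else:
                g[sl] = wrap_angle(g[sl] + rng.normal(size=n_chi) * scales.torsion_sigma)
    return child


def crossover(parent_a: Individual, parent_b: Individual, genome: Genome,
              rng: np.random.Generator) -> tuple[Individual, Individual]:
    """Gene-level uniform crossover: each gene swapped with probability 1/2;
    chi blocks swap atomically per residue."""
    ca, cb = parent_a.copy(), parent_b.copy()
    for _, sl in genome.genes():
        if rng.random() < 0.5:
            tmp = ca.genotype[sl].copy()
            ca.genotype[sl] = cb.genotype[sl]
            cb.genotype[sl] = tmp
    return ca, cb


def randomize_ligand_pose(ind: Individual, genome: Genome, center, half_extent: float,
                          rng: np.random.Generator) -> Individual:
    """Randomize position (uniform in the box), orientation (Haar-uniform)
    and torsions; chi genes untouched."""
    child = ind.copy()
    g = child.genotype
    c = np.asarray(center, dtype=float)
    g[genome.translation] = c + rng.uniform(-half_extent, half_extent, size=3)
    g[genome.quaternion] = random_unit_quaternion(rng)
    if genome.n_torsions:
        g[genome.torsions] = wrap_angle(rng.uniform(-180.0, 180.0, size=genome.n_torsions))
    return child
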