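"""Fully synthetic receptor/ligand systems with enumerable optima.

These fixtures stand in for crystallographic complexes: a spherical shell
of carbon pseudo-atoms forms an open pocket (or a sealed cavity), real
serine side-chain geometry provides flexible residues, and ligands are one
to four atoms so the genotype space can be enumerated exhaustively.  The
brute-force oracle scores candidate genotypes through the same scorer the
genetic algorithm uses -- it only adds enumeration control, never a second
energy implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import circular_difference
from .conformation import Individual, PhenotypeBuilder
from .forcefield import Scorer, ScoreBreakdown
from .geom import place_atom
from .grids import (InteriorMask, build_interior_mask, compute_maps,
                    extract_translational_points, postprocess_map)
from .io_formats import (AffinityMapSet, Atom, Branch, LigandTopology,
                         ReceptorModel, TranslationalPointSet, make_receptor_model)
from .params import FFParameters, default_parameters

__all__ = [
    "SyntheticSystem", "BruteForceResult", "make_pocket_system",
    "brute_force_dock", "make_map_fixture", "make_single_atom_ligand",
    "make_butane_ligand", "make_serine", "downweight_poses",
]

_TEMPLATES = ("open-pocket", "buried-cavity", "apo-clash", "two-flex")


# ---------------------------------------------------------------------------
# Building blocks

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


def _shell_atoms(radius: float, n: int, zcap: float | None,
                 rng: np.random.Generator, serial0: int = 1) -> list[Atom]:
    pts = _fibonacci_sphere(n, radius)
    pts = pts + rng.normal(scale=0.03, size=pts.shape)
    atoms = []
    k = 0
    for p in pts:
        if zcap is not None and p[2] > zcap:
            continue
        charge = 0.05 if k % 2 == 0 else -0.05
        atoms.append(Atom(serial0 + k, "C", "SHL", 500, "Z", "C", p, charge))
        k += 1
    return atoms


def make_single_atom_ligand(ad_type: str = "C", charge: float = 0.1,
                            position=(0.0, 0.0, 0.0)) -> LigandTopology:
    atom = Atom(1, "C1", "LIG", 1, "L", ad_type, np.asarray(position, dtype=float), charge)
    return LigandTopology([atom], root_atom=0, branches=[], torsdof=0)


def make_butane_ligand() -> LigandTopology:
    """Four-carbon chain with the central bond rotatable."""
    coords = np.array([
        [0.000, 0.000, 0.000],
        [1.526, 0.000, 0.000],
        [2.078, 1.423, 0.000],
        [3.604, 1.423, 0.060],
    ])
    atoms = [Atom(i + 1, f"C{i+1}", "LIG", 1, "L", "C", coords[i], 0.0) for i in range(4)]
    branches = [Branch(parent=1, child=2, moved=frozenset({2, 3}))]
    return LigandTopology(atoms, root_atom=0, branches=branches, torsdof=1)


# idealized serine internal coordinates (bond lengths A, angles deg)
_SER_CHARGES = {"N": -0.35, "CA": 0.18, "C": 0.24, "O": -0.27,
                "CB": 0.20, "OG": -0.39, "HG": 0.21}
_SER_TYPES = {"N": "N", "CA": "C", "C": "C", "O": "OA",
              "CB": "C", "OG": "OA", "HG": "HD"}


def make_serine(cb_pos, out_dir, chi1: float, resnum: int = 1, chain: str = "A",
                serial0: int = 100, ref_dir=(1.0, 0.0, 0.0)) -> list[Atom]:
    """Build an idealized SER residue with CB at `cb_pos`, the CB->CA bond
    along `out_dir`, and chi1 (N-CA-CB-OG) set to `chi1` degrees."""
    cb = np.asarray(cb_pos, dtype=float)
    u = np.asarray(out_dir, dtype=float)
    u = u / np.linalg.norm(u)
    ca = cb + 1.53 * u
    virtual = cb + np.asarray(ref_dir, dtype=float)
    n = place_atom(virtual, cb, ca, 1.45, 110.0, 60.0)
    c = place_atom(cb, n, ca, 1.52, 111.0, -120.0)
    o = place_atom(n, ca, c, 1.23, 120.5, 0.0)
    og = place_atom(n, ca, cb, 1.41, 110.5, chi1)
    hg = place_atom(ca, cb, og, 0.96, 110.0, 180.0)
    positions = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "OG": og, "HG": hg}
    return [Atom(serial0 + i, name, "SER", resnum, chain, _SER_TYPES[name],
                 positions[name], _SER_CHARGES[name])
            for i, name in enumerate(["N", "CA", "C", "O", "CB", "OG", "HG"])]


# ---------------------------------------------------------------------------
# Systems

@dataclass
class SyntheticSystem:
    name: str
    seed: int
    ligand: LigandTopology
    receptor: ReceptorModel
    center: np.ndarray
    npts: int
    spacing: float
    params: FFParameters
    maps: AffinityMapSet | None = None
    mask: InteriorMask | None = None
    tpoints: TranslationalPointSet | None = None
    optimum: "BruteForceResult | None" = None
    meta: dict = field(default_factory=dict)

    @property
    def probe_types(self) -> list[str]:
        types = set(self.ligand.ad_types)
        types.update(a.ad_type for a in self.receptor.movable_atoms)
        return sorted(types)

    def build_grids(self, cutoff: float = -0.3, stride: int = 3) -> None:
        raw = compute_maps(self.receptor.rigid_atoms, self.center, self.npts,
                           self.spacing, self.probe_types, self.params)
        self.mask = build_interior_mask(self.receptor.rigid_atoms, self.center,
                                        self.npts, self.spacing, self.params)
        self.maps = postprocess_map(raw, self.mask)
        self.tpoints = extract_translational_points(self.maps, self.mask,
                                                    cutoff=cutoff, stride=stride)

    def scorer(self, w_rec: float | None = None) -> Scorer:
        return Scorer(self.ligand, self.receptor, self.maps, params=self.params,
                      w_rec=w_rec)


@dataclass
class BruteForceResult:
    genotype: np.ndarray
    score: ScoreBreakdown
    n_evaluated: int
    table: list[tuple[np.ndarray, float]] | None = None

    @property
    def total(self) -> float:
        return self.score.total


def brute_force_dock(system: SyntheticSystem, chi_step: float = 10.0,
                     torsion_step: float = 30.0, w_rec: float | None = None,
                     keep_table: bool = False, max_genotypes: int = 1_000_000
                     ) -> BruteForceResult:
    """Exhaustive minimization over a discretized genome: translations over
    the system's translational points, torsions and chi angles on regular
    grids, orientation at the identity (exact for point ligands).  Scores
    go through the same Scorer as the GA."""
    if system.maps is None or system.tpoints is None:
        raise ValueError("system grids not built")
    builder = PhenotypeBuilder(system.ligand, system.receptor)
    genome = builder.genome
    base = builder.initial_genotype()
    angle_grid = lambda step: np.arange(-180.0 + step, 180.0 + 1e-9, step)  # noqa: E731

    torsion_axes = [angle_grid(torsion_step) for _ in range(genome.n_torsions)]
    chi_axes = []
    for k, count in enumerate(genome.chi_counts):
        chi_axes.extend(angle_grid(chi_step) for _ in range(count))
    n_total = len(system.tpoints)
    for ax in torsion_axes + chi_axes:
        n_total *= len(ax)
    if n_total > max_genotypes:
        raise ValueError(f"enumeration grid too large: {n_total} genotypes")

    scorer = system.scorer(w_rec=w_rec)
    best_g, best_s = None, None
    table = [] if keep_table else None
    angle_axes = torsion_axes + chi_axes
    combos = [np.array([])] if not angle_axes else \
        np.stack(np.meshgrid(*angle_axes, indexing="ij"), axis=-1).reshape(-1, len(angle_axes))
    for point in system.tpoints.points:
        for combo in combos:
            g = base.copy()
            g[genome.translation] = point
            if len(combo):
                g[7:7 + len(combo)] = combo
            ind = Individual(g)
            lig, fr = builder.build(ind)
            s = scorer.score(lig, fr)
            if best_s is None or s.total < best_s.total:
                best_g, best_s = g.copy(), s
            if keep_table:
                table.append((g.copy(), s.total))
    return BruteForceResult(best_g, best_s, scorer.evaluations, table)


def make_pocket_system(template: str, seed: int = 0, radius: float = 4.0,
                       n_shell: int = 110, zcap: float = 2.0, npts: int = 19,
                       spacing: float = 0.5, ligand: str = "atom",
                       build: bool = True, chi_step: float = 10.0) -> SyntheticSystem:
    """Construct one of the synthetic pocket templates.

    open-pocket    rigid shell with an opening; single-atom ligand.
    buried-cavity  sealed shell enclosing a cavity (mask/map tests).
    apo-clash      open pocket plus a flexible SER whose input chi1 blocks
                   the best site; the side chain must rotate >= 60 degrees
                   to admit the ligand.
    two-flex       apo-clash plus a second (non-blocking) flexible SER.
    """
    if template not in _TEMPLATES:
        raise ValueError(f"unknown template {template!r}")
    rng = np.random.default_rng(seed)
    params = default_parameters()

    lig = make_single_atom_ligand() if ligand == "atom" else make_butane_ligand()
    span = float(np.max(np.linalg.norm(lig.coords - lig.coords.mean(axis=0), axis=1)))
    if 2.0 * span > 1.6 * radius:
        raise ValueError("ligand larger than pocket")

    cap = None if template == "buried-cavity" else zcap
    atoms = _shell_atoms(radius, n_shell, cap, rng)
    flexible_ids: list[str] = []

    # flexible SER anchors: CB on a radial rim direction, CB->CA axis tilted
    # sideways so that rotating chi1 actually sweeps OG toward/away from the
    # pocket centre (an untilted axis would pass through the centre and make
    # the OG-centre distance chi-invariant)
    def _tilted(d, toward):
        perp = np.asarray(toward, dtype=float) - np.dot(toward, d) * d
        perp /= np.linalg.norm(perp)
        u = d + 1.2 * perp
        return u / np.linalg.norm(u)

    if template in ("apo-clash", "two-flex"):
        d0 = np.array([0.0, 0.55, 0.84])
        d0 /= np.linalg.norm(d0)
        ser1 = make_serine(3.1 * d0, _tilted(d0, (0.0, 1.0, 0.0)), chi1=60.0,
                           resnum=1, chain="A", serial0=len(atoms) + 1)
        atoms += ser1
        flexible_ids.append("A:SER1")
    if template == "two-flex":
        d1 = np.array([0.0, -0.55, 0.84])
        d1 /= np.linalg.norm(d1)
        ser2 = make_serine(3.1 * d1, _tilted(d1, (0.0, -1.0, 0.0)), chi1=60.0,
                           resnum=2, chain="A", serial0=len(atoms) + 1,
                           ref_dir=(-1.0, 0.0, 0.0))
        atoms += ser2
        flexible_ids.append("A:SER2")

    receptor = make_receptor_model(atoms, flexible_ids)
    system = SyntheticSystem(template, seed, lig, receptor,
                             np.zeros(3), npts, spacing, params)
    if not build:
        return system
    system.build_grids()

    if template == "buried-cavity":
        return system

    if template in ("apo-clash", "two-flex"):
        _configure_blocking_serine(system, chi_step)
    system.optimum = brute_force_dock(system, chi_step=chi_step)
    system.meta["optimum_total"] = system.optimum.total

    if template in ("apo-clash", "two-flex"):
        _verify_apo_clash(system, chi_step)
    return system


def _serine_og_position(system: SyntheticSystem, res_index: int, chi: float) -> np.ndarray:
    builder = PhenotypeBuilder(system.ligand, system.receptor)
    g = builder.initial_genotype()
    g[builder.genome.chi_block(res_index)] = chi
    fr = builder.receptor_coords(g)
    fr_names = [system.receptor.atoms[i].name for i in system.receptor.movable_indices]
    # movable atoms are concatenated per residue in receptor order
    offset = sum(len(system.receptor.flexible_residues[k].movable)
                 for k in range(res_index))
    names = fr_names[offset:offset + len(system.receptor.flexible_residues[res_index].movable)]
    return fr[offset + names.index("OG")]


def _configure_blocking_serine(system: SyntheticSystem, chi_step: float) -> None:
    """Rotate the first SER so its input chi1 places OG over the most
    favourable translational point (the apo conformation blocks the site)."""
    c_map_vals = system.tpoints.affinities
    site = system.tpoints.points[int(np.argmin(c_map_vals))]
    grid = np.arange(-180.0, 180.0, 2.0)
    dists = [np.linalg.norm(_serine_og_position(system, 0, chi) - site) for chi in grid]
    chi_block = float(grid[int(np.argmin(dists))])
    # rebuild the receptor with the blocking chi as the input conformation
    fr = system.receptor.flexible_residues[0]
    builder = PhenotypeBuilder(system.ligand, system.receptor)
    g = builder.initial_genotype()
    g[builder.genome.chi_block(0)] = chi_block
    fr_coords = builder.receptor_coords(g)
    for pos, gi in zip(fr_coords, system.receptor.movable_indices):
        system.receptor.atoms[gi].position = pos
    flexible_ids = [f"{f.chain}:{f.residue_name}{f.residue_number}"
                    for f in system.receptor.flexible_residues]
    system.receptor = make_receptor_model(system.receptor.atoms, flexible_ids)
    system.meta["blocking_chi1"] = chi_block
    system.meta["blocked_site"] = site


def _verify_apo_clash(system: SyntheticSystem, chi_step: float) -> None:
    """Construction invariants: the flexible optimum needs a >= 60 degree
    chi1 change, and the rigid variant cannot reach the flexible optimum."""
    builder = PhenotypeBuilder(system.ligand, system.receptor)
    chi_opt = system.optimum.genotype[builder.genome.chi_block(0)][0]
    chi_in = system.receptor.flexible_residues[0].chi0[0]
    if circular_difference(chi_opt, chi_in) < 60.0:
        raise ValueError("apo-clash construction failed: optimum needs no rotation")
    rigid = rigid_variant(system)
    gap = rigid.optimum.total - system.optimum.total
    system.meta["rigid_optimum_total"] = rigid.optimum.total
    system.meta["gap"] = gap
    if gap < 0.5:
        raise ValueError(f"apo-clash construction failed: gap {gap:.2f} too small")


def rigid_variant(system: SyntheticSystem) -> SyntheticSystem:
    """The same system with every side chain frozen in its input
    conformation (all atoms rigid, included in the maps)."""
    receptor = make_receptor_model([a.copy() for a in system.receptor.atoms], [])
    rigid = SyntheticSystem(system.name + "-rigid", system.seed, system.ligand,
                            receptor, system.center.copy(), system.npts,
                            system.spacing, system.params)
    rigid.build_grids()
    rigid.optimum = brute_force_dock(rigid)
    return rigid


# ---------------------------------------------------------------------------
# Map fixtures

def make_map_fixture(shape: str, npts: int = 9, seed: int = 0,
                     spacing: float = 0.6) -> tuple[AffinityMapSet, InteriorMask]:
    """Analytic or constructed map fixtures with known interior/exterior
    classification: uniform, single-well, hollow-shell, pocket."""
    center = np.zeros(3)
    if shape == "uniform":
        grid = np.full((npts,) * 3, -1.0)
        mapset = AffinityMapSet(center, spacing, npts, {"C": grid},
                                np.zeros((npts,) * 3), np.zeros((npts,) * 3))
        mask = InteriorMask(np.zeros((npts,) * 3, dtype=bool),
                            np.zeros((npts,) * 3, dtype=int))
        return mapset, mask
    if shape == "single-well":
        ax = center[0] - 0.5 * (npts - 1) * spacing + spacing * np.arange(npts)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = -3.0 * np.exp(-(X**2 + Y**2 + Z**2) / 2.0)
        mapset = AffinityMapSet(center, spacing, npts, {"C": grid},
                                np.zeros((npts,) * 3), np.zeros((npts,) * 3))
        mask = InteriorMask(np.zeros((npts,) * 3, dtype=bool),
                            np.zeros((npts,) * 3, dtype=int))
        return mapset, mask
    if shape in ("hollow-shell", "pocket"):
        rng = np.random.default_rng(seed)
        zcap = None if shape == "hollow-shell" else 1.2
        atoms = _shell_atoms(2.2, 90, zcap, rng)
        params = default_parameters()
        mapset = compute_maps(atoms, center, npts, spacing, ["C"], params)
        mask = build_interior_mask(atoms, center, npts, spacing, params)
        return mapset, mask
    raise ValueError(f"unknown map fixture shape {shape!r}")


# ---------------------------------------------------------------------------
# Down-weighting scenario

def downweight_poses(system: SyntheticSystem) -> tuple[Individual, Individual]:
    """Construct a correct/decoy pose pair on the two-flex system.

    The correct pose puts the ligand on the enumerated optimum site but
    strains the second side chain (positive receptor internal energy); the
    decoy parks the ligand on an inferior distant site with both side
    chains relaxed.  Down-weighting the receptor term should rank the
    correct pose at least as well as unweighted scoring does.
    """
    if system.name != "two-flex" or system.optimum is None:
        raise ValueError("down-weighting scenario requires a built two-flex system")
    builder = PhenotypeBuilder(system.ligand, system.receptor)
    genome = builder.genome
    scorer_raw = system.scorer(w_rec=1.0)
    n_flex = len(genome.chi_counts)
    w_down = 1.0 / n_flex

    def totals(g):
        lig, fr = builder.build(Individual(g.copy()))
        s = scorer_raw.score(lig, fr)
        rec = s.e_frfr + s.e_frrr
        base = s.e_ll + s.e_lrr + s.e_lfr
        return base + rec, base + w_down * rec

    site = system.optimum.genotype[genome.translation]
    chi_grid = np.arange(-180.0, 180.0, 5.0)

    # decoy: best alternative site >= 2.5 A from the optimum, each side
    # chain relaxed to its own internal-energy minimum at that site
    best_decoy, best_t1 = None, np.inf
    for point in system.tpoints.points:
        if np.linalg.norm(point - site) < 2.5:
            continue
        gd = system.optimum.genotype.copy()
        gd[genome.translation] = point
        for k in range(n_flex):
            chis_t1 = []
            for chi in chi_grid:
                gk = gd.copy()
                gk[genome.chi_block(k)] = chi
                chis_t1.append(totals(gk)[0])
            gd[genome.chi_block(k)] = chi_grid[int(np.argmin(chis_t1))]
        t1, _ = totals(gd)
        if t1 < best_t1:
            best_t1, best_decoy = t1, gd.copy()
    decoy = Individual(best_decoy)
    t1_decoy, tw_decoy = totals(decoy.genotype)

    # correct pose: enumerated optimum site/chi1, second side chain strained
    # so that unweighted scoring prefers the decoy but 1/NFS does not
    best_g, best_margin = None, -np.inf
    for chi in chi_grid:
        g = system.optimum.genotype.copy()
        g[genome.chi_block(1)] = chi
        if np.linalg.norm(_serine_og_position(system, 1, chi) - site) < 3.0:
            continue
        t1, tw = totals(g)
        margin = min(t1 - t1_decoy, tw_decoy - tw)
        if margin > best_margin:
            best_margin, best_g = margin, g.copy()
    correct = Individual(best_g)
    return correct, decoy
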