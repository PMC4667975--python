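"""Reading and writing the docking tool's file formats.

Supported formats:

* PDBQT ligands (ROOT/BRANCH/TORSDOF torsion tree, partial charges,
  AutoDock atom types) and PDBQT receptors, with flexible side-chain
  poses written as BEGIN_RES/END_RES blocks;
* AutoGrid-style ASCII affinity maps (SPACING / NELEMENTS / CENTER header,
  one value per line, x varying fastest);
* translational-point files (4 columns: x y z carbon-affinity);
* YAML run configurations.

Coordinates are Angstroms in a right-handed frame as in PDB.  Grid node
(0,0,0) sits at center - (npts-1)/2 * spacing on each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import residues
from .geom import dihedral
from .params import FFParameters, UnknownAtomTypeError, default_parameters

__all__ = [
    "Atom", "Branch", "LigandTopology", "FlexibleResidue", "ReceptorModel",
    "AffinityMapSet", "TranslationalPointSet", "PDBQTParseError",
    "read_ligand_pdbqt", "read_receptor_pdbqt", "make_receptor_model",
    "write_ligand_pdbqt", "read_map", "write_map", "read_map_set",
    "write_map_set", "read_translational_points", "write_translational_points",
    "load_config", "write_solutions",
]


class PDBQTParseError(ValueError):
    pass


@dataclass
class Atom:
    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    ad_type: str
    position: np.ndarray
    charge: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return residues.is_heavy(self.ad_type)

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.residue_name, self.residue_number,
                    self.chain, self.ad_type, self.position.copy(), self.charge)


@dataclass(frozen=True)
class Branch:
    """One rotatable bond of the ligand torsion tree."""
    parent: int                 # proximal axis atom index
    child: int                  # distal axis atom index
    moved: frozenset[int]       # atom indices moved by rotating this bond


@dataclass
class LigandTopology:
    atoms: list[Atom]
    root_atom: int
    branches: list[Branch]
    torsdof: int = 0
    _bonds: list[tuple[int, int]] | None = field(default=None, repr=False)

    @property
    def n_rotatable_bonds(self) -> int:
        return len(self.branches)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def ad_types(self) -> list[str]:
        return [a.ad_type for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def bonds(self) -> list[tuple[int, int]]:
        if self._bonds is None:
            self._bonds = residues.infer_bonds(self.coords, self.ad_types)
        return self._bonds

    def rotatable_bond_set(self) -> set[frozenset[int]]:
        return {frozenset((b.parent, b.child)) for b in self.branches}

    def torsion_quadruples(self) -> list[tuple[int, int, int, int]]:
        """Dihedral quadruple (p, a, b, c) per branch: p is the lowest-index
        bonded neighbour of the proximal axis atom outside the moved set, c
        the lowest-index neighbour of the distal atom inside it."""
        adj = residues.bond_adjacency(len(self.atoms), self.bonds)
        quads = []
        for br in self.branches:
            p = min(i for i in adj[br.parent] if i != br.child and i not in br.moved)
            c = min(i for i in adj[br.child] if i != br.parent and i in br.moved)
            quads.append((p, br.parent, br.child, c))
        return quads


@dataclass
class FlexibleResidue:
    """A receptor residue whose side chain beyond CB is movable."""
    chain: str
    residue_name: str
    residue_number: int
    atom_indices: list[int]                 # all atoms of the residue (global)
    chi_quads: list[tuple[int, int, int, int]]   # global indices
    chi_moved: list[frozenset[int]]         # global indices moved per chi
    chi0: np.ndarray                        # initial chi angles, degrees

    @property
    def residue_id(self) -> str:
        return f"{self.residue_name}{self.residue_number}"

    @property
    def n_chi(self) -> int:
        return len(self.chi_quads)

    @property
    def movable(self) -> list[int]:
        return sorted(self.chi_moved[0]) if self.chi_moved else []


@dataclass
class ReceptorModel:
    atoms: list[Atom]
    flexible_residues: list[FlexibleResidue]

    @property
    def movable_indices(self) -> list[int]:
        out: list[int] = []
        for fr in self.flexible_residues:
            out.extend(fr.movable)
        return out

    @property
    def rigid_indices(self) -> list[int]:
        movable = set(self.movable_indices)
        return [i for i in range(len(self.atoms)) if i not in movable]

    @property
    def rigid_atoms(self) -> list[Atom]:
        return [self.atoms[i] for i in self.rigid_indices]

    @property
    def movable_atoms(self) -> list[Atom]:
        return [self.atoms[i] for i in self.movable_indices]

    @property
    def n_flexible(self) -> int:
        return len(self.flexible_residues)

    def initial_chi_angles(self) -> list[np.ndarray]:
        return [fr.chi0.copy() for fr in self.flexible_residues]


# ---------------------------------------------------------------------------
# PDBQT

def _parse_atom_line(line: str, lineno: int, params: FFParameters) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resnum = int(line[22:26])
        pos = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        charge = float(line[70:76])
        ad_type = line[77:79].strip()
    except (ValueError, IndexError) as exc:
        raise PDBQTParseError(f"malformed ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    if not params.has_type(ad_type):
        raise UnknownAtomTypeError(ad_type)
    return Atom(serial, name, resname, resnum, chain, ad_type, np.array(pos), charge)


def _format_atom_line(a: Atom, serial: int | None = None, record: str = "ATOM") -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.position
    return (f"{record:<6s}{serial if serial is not None else a.serial:>5d} {name:<4s}"
            f" {a.residue_name:>3s} {a.chain:1s}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    {a.charge:6.3f} {a.ad_type:<2s}")


def read_ligand_pdbqt(path, params: FFParameters | None = None) -> LigandTopology:
    """Parse a PDBQT ligand file into atoms plus a torsion tree.

    Raises PDBQTParseError (naming the line) on unbalanced BRANCH nesting and
    UnknownAtomTypeError for atom-type codes missing from the parameter table.
    """
    params = params or default_parameters()
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    stack: list[tuple[int, int, list[int]]] = []   # (parent_serial, child_serial, moved)
    finished: list[Branch] = []
    root_atom: int | None = None
    in_root = False
    torsdof = 0
    layout: list[tuple] = []

    in_flex = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip().upper()
        if line.startswith("BEGIN_RES"):
            in_flex = True     # flexible-residue blocks are not ligand atoms
        elif line.startswith("END_RES"):
            in_flex = False
        elif in_flex:
            pass
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno, params)
            idx = len(atoms)
            atoms.append(atom)
            serial_to_index[atom.serial] = idx
            for _, _, moved in stack:
                moved.append(idx)
            if in_root and root_atom is None:
                root_atom = idx
            layout.append(("ATOM", idx))
        elif line.startswith("ROOT"):
            in_root = True
            layout.append(("ROOT",))
        elif line.startswith("ENDROOT"):
            in_root = False
            layout.append(("ENDROOT",))
        elif line.startswith("BRANCH"):
            try:
                _, s1, s2 = line.split()
            except ValueError:
                raise PDBQTParseError(f"malformed BRANCH at line {lineno}")
            stack.append((int(s1), int(s2), []))
            layout.append(("BRANCH", int(s1), int(s2)))
        elif line.startswith("ENDBRANCH"):
            if not stack:
                raise PDBQTParseError(f"ENDBRANCH without matching BRANCH at line {lineno}")
            s1, s2, moved = stack.pop()
            try:
                finished.append(Branch(serial_to_index[s1], serial_to_index[s2], frozenset(moved)))
            except KeyError as exc:
                raise PDBQTParseError(f"BRANCH at line {lineno} references unknown serial {exc}") from None
            layout.append(("ENDBRANCH", s1, s2))
        elif line.startswith("TORSDOF"):
            torsdof = int(line.split()[1])
            layout.append(("TORSDOF",))

    if stack:
        raise PDBQTParseError(f"unclosed BRANCH record(s): {[(s1, s2) for s1, s2, _ in stack]}")
    if root_atom is None:
        raise PDBQTParseError("no ROOT record found")
    # restore file order of branches (outermost first)
    order = {(b.parent, b.child): i for i, b in enumerate(finished)}
    branch_seq = [t for t in layout if t[0] == "BRANCH"]
    ordered = sorted(finished, key=lambda b: branch_seq.index(
        ("BRANCH", atoms[b.parent].serial, atoms[b.child].serial)))
    del order
    top = LigandTopology(atoms, root_atom, ordered, torsdof)
    top._layout = layout  # used to re-emit an identically structured file
    return top


def write_ligand_pdbqt(top: LigandTopology, path, coords: np.ndarray | None = None) -> None:
    """Write a ligand PDBQT reproducing the torsion-tree record structure."""
    coords = top.coords if coords is None else np.asarray(coords)
    layout = getattr(top, "_layout", None)
    if layout is None:
        layout = _synthesize_layout(top)
    lines = []
    for tok in layout:
        if tok[0] == "ATOM":
            a = top.atoms[tok[1]]
            a2 = a.copy()
            a2.position = coords[tok[1]]
            lines.append(_format_atom_line(a2))
        elif tok[0] == "ROOT":
            lines.append("ROOT")
        elif tok[0] == "ENDROOT":
            lines.append("ENDROOT")
        elif tok[0] == "BRANCH":
            lines.append(f"BRANCH {tok[1]:>3d} {tok[2]:>3d}")
        elif tok[0] == "ENDBRANCH":
            lines.append(f"ENDBRANCH {tok[1]:>3d} {tok[2]:>3d}")
        elif tok[0] == "TORSDOF":
            lines.append(f"TORSDOF {top.torsdof}")
    if not any(t[0] == "TORSDOF" for t in layout):
        lines.append(f"TORSDOF {top.torsdof}")
    Path(path).write_text("\n".join(lines) + "\n")


def _synthesize_layout(top: LigandTopology) -> list[tuple]:
    """Build a ROOT/BRANCH record layout for a programmatically built ligand."""
    all_moved = set().union(*[b.moved for b in top.branches]) if top.branches else set()
    root_atoms = [i for i in range(len(top.atoms)) if i not in all_moved]
    layout: list[tuple] = [("ROOT",)] + [("ATOM", i) for i in root_atoms] + [("ENDROOT",)]

    # nest branches: children of a branch are branches whose moved set is a strict subset
    tops = [b for b in top.branches]

    def emit(branch: Branch, remaining: list[Branch]):
        seq = [("BRANCH", top.atoms[branch.parent].serial, top.atoms[branch.child].serial)]
        inner = [b for b in remaining if b is not branch and b.moved < branch.moved]
        direct = [b for b in inner if not any(b.moved < o.moved for o in inner if o is not b)]
        covered = set().union(*[b.moved for b in inner]) if inner else set()
        seq += [("ATOM", i) for i in sorted(branch.moved - covered)]
        for b in direct:
            seq += emit(b, inner)
        seq.append(("ENDBRANCH", top.atoms[branch.parent].serial, top.atoms[branch.child].serial))
        return seq

    outer = [b for b in tops if not any(b.moved < o.moved for o in tops if o is not b)]
    for b in outer:
        layout += emit(b, tops)
    layout.append(("TORSDOF",))
    return layout


def read_flex_blocks(path, params: FFParameters | None = None) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Parse BEGIN_RES/END_RES blocks of a pose file: residue id ->
    (coordinates, atom types) of the residue's atoms."""
    params = params or default_parameters()
    blocks: dict[str, tuple[list, list]] = {}
    current = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("BEGIN_RES"):
            _, resname, chain, resnum = line.split()
            current = f"{resname}{resnum}"
            blocks[current] = ([], [])
        elif line.startswith("END_RES"):
            current = None
        elif current is not None and line[:6].strip().upper() in ("ATOM", "HETATM"):
            a = _parse_atom_line(line, lineno, params)
            blocks[current][0].append(a.position)
            blocks[current][1].append(a.ad_type)
    return {k: (np.array(pos), types) for k, (pos, types) in blocks.items()}


def read_receptor_pdbqt(path, flexible_residue_ids=(), params: FFParameters | None = None) -> ReceptorModel:
    """Parse a receptor PDBQT and register the named flexible residues.

    `flexible_residue_ids` entries are strings like "LYS33" or "A:LYS33".
    """
    params = params or default_parameters()
    atoms: list[Atom] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line[:6].strip().upper() in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno, params))
    return make_receptor_model(atoms, flexible_residue_ids)


def _match_residue(atoms: list[Atom], rid: str) -> tuple[str, str, int]:
    chain = None
    if ":" in rid:
        chain, rid = rid.split(":", 1)
    resname = "".join(ch for ch in rid if ch.isalpha()).upper()
    resnum = int("".join(ch for ch in rid if ch.isdigit()))
    for a in atoms:
        if a.residue_name == resname and a.residue_number == resnum and (chain is None or a.chain == chain):
            return a.chain, resname, resnum
    raise KeyError(f"flexible residue {rid!r} not found in receptor")


def make_receptor_model(atoms: list[Atom], flexible_residue_ids=()) -> ReceptorModel:
    """Assemble a ReceptorModel, deriving chi definitions, movable-atom sets
    and initial chi angles for every requested flexible residue."""
    flex: list[FlexibleResidue] = []
    for rid in flexible_residue_ids:
        chain, resname, resnum = _match_residue(atoms, rid)
        if resname in residues.NO_CHI:
            raise ValueError(f"residue {rid}: {resname} has no chi angles")
        if resname not in residues.FLEXIBLE_CAPABLE:
            raise ValueError(f"residue {rid}: {resname} cannot be made flexible")
        idx = [i for i, a in enumerate(atoms)
               if a.chain == chain and a.residue_number == resnum and a.residue_name == resname]
        by_name = {atoms[i].name: i for i in idx}
        local_pos = np.array([atoms[i].position for i in idx])
        local_types = [atoms[i].ad_type for i in idx]
        bonds = residues.infer_bonds(local_pos, local_types)
        adj = residues.bond_adjacency(len(idx), bonds)
        loc = {g: l for l, g in enumerate(idx)}

        quads, moved_sets, chi0 = [], [], []
        for quad_names in residues.CHI_ATOMS[resname]:
            try:
                q = tuple(by_name[n] for n in quad_names)
            except KeyError as exc:
                raise PDBQTParseError(f"residue {rid}: missing atom {exc} for chi definition") from None
            a2, a3 = loc[q[1]], loc[q[2]]
            comp = residues.connected_component(adj, a3, blocked_edge=(a2, a3))
            moved = frozenset(idx[l] for l in comp) - {q[2]}
            moved_sets.append(moved | {q[3]} if q[3] not in moved else moved)
            quads.append(q)
            chi0.append(dihedral(*[atoms[i].position for i in q]))
        # movable sets must be nested along the chain
        for k in range(1, len(moved_sets)):
            if not moved_sets[k] <= moved_sets[k - 1]:
                raise PDBQTParseError(f"residue {rid}: chi moved-sets are not nested")
        flex.append(FlexibleResidue(chain, resname, resnum, idx, quads, moved_sets,
                                    np.array(chi0)))
    return ReceptorModel(atoms, flex)


# ---------------------------------------------------------------------------
# Affinity maps

@dataclass
class AffinityMapSet:
    """Per-atom-type affinity grids plus electrostatic and desolvation grids.

    Grids are indexed [ix, iy, iz]; values are kcal/mol (electrostatic grid:
    kcal/mol per unit probe charge; desolvation grid: kcal/mol per unit |q|).
    """
    center: np.ndarray
    spacing: float
    npts: int
    maps: dict[str, np.ndarray]
    electrostatic: np.ndarray | None = None
    desolvation: np.ndarray | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.npts % 2 == 0:
            raise ValueError("npts must be odd")
        for g in self.all_grids().values():
            if g.shape != (self.npts,) * 3:
                raise ValueError("all grids must share npts")

    def all_grids(self) -> dict[str, np.ndarray]:
        out = dict(self.maps)
        if self.electrostatic is not None:
            out["e"] = self.electrostatic
        if self.desolvation is not None:
            out["d"] = self.desolvation
        return out

    @property
    def origin(self) -> np.ndarray:
        return self.center - 0.5 * (self.npts - 1) * self.spacing

    @property
    def extent(self) -> float:
        """Half edge length of the box, A."""
        return 0.5 * (self.npts - 1) * self.spacing

    def axis_coords(self) -> list[np.ndarray]:
        return [self.origin[k] + self.spacing * np.arange(self.npts) for k in range(3)]

    def contains(self, pos: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pos)
        lo, hi = self.origin, self.origin + (self.npts - 1) * self.spacing
        return np.all((p >= lo) & (p <= hi), axis=1)


def write_map(path, grid: np.ndarray, center, spacing: float, label: str = "receptor") -> None:
    npts = grid.shape[0]
    cx, cy, cz = np.asarray(center, dtype=float)
    lines = [
        "GRID_PARAMETER_FILE none",
        "GRID_DATA_FILE none",
        f"MACROMOLECULE {label}",
        f"SPACING {spacing:.6g}",
        f"NELEMENTS {npts - 1} {npts - 1} {npts - 1}",
        f"CENTER {cx:.3f} {cy:.3f} {cz:.3f}",
    ]
    # x varies fastest, z slowest (AutoGrid convention)
    vals = grid.transpose(2, 1, 0).ravel()
    lines.extend(f"{v:.6f}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def read_map(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read one ASCII map; returns (grid, center, spacing)."""
    lines = Path(path).read_text().splitlines()
    spacing = npts = center = None
    body_start = 0
    for i, line in enumerate(lines):
        key = line.split()[0] if line.split() else ""
        if key == "SPACING":
            spacing = float(line.split()[1])
        elif key == "NELEMENTS":
            nel = [int(v) for v in line.split()[1:4]]
            if len(set(nel)) != 1:
                raise PDBQTParseError("only cubic maps are supported")
            npts = nel[0] + 1
        elif key == "CENTER":
            center = np.array([float(v) for v in line.split()[1:4]])
        elif key in ("GRID_PARAMETER_FILE", "GRID_DATA_FILE", "MACROMOLECULE"):
            pass
        else:
            body_start = i
            break
    if spacing is None or npts is None or center is None:
        raise PDBQTParseError(f"incomplete map header in {path}")
    vals = np.array([float(v) for v in lines[body_start:] if v.strip()])
    if vals.size != npts**3:
        raise PDBQTParseError(
            f"truncated map {path}: expected {npts**3} values, found {vals.size}")
    grid = vals.reshape(npts, npts, npts).transpose(2, 1, 0)
    return grid, center, spacing


def write_map_set(mapset: AffinityMapSet, out_dir, stem: str = "rec") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, grid in mapset.all_grids().items():
        p = out_dir / f"{stem}.{name}.map"
        write_map(p, grid, mapset.center, mapset.spacing)
        written.append(p)
    return written


def read_map_set(map_dir, stem: str = "rec") -> AffinityMapSet:
    map_dir = Path(map_dir)
    maps, e_grid, d_grid = {}, None, None
    center = spacing = None
    paths = sorted(map_dir.glob(f"{stem}.*.map"))
    if not paths:
        raise FileNotFoundError(f"no {stem}.*.map files in {map_dir}")
    for p in paths:
        name = p.name[len(stem) + 1:-4]
        grid, c, s = read_map(p)
        if center is None:
            center, spacing = c, s
        elif not (np.allclose(center, c) and math.isclose(spacing, s)):
            raise PDBQTParseError(f"map {p} has inconsistent geometry")
        if name == "e":
            e_grid = grid
        elif name == "d":
            d_grid = grid
        else:
            maps[name] = grid
    npts = next(iter(maps.values())).shape[0] if maps else (e_grid.shape[0] if e_grid is not None else d_grid.shape[0])
    return AffinityMapSet(center, spacing, npts, maps, e_grid, d_grid)


# ---------------------------------------------------------------------------
# Translational points

@dataclass
class TranslationalPointSet:
    points: np.ndarray          # (n, 3) A
    affinities: np.ndarray      # (n,) kcal/mol carbon affinity
    source_spacing: float       # spacing of the originating map, A

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.affinities = np.asarray(self.affinities, dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lattice_spacing(self) -> float:
        """Nearest-neighbour spacing of the down-sampled point lattice, A."""
        if len(self) < 2:
            return 0.0
        d = np.linalg.norm(self.points[None, :, :] - self.points[:, None, :], axis=-1)
        d[d == 0] = np.inf
        return float(d.min())


def write_translational_points(tp: TranslationalPointSet, path) -> None:
    lines = [f"# translational points; source map spacing {tp.source_spacing:.6g} A",
             "# x y z carbon_affinity"]
    for (x, y, z), a in zip(tp.points, tp.affinities):
        lines.append(f"{x:10.4f} {y:10.4f} {z:10.4f} {a:10.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_translational_points(path) -> TranslationalPointSet:
    pts, affs = [], []
    spacing = 0.375
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "spacing" in line:
                spacing = float(line.split()[-2])
            continue
        if line.strip():
            x, y, z, a = (float(v) for v in line.split())
            pts.append((x, y, z))
            affs.append(a)
    return TranslationalPointSet(np.array(pts), np.array(affs), spacing)


# ---------------------------------------------------------------------------
# Config and solutions

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping of keys to values")
    return cfg


def write_solutions(result, out_dir, ligand: LigandTopology, receptor: ReceptorModel) -> list[Path]:
    """Write one PDBQT pose per reported cluster plus a TSV score table."""
    from .ga import DockingResult  # local import to avoid a cycle
    assert isinstance(result, DockingResult)
    if not result.solutions:
        raise ValueError("empty docking result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows = ["rank\ttotal\te_ll\te_lrr\te_lfr\te_frfr\te_frrr\tw_rec\tcluster_size"]
    for rank, sol in enumerate(result.solutions, start=1):
        lig_coords, fr_coords = sol.phenotype
        pose_path = out_dir / f"pose_{rank:02d}.pdbqt"
        write_ligand_pdbqt(ligand, pose_path, lig_coords)
        if receptor.n_flexible:
            with open(pose_path, "a") as fh:
                fr_by_index = dict(zip(receptor.movable_indices,
                                       fr_coords if fr_coords is not None else []))
                for fr in receptor.flexible_residues:
                    fh.write(f"BEGIN_RES {fr.residue_name} {fr.chain} {fr.residue_number}\n")
                    for gi in fr.atom_indices:
                        a = receptor.atoms[gi].copy()
                        if gi in fr_by_index:
                            a.position = fr_by_index[gi]
                        fh.write(_format_atom_line(a) + "\n")
                    fh.write(f"END_RES {fr.residue_name} {fr.chain} {fr.residue_number}\n")
        written.append(pose_path)
        s = sol.score
        rows.append(f"{rank}\t{s.total:.4f}\t{s.e_ll:.4f}\t{s.e_lrr:.4f}\t{s.e_lfr:.4f}"
                    f"\t{s.e_frfr:.4f}\t{s.e_frrr:.4f}\t{s.w_rec:.6g}\t{sol.cluster_size}")
    table = out_dir / "solutions.tsv"
    table.write_text("\n".join(rows) + "\n")
    written.append(table)
    return written
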