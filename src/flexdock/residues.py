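"""Amino-acid side-chain dihedral (chi) definitions and element utilities.

The chi table follows the IUPAC heavy-atom convention for the 18 chi-bearing
residue types.  PRO is listed for completeness but cannot be made flexible:
its side chain closes a ring onto the backbone, so free chi rotation would
break covalent geometry.
"""

from __future__ import annotations

import numpy as np

# chi dihedral atom-name quadruples, chi1..chiN per residue type
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# residues that may be declared flexible (PRO excluded: ring closure)
FLEXIBLE_CAPABLE = frozenset(CHI_ATOMS) - {"PRO"}

# residues without chi angles
NO_CHI = frozenset({"GLY", "ALA"})

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HN", "HA"})

# topologically equivalent terminal atom pairs (ring flips / carboxylates);
# kept for symmetry-aware pose comparison
SYMMETRIC_TERMINI: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
}

# map AutoDock atom-type codes to chemical elements
_AD_TYPE_ELEMENT = {
    "H": "H", "HD": "H", "HS": "H",
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "P": "P", "F": "F", "Cl": "Cl", "Br": "Br", "I": "I",
    "Mg": "Mg", "Ca": "Ca", "Mn": "Mn", "Fe": "Fe", "Zn": "Zn",
}

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Mg": 1.41, "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Zn": 1.22,
}


def element_of(ad_type: str) -> str:
    return _AD_TYPE_ELEMENT.get(ad_type, ad_type[:1].upper())


def is_heavy(ad_type: str) -> bool:
    return element_of(ad_type) != "H"


def infer_bonds(positions: np.ndarray, ad_types: list[str], slack: float = 0.45) -> list[tuple[int, int]]:
    """Infer covalent bonds from distances vs covalent-radius sums.

    Two atoms are bonded when their distance is below the sum of covalent
    radii plus `slack` Angstroms; standard heuristic for files without
    explicit connectivity records.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    radii = np.array([_COVALENT_RADII.get(element_of(t), 0.77) for t in ad_types])
    bonds = []
    for i in range(n):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        cut = radii[i] + radii[i + 1:] + slack
        for off in np.nonzero((d < cut) & (d > 1e-6))[0]:
            bonds.append((i, int(i + 1 + off)))
    return bonds


def bond_adjacency(n_atoms: int, bonds) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def connected_component(adj: list[set[int]], start: int, blocked_edge: tuple[int, int] | None = None) -> set[int]:
    """Atoms reachable from `start`, optionally with one edge removed."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if blocked_edge and {u, v} == set(blocked_edge):
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen
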