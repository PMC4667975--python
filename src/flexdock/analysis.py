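"""Pose comparison and docking-outcome analyses.

Provides the symmetry-corrected (Hungarian) RMSD used for all reported
pose comparisons, rank/success metrics for ranked solution lists, the
steric-clash rule and distance-based flexible-residue selection used when
assembling cross-docking systems, contact-recovery tabulation between a
reference (holo) complex and a docked pose, and the rotamer-change count
for side-chain motion analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import residues
from .io_formats import Atom
from .params import FFParameters, default_parameters

__all__ = [
    "ContactRecoveryReport", "hungarian_rmsd", "hungarian_matching",
    "rank_solutions", "detect_clashes", "select_flexible_residues",
    "contact_recovery", "rotamer_change_count", "circular_difference",
]


def hungarian_matching(coords_a: np.ndarray, types_a, coords_b: np.ndarray,
                       types_b) -> np.ndarray:
    """Optimal same-type atom correspondence between two poses.

    Returns an index array sigma with b[sigma[i]] matched to a[i]; the
    assignment minimizes summed squared distances within each atom-type
    block (Hungarian algorithm).  Raises ValueError when the type multisets
    differ.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    types_a, types_b = list(types_a), list(types_b)
    if sorted(types_a) != sorted(types_b):
        raise ValueError("atom-type multisets differ between poses")
    sigma = np.empty(len(types_a), dtype=int)
    for t in set(types_a):
        ia = np.array([i for i, x in enumerate(types_a) if x == t])
        ib = np.array([i for i, x in enumerate(types_b) if x == t])
        cost = cdist(coords_a[ia], coords_b[ib], metric="sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        sigma[ia[rows]] = ib[cols]
    return sigma


def hungarian_rmsd(coords_a: np.ndarray, types_a, coords_b: np.ndarray,
                   types_b) -> float:
    """Symmetry-corrected RMSD: minimum-cost pairing of same-type atoms, no
    superposition (both poses share one frame)."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    sigma = hungarian_matching(coords_a, types_a, coords_b, types_b)
    d = coords_a - coords_b[sigma]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rank_solutions(result, reference_coords: np.ndarray, reference_types,
                   rmsd_cutoff: float = 2.0):
    """1-based rank of the first solution within `rmsd_cutoff` of the
    reference pose (None when absent), plus the score difference between the
    best correct and best incorrect solution when both exist.

    A rank of N > 1 means N-1 false positives scored better than the first
    correct pose.
    """
    rank = None
    best_correct = best_incorrect = None
    for i, sol in enumerate(result.solutions, start=1):
        lig = sol.phenotype[0]
        ok = hungarian_rmsd(lig, reference_types, reference_coords, reference_types) <= rmsd_cutoff
        if ok and rank is None:
            rank = i
            best_correct = sol.score.total
        elif not ok and best_incorrect is None:
            best_incorrect = sol.score.total
    delta = None
    if best_correct is not None and best_incorrect is not None:
        delta = best_correct - best_incorrect
    return rank, delta


def detect_clashes(lig_coords: np.ndarray, lig_types, rec_coords: np.ndarray,
                   rec_types, params: FFParameters | None = None) -> list[tuple[int, int]]:
    """Heavy-atom pairs closer than half the sum of their vdW radii."""
    params = params or default_parameters()
    li = [i for i, t in enumerate(lig_types) if residues.is_heavy(t)]
    ri = [j for j, t in enumerate(rec_types) if residues.is_heavy(t)]
    if not li or not ri:
        return []
    lrad = np.array([params.vdw_radius(lig_types[i]) for i in li])
    rrad = np.array([params.vdw_radius(rec_types[j]) for j in ri])
    d = cdist(np.asarray(lig_coords)[li], np.asarray(rec_coords)[ri])
    thr = 0.5 * (lrad[:, None] + rrad[None, :])
    out = []
    for a, b in zip(*np.nonzero(d < thr)):
        out.append((li[a], ri[b]))
    return out


def select_flexible_residues(lig_coords: np.ndarray, lig_types,
                             receptor_atoms: list[Atom],
                             distance: float = 4.0) -> list[str]:
    """Residues with at least one side-chain heavy atom beyond CB within
    `distance` of a ligand heavy atom.  GLY/ALA (no atoms beyond CB) are
    never returned."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    lig_heavy = np.asarray(lig_coords)[[i for i, t in enumerate(lig_types)
                                        if residues.is_heavy(t)]]
    if len(lig_heavy) == 0:
        return []
    hits: dict[tuple, str] = {}
    backbone_plus_cb = residues.BACKBONE_NAMES | {"CB"}
    for a in receptor_atoms:
        if a.residue_name in residues.NO_CHI or a.residue_name not in residues.CHI_ATOMS:
            continue
        if a.name in backbone_plus_cb or not a.is_heavy:
            continue
        if np.min(np.linalg.norm(lig_heavy - a.position, axis=1)) <= distance:
            hits[(a.chain, a.residue_number)] = f"{a.residue_name}{a.residue_number}"
    return [hits[k] for k in sorted(hits)]


@dataclass
class ContactRecoveryReport:
    per_residue: dict[str, dict]       # id -> {reference, recovered, novel}
    recovery_percent: float

    def residue_percent(self, rid: str) -> float:
        rec = self.per_residue[rid]
        return 100.0 * rec["recovered"] / rec["reference"] if rec["reference"] else 100.0


def contact_recovery(holo_lig_coords, lig_types, holo_residue_atoms: dict,
                     docked_lig_coords, docked_residue_coords: dict,
                     threshold: float = 5.0) -> ContactRecoveryReport:
    """Fraction of reference ligand/side-chain atom contacts reproduced in a
    docked pose.

    `holo_residue_atoms` maps residue id -> (coords, types) of its movable
    atoms in the reference complex; `docked_residue_coords` maps the same
    ids -> coords of those atoms in the docked pose (same atom order).
    Ligand atom symmetry is handled by the same per-type Hungarian
    correspondence as the RMSD metric; contacts present only in the docked
    pose are counted as novel.
    """
    holo_lig = np.asarray(holo_lig_coords, dtype=float)
    dock_lig = np.asarray(docked_lig_coords, dtype=float)
    if holo_lig.shape != dock_lig.shape:
        raise ValueError("ligand chemistry differs between complexes")
    sigma = hungarian_matching(holo_lig, lig_types, dock_lig, lig_types)
    per_residue = {}
    total_ref = total_rec = 0
    for rid, (rc, rt) in holo_residue_atoms.items():
        rc = np.asarray(rc, dtype=float)
        dc = np.asarray(docked_residue_coords[rid], dtype=float)
        if rc.shape != dc.shape:
            raise ValueError(f"residue {rid}: atom count differs between complexes")
        ref_d = cdist(holo_lig, rc)
        doc_d = cdist(dock_lig[sigma], dc)
        ref_pairs = ref_d <= threshold
        doc_pairs = doc_d <= threshold
        n_ref = int(ref_pairs.sum())
        n_rec = int((ref_pairs & doc_pairs).sum())
        n_novel = int((doc_pairs & ~ref_pairs).sum())
        per_residue[rid] = {"reference": n_ref, "recovered": n_rec, "novel": n_novel}
        total_ref += n_ref
        total_rec += n_rec
    pct = 100.0 * total_rec / total_ref if total_ref else 100.0
    return ContactRecoveryReport(per_residue, pct)


def circular_difference(a, b):
    """Absolute circular angle difference in degrees, wrapped to [0, 180]."""
    d = np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0)
    return d


def rotamer_change_count(reference_chis: list[np.ndarray],
                         chis: list[np.ndarray], threshold: float = 50.0) -> int:
    """Number of residues with at least one chi deviating by >= `threshold`
    degrees (circular) from the reference conformation; the boundary counts
    as changed."""
    if len(reference_chis) != len(chis):
        raise ValueError("chi sets are not congruent")
    n = 0
    for ref, cur in zip(reference_chis, chis):
        if len(ref) != len(cur):
            raise ValueError("chi sets are not congruent")
        if len(ref) and np.any(circular_difference(ref, cur) >= threshold):
            n += 1
    return n
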