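"""Pairwise energy evaluation and the five-term docking score.

The total score decomposes interactions over three atom groups -- ligand
(L), rigid receptor (RR) and flexible receptor (FR):

    S = E_LL + E_LRR + E_LFR + w_rec * (E_FRFR + E_FRRR)

E_LL, E_LFR, E_FRFR and E_FRRR are explicit pairwise sums (1-2 and 1-3
pairs excluded; 1-4 pairs excluded unless the central bond is rotatable);
E_LRR comes from trilinear interpolation of precomputed affinity maps.
Movable side-chain atoms sit on or inside the receptor surface, where the
post-processed maps no longer carry physical values, so their rigid-receptor
interaction is summed explicitly against a precomputed neighbour list
instead of interpolated.
The receptor-internal terms are down-weighted by w_rec = 1/NFS, NFS being
the number of flexible side chains, which stops receptor self-energy from
swamping ligand-receptor interactions as flexibility grows.

For explicit pairs the hydrogen-bond 12-10 term is evaluated without the
angular factor (distance-only); maps bake directionality in at build time
if their builder chooses to.  This is a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AffinityMapSet, LigandTopology, ReceptorModel
from .params import FFParameters, default_parameters
from . import residues
from .grids import OutsideBoxError

__all__ = [
    "PairEnergy", "PairList", "ScoreBreakdown", "Scorer",
    "pair_energy", "build_pair_list", "set_receptor_weight",
]


@dataclass(frozen=True)
class PairEnergy:
    vdw: float       # 12-6 (or 12-10 H-bond) contribution, kcal/mol
    elec: float
    desolv: float

    @property
    def total(self) -> float:
        return self.vdw + self.elec + self.desolv


def pair_energy(ti: str, tj: str, qi: float, qj: float, r: float,
                params: FFParameters | None = None) -> PairEnergy:
    """Weighted pairwise energy between two atoms at distance r (Angstrom)."""
    params = params or default_parameters()
    if r <= 0:
        raise ValueError("pair distance must be positive")
    rep, att, is_hb = params.pair_coefficients(ti, tj)
    w = params.w_hbond if is_hb else params.w_vdw
    power = 10 if is_hb else 6
    vdw = min(w * (rep / r**12 - att / r**power), params.vdw_clamp)
    elec = params.w_elec * params.coulomb * qi * qj / (params.epsilon(r) * r)
    si = params.solvation_s(ti, qi)
    sj = params.solvation_s(tj, qj)
    vi = params.record(ti).vol
    vj = params.record(tj).vol
    desolv = params.w_sol * (si * vj + sj * vi) * np.exp(-r * r / (2.0 * params.sigma**2))
    return PairEnergy(float(vdw), float(elec), float(desolv))


def set_receptor_weight(nfs: int, override: float | None = None) -> float:
    """Receptor-internal-energy weight: 1/NFS by default, overridable (e.g.
    1.0 reproduces unweighted scoring)."""
    if nfs < 0:
        raise ValueError("NFS must be non-negative")
    if override is not None:
        return float(override)
    return 1.0 / nfs if nfs >= 1 else 1.0


# ---------------------------------------------------------------------------
# Pair lists

@dataclass
class _PairBlock:
    """Vectorized coefficients for one category of explicit pairs."""
    i: np.ndarray                # indices into the mobile coordinate array
    j: np.ndarray
    rep: np.ndarray              # 12-exponent coefficient
    att: np.ndarray              # 6- or 10-exponent coefficient
    is_hb: np.ndarray            # bool
    qq: np.ndarray               # q_i * q_j
    solv: np.ndarray             # S_i V_j + S_j V_i

    @classmethod
    def from_pairs(cls, pairs, types, charges, params: FFParameters) -> "_PairBlock":
        n = len(pairs)
        i = np.empty(n, dtype=int)
        j = np.empty(n, dtype=int)
        rep = np.empty(n)
        att = np.empty(n)
        hb = np.empty(n, dtype=bool)
        qq = np.empty(n)
        solv = np.empty(n)
        for k, (a, b) in enumerate(pairs):
            i[k], j[k] = a, b
            rep[k], att[k], hb[k] = params.pair_coefficients(types[a], types[b])
            qq[k] = charges[a] * charges[b]
            sa = params.solvation_s(types[a], charges[a])
            sb = params.solvation_s(types[b], charges[b])
            solv[k] = sa * params.record(types[b]).vol + sb * params.record(types[a]).vol
        return cls(i, j, rep, att, hb, qq, solv)

    def __len__(self) -> int:
        return len(self.i)

    def energy(self, coords: np.ndarray, params: FFParameters) -> float:
        if len(self) == 0:
            return 0.0
        d = coords[self.i] - coords[self.j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        within = r <= params.nb_cutoff
        if not within.any():
            return 0.0
        r = r[within]
        r = np.where(r < 1e-6, 1e-6, r)
        rep, att, hb = self.rep[within], self.att[within], self.is_hb[within]
        r6 = r**6
        r12 = r6 * r6
        r10 = r6 * r**4
        w = np.where(hb, params.w_hbond, params.w_vdw)
        attr = np.where(hb, att / r10, att / r6)
        vdw = np.minimum(w * (rep / r12 - attr), params.vdw_clamp)
        elec = params.w_elec * params.coulomb * self.qq[within] / (params.epsilon(r) * r)
        desolv = params.w_sol * self.solv[within] * np.exp(-r * r / (2.0 * params.sigma**2))
        return float(np.sum(vdw + elec + desolv))


@dataclass
class PairList:
    """Explicit nonbonded pairs by category, plus the exclusion log and the
    excluded movable/rigid pairs (skipped when summing E_FRRR)."""
    ll: _PairBlock
    lfr: _PairBlock
    frfr: _PairBlock
    excluded: list[tuple[int, int, str]]
    # (fr_local_index, rigid_global_index) pairs on an exclusion list
    fr_rigid_exclusions: frozenset[tuple[int, int]] = frozenset()

    def pairs_of(self, category: str):
        block = {"L-L": self.ll, "L-FR": self.lfr, "FR-FR": self.frfr}[category]
        return list(zip(block.i.tolist(), block.j.tolist()))


def _graph_distances(n: int, bonds) -> np.ndarray:
    adj = residues.bond_adjacency(n, bonds)
    dist = np.full((n, n), 99, dtype=int)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier and d < 4:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[s, v] > d:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def _intra_pairs(n: int, bonds, rotatable: set[frozenset[int]],
                 offset: int = 0) -> tuple[list[tuple[int, int]], list[tuple[int, int, str]]]:
    """Nonbonded pairs within one covalent unit, applying the 1-2/1-3/rigid-1-4
    exclusion rule.  Returns (kept pairs, exclusion log), indices offset."""
    adj = residues.bond_adjacency(n, bonds)
    dist = _graph_distances(n, bonds)
    kept, excl = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if d == 1:
                excl.append((i + offset, j + offset, "1-2"))
            elif d == 2:
                excl.append((i + offset, j + offset, "1-3"))
            elif d == 3:
                mediated = any(
                    frozenset((a, b)) in rotatable
                    for a in adj[i] for b in adj[j]
                    if b in adj[a] and a != j and b != i)
                if mediated:
                    kept.append((i + offset, j + offset))
                else:
                    excl.append((i + offset, j + offset, "rigid 1-4"))
            else:
                kept.append((i + offset, j + offset))
    return kept, excl


def build_pair_list(ligand: LigandTopology, receptor: ReceptorModel | None = None,
                    params: FFParameters | None = None) -> PairList:
    """Enumerate explicit nonbonded pairs for the mobile atoms.

    Mobile-array indexing: ligand atoms first (0..n_lig-1) followed by the
    movable flexible-receptor atoms in receptor order.
    """
    params = params or default_parameters()
    n_lig = len(ligand.atoms)
    lig_types = ligand.ad_types
    lig_charges = ligand.charges

    if n_lig > 1:
        adj = residues.bond_adjacency(n_lig, ligand.bonds)
        if len(residues.connected_component(adj, 0)) != n_lig:
            raise ValueError("ligand covalent graph is disconnected")

    ll_pairs, excluded = _intra_pairs(n_lig, ligand.bonds, ligand.rotatable_bond_set())

    types = list(lig_types)
    charges = list(lig_charges)
    lfr_pairs: list[tuple[int, int]] = []
    frfr_pairs: list[tuple[int, int]] = []
    fr_rigid_excl: set[tuple[int, int]] = set()

    if receptor is not None and receptor.n_flexible:
        movable_global = receptor.movable_indices
        mob_of_global = {g: n_lig + k for k, g in enumerate(movable_global)}
        for g in movable_global:
            a = receptor.atoms[g]
            types.append(a.ad_type)
            charges.append(a.charge)

        # ligand vs all movable receptor atoms: never covalently linked
        for li in range(n_lig):
            for g in movable_global:
                lfr_pairs.append((li, mob_of_global[g]))

        per_res_movable: list[list[int]] = []
        for fr in receptor.flexible_residues:
            res_atoms = fr.atom_indices
            res_pos = np.array([receptor.atoms[i].position for i in res_atoms])
            res_types = [receptor.atoms[i].ad_type for i in res_atoms]
            bonds = residues.infer_bonds(res_pos, res_types)
            loc = {g: l for l, g in enumerate(res_atoms)}
            rot = {frozenset((loc[q[1]], loc[q[2]])) for q in fr.chi_quads}
            kept, excl = _intra_pairs(len(res_atoms), bonds, rot)
            movable_loc = {loc[g] for g in fr.movable}
            for i, j in kept:
                gi, gj = res_atoms[i], res_atoms[j]
                mi, mj = i in movable_loc, j in movable_loc
                if mi and mj:
                    frfr_pairs.append((mob_of_global[gi], mob_of_global[gj]))
                # movable-vs-rigid kept pairs are handled through the maps
            for i, j, why in excl:
                gi, gj = res_atoms[i], res_atoms[j]
                mi, mj = i in movable_loc, j in movable_loc
                if mi and mj:
                    excluded.append((mob_of_global[gi], mob_of_global[gj], why))
                elif mi != mj:
                    # excluded movable/rigid pair: skipped in the explicit
                    # E_FRRR sum
                    mob = mob_of_global[gi] if mi else mob_of_global[gj]
                    rigid_g = gj if mi else gi
                    fr_rigid_excl.add((mob - n_lig, rigid_g))
                    excluded.append((mob, -1 - rigid_g, why))
            per_res_movable.append([mob_of_global[g] for g in fr.movable])

        # movable atoms of different residues: all pairs interact
        for a in range(len(per_res_movable)):
            for b in range(a + 1, len(per_res_movable)):
                for mi in per_res_movable[a]:
                    for mj in per_res_movable[b]:
                        frfr_pairs.append((mi, mj))

    charges_arr = np.array(charges)
    ll = _PairBlock.from_pairs(ll_pairs, types, charges_arr, params)
    lfr = _PairBlock.from_pairs(lfr_pairs, types, charges_arr, params)
    frfr = _PairBlock.from_pairs(frfr_pairs, types, charges_arr, params)
    return PairList(ll, lfr, frfr, excluded, frozenset(fr_rigid_excl))


# ---------------------------------------------------------------------------
# Score assembly

@dataclass
class ScoreBreakdown:
    e_ll: float
    e_lrr: float
    e_lfr: float = 0.0
    e_frfr: float = 0.0
    e_frrr: float = 0.0
    w_rec: float = 1.0

    @property
    def total(self) -> float:
        return self.e_ll + self.e_lrr + self.e_lfr + self.w_rec * (self.e_frfr + self.e_frrr)


class Scorer:
    """Scores phenotypes (ligand + flexible-receptor coordinates).

    E_L-RR comes from trilinear map interpolation; E_FR-RR is an explicit
    pairwise sum over movable-atom/rigid-atom pairs within the cutoff
    (honouring the 1-2/1-3/rigid-1-4 exclusions exactly), prefiltered once
    to the rigid atoms reachable by each side chain.  Every call increments
    the evaluation counter.
    """

    # how far a side chain can swing from its CB, plus margin (A)
    _FR_REACH = 8.0

    def __init__(self, ligand: LigandTopology, receptor: ReceptorModel,
                 mapset: AffinityMapSet, params: FFParameters | None = None,
                 w_rec: float | None = None, outside_policy: str = "penalty",
                 outside_penalty: float = 1000.0):
        self.params = params or default_parameters()
        self.ligand = ligand
        self.receptor = receptor
        self.mapset = mapset
        self.w_rec = set_receptor_weight(receptor.n_flexible) if w_rec is None else float(w_rec)
        self.outside_policy = outside_policy
        self.outside_penalty = outside_penalty
        self.pair_list = build_pair_list(ligand, receptor, self.params)
        self.evaluations = 0
        self._lig_types = ligand.ad_types
        self._lig_charges = ligand.charges
        for t in set(self._lig_types):
            if t not in mapset.maps:
                raise KeyError(f"map set lacks a grid for atom type {t!r}")
        self._build_frrr_block()
        # per-ligand-atom combined grid: map_t + q * map_e + |q| * map_d
        # (charges are fixed, so the combination can be precomputed and all
        # atoms gathered in one trilinear pass)
        combos: dict[tuple[str, float], int] = {}
        grids = []
        self._atom_grid = np.empty(len(self._lig_types), dtype=int)
        for i, (t, q) in enumerate(zip(self._lig_types, self._lig_charges)):
            key = (t, float(q))
            if key not in combos:
                g = mapset.maps[t].copy()
                if mapset.electrostatic is not None:
                    g += q * mapset.electrostatic
                if mapset.desolvation is not None:
                    g += abs(q) * mapset.desolvation
                combos[key] = len(grids)
                grids.append(g)
            self._atom_grid[i] = combos[key]
        self._grids = np.stack(grids)
        self._lo = mapset.origin
        self._hi = mapset.origin + (mapset.npts - 1) * mapset.spacing

    def _build_frrr_block(self) -> None:
        """Precompute the movable/rigid pair block for explicit E_FRRR."""
        self._frrr_block = None
        rec = self.receptor
        if not rec.n_flexible:
            return
        movable = rec.movable_indices
        rigid = rec.rigid_indices
        rigid_pos = np.array([rec.atoms[g].position for g in rigid])
        # anchor each movable atom at its residue's CB (fallback: own position)
        anchors = []
        for fr in rec.flexible_residues:
            names = {rec.atoms[i].name: i for i in fr.atom_indices}
            cb = rec.atoms[names.get("CB", fr.movable[0])].position
            anchors.extend([cb] * len(fr.movable))
        reach = self.params.nb_cutoff + self._FR_REACH
        pairs, rigid_keep, seen = [], [], {}
        excl = self.pair_list.fr_rigid_exclusions
        for k, (g, anchor) in enumerate(zip(movable, anchors)):
            near = np.nonzero(np.linalg.norm(rigid_pos - anchor, axis=1) <= reach)[0]
            for ri in near:
                g_r = rigid[ri]
                if (k, g_r) in excl:
                    continue
                if g_r not in seen:
                    seen[g_r] = len(rigid_keep)
                    rigid_keep.append(g_r)
                pairs.append((k, len(movable) + seen[g_r]))
        if not pairs:
            return
        types = [rec.atoms[g].ad_type for g in movable] + \
                [rec.atoms[g].ad_type for g in rigid_keep]
        charges = np.array([rec.atoms[g].charge for g in movable] +
                           [rec.atoms[g].charge for g in rigid_keep])
        self._frrr_block = _PairBlock.from_pairs(pairs, types, charges, self.params)
        self._frrr_rigid_coords = np.array([rec.atoms[g].position for g in rigid_keep])

    def _map_energy(self, coords: np.ndarray) -> float:
        """Ligand-atom map interpolation over the precomputed combined grids."""
        lo, hi = self._lo, self._hi
        inside = np.all((coords >= lo) & (coords <= hi), axis=1)
        total = 0.0
        if not inside.all():
            if self.outside_policy == "error":
                raise OutsideBoxError("atom outside the map box")
            out = coords[~inside]
            excess = np.maximum(lo - out, 0) + np.maximum(out - hi, 0)
            total += float(np.sum(self.outside_penalty * (1.0 + np.linalg.norm(excess, axis=1))))
            coords = coords[inside]
            gi = self._atom_grid[inside]
        else:
            gi = self._atom_grid
        if coords.shape[0] == 0:
            return total
        n = self.mapset.npts
        p = (coords - lo) / self.mapset.spacing
        i0 = np.minimum(p.astype(int), n - 2)
        f = p - i0
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        G = self._grids
        v = ((G[gi, ix, iy, iz] * (1 - fx) + G[gi, ix + 1, iy, iz] * fx) * (1 - fy)
             + (G[gi, ix, iy + 1, iz] * (1 - fx) + G[gi, ix + 1, iy + 1, iz] * fx) * fy) * (1 - fz) \
            + ((G[gi, ix, iy, iz + 1] * (1 - fx) + G[gi, ix + 1, iy, iz + 1] * fx) * (1 - fy)
               + (G[gi, ix, iy + 1, iz + 1] * (1 - fx) + G[gi, ix + 1, iy + 1, iz + 1] * fx) * fy) * fz
        return total + float(v.sum())

    def score(self, lig_coords: np.ndarray, fr_coords: np.ndarray | None = None) -> ScoreBreakdown:
        self.evaluations += 1
        p = self.params
        fr_coords = np.zeros((0, 3)) if fr_coords is None else np.asarray(fr_coords)
        mobile = np.vstack([lig_coords, fr_coords]) if len(fr_coords) else np.asarray(lig_coords)
        e_ll = self.pair_list.ll.energy(mobile, p)
        e_lrr = self._map_energy(np.asarray(lig_coords))
        if self.receptor.n_flexible and len(fr_coords):
            e_lfr = self.pair_list.lfr.energy(mobile, p)
            e_frfr = self.pair_list.frfr.energy(mobile, p)
            e_frrr = 0.0
            if self._frrr_block is not None:
                comb = np.vstack([fr_coords, self._frrr_rigid_coords])
                e_frrr = self._frrr_block.energy(comb, p)
            return ScoreBreakdown(e_ll, e_lrr, e_lfr, e_frfr, e_frrr, self.w_rec)
        return ScoreBreakdown(e_ll, e_lrr, 0.0, 0.0, 0.0, self.w_rec)
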