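"""Affinity-map computation and post-processing.

Maps store, per grid node, the interaction energy of a probe atom with all
rigid receptor atoms within the nonbonded cutoff.  Three grid families are
produced: one per probe atom type (vdW/H-bond plus the charge-independent
part of desolvation), an electrostatic grid (per unit probe charge) and a
desolvation grid (per unit |probe charge|), so that the energy of an atom of
type t with charge q at position x is

    E(x) = map_t(x) + q * map_e(x) + |q| * map_d(x)

which matches an explicit pairwise sum exactly on grid nodes.

Post-processing replaces values on nodes buried inside the receptor with a
repulsive potential that increases with burial depth, guaranteeing a strict
downhill path from every interior node to the molecular surface.  This both
steers clash resolution and removes buried favourable cavities too small to
hold a ligand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import AffinityMapSet, Atom, TranslationalPointSet
from .params import FFParameters, default_parameters

__all__ = [
    "InteriorMask", "OutsideBoxError", "FullyBuriedBoxError",
    "compute_maps", "build_interior_mask", "postprocess_map",
    "interpolate", "interpolate_grid", "extract_translational_points",
]

_SIX = ndimage.generate_binary_structure(3, 1)   # 6-connected neighbourhood


class OutsideBoxError(ValueError):
    pass


class FullyBuriedBoxError(ValueError):
    pass


@dataclass
class InteriorMask:
    """Boolean interior classification plus 6-connected burial depth."""
    inside: np.ndarray    # bool grid, True = inside the receptor volume
    depth: np.ndarray     # int grid, graph steps to the nearest exterior node

    def __post_init__(self):
        if self.inside.shape != self.depth.shape:
            raise ValueError("mask grids must share shape")


def compute_maps(rigid_atoms: list[Atom], center, npts: int, spacing: float,
                 probe_types, params: FFParameters | None = None,
                 cutoff: float | None = None) -> AffinityMapSet:
    """Compute affinity maps for `probe_types` plus electrostatic and
    desolvation grids, by direct pairwise summation over rigid atoms."""
    params = params or default_parameters()
    cutoff = params.nb_cutoff if cutoff is None else cutoff
    probe_types = list(probe_types)
    center = np.asarray(center, dtype=float)
    axes = [center[k] - 0.5 * (npts - 1) * spacing + spacing * np.arange(npts)
            for k in range(3)]

    maps = {t: np.zeros((npts,) * 3) for t in probe_types}
    e_grid = np.zeros((npts,) * 3)
    d_grid = np.zeros((npts,) * 3)
    touched = False

    for atom in rigid_atoms:
        # local window of nodes within the cutoff of this atom
        sl, local_axes = [], []
        for k in range(3):
            ok = np.nonzero(np.abs(axes[k] - atom.position[k]) <= cutoff)[0]
            if ok.size == 0:
                break
            sl.append(slice(ok[0], ok[-1] + 1))
            local_axes.append(axes[k][ok[0]:ok[-1] + 1])
        if len(sl) < 3:
            continue
        dx = local_axes[0][:, None, None] - atom.position[0]
        dy = local_axes[1][None, :, None] - atom.position[1]
        dz = local_axes[2][None, None, :] - atom.position[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        mask = r <= cutoff
        if not mask.any():
            continue
        touched = True
        r = np.where(r < 1e-6, 1e-6, r)
        window = tuple(sl)
        gauss = np.exp(-r**2 / (2.0 * params.sigma**2))
        s_rec = params.solvation_s(atom.ad_type, atom.charge)
        vol_rec = params.record(atom.ad_type).vol
        for t in probe_types:
            rep, att, is_hb = params.pair_coefficients(t, atom.ad_type)
            w = params.w_hbond if is_hb else params.w_vdw
            power = 10 if is_hb else 6
            vdw = w * (rep / r**12 - att / r**power)
            vdw = np.minimum(vdw, params.vdw_clamp)
            rec_t = params.record(t)
            desol = params.w_sol * (rec_t.solpar * vol_rec + s_rec * rec_t.vol) * gauss
            maps[t][window] += np.where(mask, vdw + desol, 0.0)
        e_grid[window] += np.where(
            mask, params.w_elec * params.coulomb * atom.charge / (params.epsilon(r) * r), 0.0)
        d_grid[window] += np.where(mask, params.w_sol * params.qsolpar * vol_rec * gauss, 0.0)

    if not touched:
        warnings.warn("no rigid atom within cutoff of any grid node; maps are zero")
    return AffinityMapSet(center, spacing, npts, maps, e_grid, d_grid)


def build_interior_mask(rigid_atoms: list[Atom], center, npts: int, spacing: float,
                        params: FFParameters | None = None,
                        radius_scale: float = 0.85) -> InteriorMask:
    """Classify grid nodes as interior/exterior to the receptor volume.

    A node is candidate-interior when it lies within `radius_scale` times
    the vdW radius of any receptor heavy atom (reduced radii keep narrow
    grooves exterior).  Exterior nodes are those reachable from the box
    boundary by a 6-connected flood fill through non-candidate nodes; the
    complement (atom cores plus enclosed cavities) is interior.  Burial
    depth is the 6-connected graph distance to the nearest exterior node.
    """
    params = params or default_parameters()
    center = np.asarray(center, dtype=float)
    axes = [center[k] - 0.5 * (npts - 1) * spacing + spacing * np.arange(npts)
            for k in range(3)]
    candidate = np.zeros((npts,) * 3, dtype=bool)
    for atom in rigid_atoms:
        if not atom.is_heavy:
            continue
        rad = radius_scale * params.vdw_radius(atom.ad_type)
        sl, local_axes = [], []
        for k in range(3):
            ok = np.nonzero(np.abs(axes[k] - atom.position[k]) <= rad)[0]
            if ok.size == 0:
                break
            sl.append(slice(ok[0], ok[-1] + 1))
            local_axes.append(axes[k][ok[0]:ok[-1] + 1])
        if len(sl) < 3:
            continue
        dx = local_axes[0][:, None, None] - atom.position[0]
        dy = local_axes[1][None, :, None] - atom.position[1]
        dz = local_axes[2][None, None, :] - atom.position[2]
        candidate[tuple(sl)] |= (dx * dx + dy * dy + dz * dz) <= rad * rad

    # the box boundary is exterior by construction
    boundary = np.zeros((npts,) * 3, dtype=bool)
    for k in range(3):
        idx = [slice(None)] * 3
        idx[k] = 0
        boundary[tuple(idx)] = True
        idx[k] = npts - 1
        boundary[tuple(idx)] = True
    seed = boundary & ~candidate
    if not seed.any():
        raise FullyBuriedBoxError("no exterior seed on the box boundary")
    # the box boundary is exterior by convention once a seed exists
    candidate &= ~boundary
    seed = boundary
    exterior = ndimage.binary_propagation(seed, mask=~candidate, structure=_SIX)
    inside = ~exterior
    depth = ndimage.distance_transform_cdt(inside, metric="taxicab").astype(int)
    return InteriorMask(inside, depth)


def postprocess_map(mapset: AffinityMapSet, mask: InteriorMask,
                    e_surface: float = 1.0, k_grad: float = 1.0) -> AffinityMapSet:
    """Replace interior node values with a repulsive potential that grows
    with burial depth.

    Interior nodes are processed in increasing burial depth; each node gets
    max(e_surface, min over already-processed/exterior 6-neighbours) + k_grad.
    This guarantees that every interior node has a 6-neighbour with a
    strictly smaller value, i.e. a steepest-descent walk from any interior
    node reaches the exterior.  Exterior values are untouched.  The
    electrostatic and desolvation grids are zeroed on interior nodes so the
    gradient is carried by the type maps alone.
    """
    if mask.inside.shape != (mapset.npts,) * 3:
        raise ValueError("mask and maps are not congruent")
    inside, depth = mask.inside, mask.depth
    new_maps = {}
    for t, grid in mapset.maps.items():
        new_maps[t] = _repulsive_fill(grid, inside, depth, e_surface, k_grad)
    e_grid = None if mapset.electrostatic is None else np.where(inside, 0.0, mapset.electrostatic)
    d_grid = None if mapset.desolvation is None else np.where(inside, 0.0, mapset.desolvation)
    return AffinityMapSet(mapset.center.copy(), mapset.spacing, mapset.npts,
                          new_maps, e_grid, d_grid)


def _repulsive_fill(grid: np.ndarray, inside: np.ndarray, depth: np.ndarray,
                    e_surface: float, k_grad: float) -> np.ndarray:
    out = grid.astype(float).copy()
    max_d = int(depth.max(initial=0))
    big = np.inf
    for d in range(1, max_d + 1):
        level = inside & (depth == d)
        if not level.any():
            continue
        # values usable as descent targets: exterior nodes and shallower interior
        lower = np.where(inside & (depth >= d), big, out)
        nmin = _shifted_min(lower)   # min over the six face neighbours
        out[level] = np.maximum(e_surface, nmin[level]) + k_grad
    return out


def _shifted_min(arr: np.ndarray) -> np.ndarray:
    big = np.inf
    nmin = np.full_like(arr, big)
    n = arr.shape[0]
    pads = np.pad(arr, 1, constant_values=big)
    core = (slice(1, n + 1),) * 3
    for axis in range(3):
        for shift in (1, -1):
            sl = [slice(1, n + 1)] * 3
            sl[axis] = slice(1 + shift, n + 1 + shift)
            nmin = np.minimum(nmin, pads[tuple(sl)])
    return nmin


def interpolate_grid(grid: np.ndarray, origin, spacing: float, pos) -> np.ndarray:
    """Trilinear interpolation of `grid` at Cartesian positions (n,3)."""
    p = (np.atleast_2d(np.asarray(pos, dtype=float)) - np.asarray(origin)) / spacing
    n = grid.shape[0]
    if np.any(p < -1e-9) or np.any(p > n - 1 + 1e-9):
        raise OutsideBoxError("position outside the map box")
    p = np.clip(p, 0.0, n - 1)
    i0 = np.minimum(p.astype(int), n - 2)
    f = p - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    c000 = grid[ix, iy, iz]
    c100 = grid[ix + 1, iy, iz]
    c010 = grid[ix, iy + 1, iz]
    c001 = grid[ix, iy, iz + 1]
    c110 = grid[ix + 1, iy + 1, iz]
    c101 = grid[ix + 1, iy, iz + 1]
    c011 = grid[ix, iy + 1, iz + 1]
    c111 = grid[ix + 1, iy + 1, iz + 1]
    return (c000 * (1 - fx) * (1 - fy) * (1 - fz) + c100 * fx * (1 - fy) * (1 - fz)
            + c010 * (1 - fx) * fy * (1 - fz) + c001 * (1 - fx) * (1 - fy) * fz
            + c110 * fx * fy * (1 - fz) + c101 * fx * (1 - fy) * fz
            + c011 * (1 - fx) * fy * fz + c111 * fx * fy * fz)


def interpolate(mapset: AffinityMapSet, ad_type: str, pos) -> float:
    """Interpolated affinity of a single probe of `ad_type` (no charge terms)."""
    val = interpolate_grid(mapset.maps[ad_type], mapset.origin, mapset.spacing,
                           np.atleast_2d(pos))
    return float(val[0])


def extract_translational_points(mapset: AffinityMapSet, mask: InteriorMask,
                                 cutoff: float = -0.3, stride: int = 3,
                                 carbon_type: str = "C") -> TranslationalPointSet:
    """Select exterior nodes of the stride-downsampled lattice whose carbon
    affinity is at least as favourable as `cutoff`.

    Falls back (with a warning) to all exterior strided nodes when the filter
    retains nothing.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    grid = mapset.maps[carbon_type]
    npts = mapset.npts
    idx = np.arange(0, npts, stride)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    exterior = ~mask.inside[ii, jj, kk]
    vals = grid[ii, jj, kk]
    keep = exterior & (vals <= cutoff)
    if not keep.any():
        warnings.warn("no translational points pass the affinity cutoff; "
                      "falling back to all exterior strided nodes")
        keep = exterior
    pts = np.stack([ii[keep], jj[keep], kk[keep]], axis=-1) * mapset.spacing + mapset.origin
    return TranslationalPointSet(pts, vals[keep], mapset.spacing)
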