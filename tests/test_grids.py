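"""Affinity maps: computation, interior masking, post-processing,
interpolation and translational-point extraction."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from flexdock.fixtures import make_map_fixture
from flexdock.forcefield import pair_energy
from flexdock.grids import (FullyBuriedBoxError, InteriorMask, OutsideBoxError,
                            build_interior_mask, compute_maps,
                            extract_translational_points, interpolate,
                            interpolate_grid, postprocess_map)
from flexdock.io_formats import AffinityMapSet, Atom


def _atom(pos, ad_type="C", charge=0.0):
    return Atom(1, "C", "UNL", 1, "A", ad_type, np.asarray(pos, dtype=float), charge)


class TestComputeMaps:
    def test_single_atom_matches_pair_energy(self, params):
        mapset = compute_maps([_atom([0, 0, 0])], (0, 0, 0), 9, 0.6, ["C"], params)
        axes = mapset.axis_coords()
        for idx in [(0, 4, 4), (2, 4, 4), (4, 4, 6), (3, 3, 3)]:
            pos = np.array([axes[0][idx[0]], axes[1][idx[1]], axes[2][idx[2]]])
            r = np.linalg.norm(pos)
            expected = pair_energy("C", "C", 0, 0, r, params).total if r <= 8 else 0.0
            assert mapset.maps["C"][idx] == pytest.approx(expected, abs=1e-9)

    def test_empty_probe_list_still_builds_charge_grids(self, params):
        mapset = compute_maps([_atom([0, 0, 0], charge=0.3)], (0, 0, 0), 5, 0.5,
                              [], params)
        assert mapset.maps == {}
        assert mapset.electrostatic is not None and np.any(mapset.electrostatic != 0)
        assert mapset.desolvation is not None and np.any(mapset.desolvation > 0)

    def test_two_atom_additivity(self, params):
        a1, a2 = _atom([-1.0, 0, 0]), _atom([1.2, 0.4, 0])
        both = compute_maps([a1, a2], (0, 0, 0), 7, 0.6, ["C"], params)
        single = [compute_maps([a], (0, 0, 0), 7, 0.6, ["C"], params) for a in (a1, a2)]
        np.testing.assert_allclose(both.maps["C"],
                                   single[0].maps["C"] + single[1].maps["C"],
                                   atol=1e-9)

    def test_translation_invariance(self, params):
        shift = np.array([3.3, -1.1, 0.7])
        m0 = compute_maps([_atom([0.2, 0.1, -0.3])], (0, 0, 0), 7, 0.5, ["C"], params)
        m1 = compute_maps([_atom(np.array([0.2, 0.1, -0.3]) + shift)], shift,
                          7, 0.5, ["C"], params)
        np.testing.assert_allclose(m0.maps["C"], m1.maps["C"], atol=1e-9)

    def test_vacuum_warns_and_zeroes(self, params):
        with pytest.warns(UserWarning, match="maps are zero"):
            mapset = compute_maps([], (0, 0, 0), 5, 0.5, ["C"], params)
        assert not np.any(mapset.maps["C"])


class TestInteriorMask:
    def test_empty_receptor_all_exterior(self, params):
        mask = build_interior_mask([], (0, 0, 0), 7, 0.5, params)
        assert not mask.inside.any()
        assert not mask.depth.any()

    def test_single_atom_ball(self, params):
        mask = build_interior_mask([_atom([0, 0, 0])], (0, 0, 0), 9, 0.4, params)
        c = 4
        assert mask.inside[c, c, c]
        # all box-boundary nodes are exterior
        for face in (mask.inside[0], mask.inside[-1], mask.inside[:, 0],
                     mask.inside[:, -1], mask.inside[:, :, 0], mask.inside[:, :, -1]):
            assert not face.any()
        # the interior forms a ball: radius 0.85 * 2.0 A
        axes = np.arange(9) * 0.4 - 1.6
        X, Y, Z = np.meshgrid(axes, axes, axes, indexing="ij")
        expected = (X**2 + Y**2 + Z**2) <= (0.85 * 2.0)**2
        expected[0] = expected[-1] = False
        expected[:, 0] = expected[:, -1] = False
        expected[:, :, 0] = expected[:, :, -1] = False
        np.testing.assert_array_equal(mask.inside, expected)

    def test_hollow_shell_cavity_is_interior(self):
        """Nodes enclosed by a sealed shell are unreachable from the box
        boundary, so the flood fill classifies them interior."""
        mapset, mask = make_map_fixture("hollow-shell", npts=15)
        c = 7
        assert mask.inside[c, c, c]
        assert mask.depth[c, c, c] >= 1

    def test_pocket_cavity_is_exterior(self):
        mapset, mask = make_map_fixture("pocket", npts=15)
        c = 7
        assert not mask.inside[c, c, c]

    def test_fully_buried_box_raises(self, params):
        giant = _atom([0, 0, 0], ad_type="C")
        with pytest.raises(FullyBuriedBoxError):
            build_interior_mask([giant], (0, 0, 0), 3, 0.1, params)


def _steepest_descent_reaches_exterior(grid, mask):
    """Walk downhill (6-neighbour steepest descent) from every interior node;
    the walk must reach an exterior node."""
    npts = grid.shape[0]
    shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start in zip(*np.nonzero(mask.inside)):
        node = start
        for _ in range(npts**3):
            if not mask.inside[node]:
                break
            best, best_val = None, grid[node]
            for dx, dy, dz in shifts:
                nb = (node[0] + dx, node[1] + dy, node[2] + dz)
                if all(0 <= v < npts for v in nb) and grid[nb] < best_val:
                    best, best_val = nb, grid[nb]
            if best is None:
                return False    # stuck at an interior local minimum
            node = best
        else:
            return False
    return True


class TestPostprocess:
    def test_all_exterior_identity(self):
        mapset, mask = make_map_fixture("uniform", npts=7)
        out = postprocess_map(mapset, mask)
        np.testing.assert_array_equal(out.maps["C"], mapset.maps["C"])

    def test_depth_formula_on_slab(self):
        """With benign exterior values, an interior node at burial depth d
        gets E_surface + d * k_grad (depth 3 -> 4.0 kcal/mol)."""
        npts = 9
        grid = np.full((npts,) * 3, -1.0)
        inside = np.zeros((npts,) * 3, dtype=bool)
        inside[2:7, 2:7, 2:7] = True
        from scipy import ndimage
        depth = ndimage.distance_transform_cdt(inside, metric="taxicab").astype(int)
        mask = InteriorMask(inside, depth)
        mapset = AffinityMapSet(np.zeros(3), 0.5, npts, {"C": grid})
        out = postprocess_map(mapset, mask)
        assert depth[4, 4, 4] == 3
        assert out.maps["C"][4, 4, 4] == pytest.approx(4.0)
        assert out.maps["C"][2, 4, 4] == pytest.approx(2.0)   # depth 1
        # exterior untouched
        np.testing.assert_array_equal(out.maps["C"][~inside], grid[~inside])

    @pytest.mark.parametrize("shape", ["hollow-shell", "pocket"])
    def test_no_interior_local_minima(self, shape):
        mapset, mask = make_map_fixture(shape, npts=15)
        out = postprocess_map(mapset, mask)
        assert _steepest_descent_reaches_exterior(out.maps["C"], mask)

    def test_every_interior_node_has_smaller_neighbour(self):
        mapset, mask = make_map_fixture("hollow-shell", npts=15)
        out = postprocess_map(mapset, mask)
        grid = out.maps["C"]
        npts = grid.shape[0]
        padded = np.pad(grid, 1, constant_values=np.inf)
        nmin = np.full_like(grid, np.inf)
        for axis in range(3):
            for shift in (1, -1):
                sl = [slice(1, npts + 1)] * 3
                sl[axis] = slice(1 + shift, npts + 1 + shift)
                nmin = np.minimum(nmin, padded[tuple(sl)])
        assert np.all(nmin[mask.inside] < grid[mask.inside])


class TestInterpolation:
    def test_node_identity(self, rng):
        grid = rng.normal(size=(4, 4, 4))
        origin = np.array([-1.0, 0.0, 2.0])
        vals = interpolate_grid(grid, origin, 0.5,
                                origin + 0.5 * np.array([2, 1, 3], dtype=float))
        assert vals[0] == pytest.approx(grid[2, 1, 3], rel=1e-12)

    def test_cell_center_is_corner_mean(self, rng):
        grid = rng.normal(size=(3, 3, 3))
        origin = np.zeros(3)
        center = origin + 0.25 * np.ones(3)    # middle of the first cell
        val = interpolate_grid(grid, origin, 0.5, center[None])[0]
        assert val == pytest.approx(grid[:2, :2, :2].mean(), rel=1e-12)

    def test_matches_scipy_regular_grid(self, rng):
        grid = rng.normal(size=(4, 4, 4))
        origin, spacing = np.array([1.0, -2.0, 0.0]), 0.7
        axes = [origin[k] + spacing * np.arange(4) for k in range(3)]
        oracle = RegularGridInterpolator(axes, grid)
        pts = origin + spacing * 3 * rng.random((50, 3))
        np.testing.assert_allclose(interpolate_grid(grid, origin, spacing, pts),
                                   oracle(pts), rtol=1e-10)

    def test_outside_raises(self, rng):
        grid = rng.normal(size=(4, 4, 4))
        with pytest.raises(OutsideBoxError):
            interpolate_grid(grid, np.zeros(3), 0.5, np.array([[5.0, 0, 0]]))

    def test_mapset_interpolate_helper(self):
        mapset, _ = make_map_fixture("uniform", npts=7)
        assert interpolate(mapset, "C", [0.1, 0.2, -0.3]) == pytest.approx(-1.0)


class TestTranslationalPoints:
    def test_uniform_lattice_count(self):
        mapset, mask = make_map_fixture("uniform", npts=7)
        tp = extract_translational_points(mapset, mask, cutoff=-0.3, stride=3)
        assert len(tp) == 27    # indices {0, 3, 6} on each axis

    def test_cutoff_filter_with_fallback(self):
        mapset, mask = make_map_fixture("uniform", npts=7)
        mapset.maps["C"][:] = -0.2
        with pytest.warns(UserWarning, match="falling back"):
            tp = extract_translational_points(mapset, mask, cutoff=-0.3, stride=3)
        assert len(tp) == 27    # fallback: all exterior strided nodes

    def test_matches_bruteforce_filter(self):
        mapset, mask = make_map_fixture("pocket", npts=15, seed=2)
        tp = extract_translational_points(mapset, mask, cutoff=-0.3, stride=3)
        expected = set()
        for i in range(0, 15, 3):
            for j in range(0, 15, 3):
                for k in range(0, 15, 3):
                    if not mask.inside[i, j, k] and mapset.maps["C"][i, j, k] <= -0.3:
                        expected.add((i, j, k))
        got = {tuple(np.round((p - mapset.origin) / mapset.spacing).astype(int))
               for p in tp.points}
        assert got == expected
        assert np.all(tp.affinities <= -0.3)

    def test_monotone_in_cutoff(self):
        mapset, mask = make_map_fixture("pocket", npts=15, seed=2)
        sets = []
        for cutoff in (-0.1, -0.3, -0.5):
            tp = extract_translational_points(mapset, mask, cutoff=cutoff, stride=3)
            sets.append({tuple(p) for p in np.round(tp.points, 6)})
        assert sets[2] <= sets[1] <= sets[0]

    def test_count_bound(self):
        mapset, mask = make_map_fixture("uniform", npts=7)
        tp = extract_translational_points(mapset, mask, cutoff=-0.3, stride=3)
        assert len(tp) <= int(np.ceil(7 / 3))**3
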