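"""Hungarian RMSD, ranking, clash detection, flexible-residue selection,
contact recovery and rotamer-change counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexdock.analysis import (circular_difference, contact_recovery,
                               detect_clashes, hungarian_rmsd, rank_solutions,
                               rotamer_change_count, select_flexible_residues)
from flexdock.fixtures import make_serine
from flexdock.forcefield import ScoreBreakdown
from flexdock.ga import Solution, index_rmsd
from flexdock.conformation import Individual
from flexdock.io_formats import Atom


class TestHungarianRMSD:
    def test_identity(self, rng):
        c = rng.normal(size=(5, 3))
        t = ["C", "C", "OA", "N", "C"]
        assert hungarian_rmsd(c, t, c, t) == pytest.approx(0.0, abs=1e-12)

    def test_swapped_equivalent_atoms(self):
        """Exchanging two same-type atoms is invisible to the Hungarian
        metric but not to the index-matched one."""
        a = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        b = a[::-1]
        assert hungarian_rmsd(a, ["C", "C"], b, ["C", "C"]) == pytest.approx(0.0)
        assert index_rmsd(a, b) == pytest.approx(3.0)

    def test_matches_exhaustive_permutation_minimum(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            types = [("C", "OA")[int(v)] for v in rng.integers(0, 2, size=n)]
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            got = hungarian_rmsd(a, types, b, types)
            by_type = {}
            for i, t in enumerate(types):
                by_type.setdefault(t, []).append(i)
            best = np.inf
            blocks = list(by_type.values())
            for perms in itertools.product(*[itertools.permutations(ix) for ix in blocks]):
                sigma = np.empty(n, dtype=int)
                for ix, perm in zip(blocks, perms):
                    for src, dst in zip(ix, perm):
                        sigma[src] = dst
                d = a - b[sigma]
                best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
            assert got == pytest.approx(best, abs=1e-10)

    def test_type_mismatch_raises(self):
        with pytest.raises(ValueError, match="multisets differ"):
            hungarian_rmsd(np.zeros((2, 3)), ["C", "C"], np.zeros((2, 3)), ["C", "N"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_never_exceeds_index_rmsd_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        types = ["C", "C", "C", "OA", "OA"]
        a, b = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
        h = hungarian_rmsd(a, types, b, types)
        assert h <= index_rmsd(a, b) + 1e-12
        assert h == pytest.approx(hungarian_rmsd(b, types, a, types), abs=1e-10)


def _solution(total, coords):
    ind = Individual(np.zeros(7))
    score = ScoreBreakdown(e_ll=total, e_lrr=0.0)
    ind.score = score
    return Solution(ind, score, (np.atleast_2d(coords), None), 1, 0, 0)


class _FakeResult:
    def __init__(self, solutions):
        self.solutions = solutions


class TestRankSolutions:
    def test_rank_one(self):
        ref = np.array([[0.0, 0, 0]])
        res = _FakeResult([_solution(-8.0, [0.1, 0, 0]),
                           _solution(-7.0, [5.0, 0, 0])])
        rank, delta = rank_solutions(res, ref, ["C"], rmsd_cutoff=2.0)
        assert rank == 1
        assert delta == pytest.approx(-1.0)

    def test_no_correct_solution(self):
        ref = np.array([[0.0, 0, 0]])
        res = _FakeResult([_solution(-8.0, [9.0, 0, 0])])
        rank, delta = rank_solutions(res, ref, ["C"], rmsd_cutoff=2.0)
        assert rank is None and delta is None

    def test_false_positives_counted(self):
        """A correct pose at position 3 means two better-scoring false
        positives were reported."""
        ref = np.array([[0.0, 0, 0]])
        res = _FakeResult([_solution(-9.0, [7.0, 0, 0]),
                           _solution(-8.5, [6.0, 0, 0]),
                           _solution(-8.0, [0.2, 0, 0])])
        rank, delta = rank_solutions(res, ref, ["C"], rmsd_cutoff=2.0)
        assert rank == 3
        assert delta == pytest.approx(-8.0 - (-9.0))


class TestClashes:
    def test_threshold_rule(self, params):
        # two carbons: vdW radii 2.0 + 2.0 -> clash below 2.0 A
        far = detect_clashes(np.array([[0.0, 0, 0]]), ["C"],
                             np.array([[3.4, 0, 0]]), ["C"], params)
        close = detect_clashes(np.array([[0.0, 0, 0]]), ["C"],
                               np.array([[1.9, 0, 0]]), ["C"], params)
        assert far == []
        assert close == [(0, 0)]

    def test_hydrogens_ignored(self, params):
        pairs = detect_clashes(np.array([[0.0, 0, 0]]), ["HD"],
                               np.array([[0.1, 0, 0]]), ["C"], params)
        assert pairs == []

    def test_matches_double_loop(self, params, rng):
        lig = rng.normal(scale=2, size=(6, 3))
        rec = rng.normal(scale=2, size=(10, 3))
        lt = ["C", "OA", "C", "N", "C", "C"]
        rt = ["C"] * 5 + ["OA"] * 5
        got = set(detect_clashes(lig, lt, rec, rt, params))
        expected = set()
        for i in range(6):
            for j in range(10):
                thr = 0.5 * (params.vdw_radius(lt[i]) + params.vdw_radius(rt[j]))
                if np.linalg.norm(lig[i] - rec[j]) < thr:
                    expected.add((i, j))
        assert got == expected


class TestFlexibleResidueSelection:
    def _receptor(self):
        ser = make_serine([3.0, 0.0, 0.0], [1.0, 0.3, 0.2], chi1=60.0, resnum=5)
        gly = [Atom(50, "CA", "GLY", 6, "A", "C", np.array([3.5, 0, 0]), 0.0)]
        return ser + gly

    def test_side_chain_within_cutoff_selected(self):
        atoms = self._receptor()
        og = next(a.position for a in atoms if a.name == "OG")
        lig = np.array([og + [0.0, 0.0, 3.9]])
        assert select_flexible_residues(lig, ["C"], atoms, 4.0) == ["SER5"]

    def test_cb_contact_alone_not_selected(self):
        atoms = self._receptor()
        cb = next(a.position for a in atoms if a.name == "CB")
        og = next(a.position for a in atoms if a.name == "OG")
        # ligand near CB but > 4 A from every beyond-CB heavy atom
        probe = cb + 3.9 * (cb - og) / np.linalg.norm(cb - og)
        assert np.linalg.norm(probe - og) > 4.0
        assert select_flexible_residues(np.array([probe]), ["C"], atoms, 4.0) == []

    def test_monotone_in_distance(self, rng):
        atoms = self._receptor()
        lig = rng.normal(scale=4, size=(3, 3))
        prev = set()
        for d in (2.0, 4.0, 8.0, 16.0):
            cur = set(select_flexible_residues(lig, ["C", "C", "C"], atoms, d))
            assert prev <= cur
            prev = cur

    def test_matches_exhaustive_scan(self, rng):
        atoms = self._receptor()
        lig = rng.normal(scale=3, size=(4, 3))
        got = set(select_flexible_residues(lig, ["C"] * 4, atoms, 4.0))
        expected = set()
        backbone = {"N", "CA", "C", "O", "OXT", "CB", "H", "HN", "HA"}
        for a in atoms:
            if a.residue_name in ("GLY", "ALA") or a.name in backbone or not a.is_heavy:
                continue
            if np.min(np.linalg.norm(lig - a.position, axis=1)) <= 4.0:
                expected.add(f"{a.residue_name}{a.residue_number}")
        assert got == expected


class TestContactRecovery:
    def _complex(self, rng):
        lig = rng.normal(scale=2, size=(4, 3))
        types = ["C", "C", "OA", "N"]
        res_atoms = {"SER5": (rng.normal(scale=2, size=(2, 3)), ["OA", "HD"]),
                     "LYS9": (rng.normal(scale=2, size=(4, 3)), ["C", "C", "C", "N"])}
        return lig, types, res_atoms

    def test_identity_full_recovery(self, rng):
        lig, types, res = self._complex(rng)
        docked_res = {k: v[0] for k, v in res.items()}
        rep = contact_recovery(lig, types, res, lig, docked_res, threshold=5.0)
        assert rep.recovery_percent == pytest.approx(100.0)
        assert all(v["novel"] == 0 for v in rep.per_residue.values())

    def test_displaced_residue_loses_contacts(self, rng):
        lig, types, res = self._complex(rng)
        docked_res = {k: v[0].copy() for k, v in res.items()}
        docked_res["SER5"] = docked_res["SER5"] + 100.0   # rotated far away
        rep = contact_recovery(lig, types, res, lig, docked_res, threshold=5.0)
        assert rep.per_residue["SER5"]["recovered"] == 0
        assert rep.per_residue["LYS9"]["recovered"] == rep.per_residue["LYS9"]["reference"]

    def test_symmetric_ligand_relabeling_invariant(self, rng):
        """Swapping two same-type ligand atoms between holo and docked poses
        does not change the recovery percentage."""
        lig, types, res = self._complex(rng)
        docked_res = {k: v[0] for k, v in res.items()}
        swapped = lig.copy()
        swapped[[0, 1]] = swapped[[1, 0]]   # both type C
        r0 = contact_recovery(lig, types, res, lig, docked_res)
        r1 = contact_recovery(lig, types, res, swapped, docked_res)
        assert r1.recovery_percent == pytest.approx(r0.recovery_percent)

    def test_hand_counted_fixture(self):
        lig = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        res = {"SER1": (np.array([[3.0, 0, 0], [10.0, 3.0, 0]]), ["OA", "HD"])}
        docked = {"SER1": np.array([[3.0, 0, 0], [50.0, 0, 0]])}
        rep = contact_recovery(lig, ["C", "C"], res, lig, docked, threshold=5.0)
        # reference pairs: lig0-OA (3 A), lig1-HD (3 A); recovered: lig0-OA only
        assert rep.per_residue["SER1"]["reference"] == 2
        assert rep.per_residue["SER1"]["recovered"] == 1
        assert rep.recovery_percent == pytest.approx(50.0)


class TestRotamerChange:
    def test_no_change(self):
        ref = [np.array([60.0, 180.0]), np.array([-65.0])]
        assert rotamer_change_count(ref, [c.copy() for c in ref]) == 0

    def test_wrap_handling(self):
        ref = [np.array([-179.0])]
        cur = [np.array([0.0])]       # circular difference 179
        assert rotamer_change_count(ref, cur) == 1
        cur = [np.array([179.0])]     # circular difference 2
        assert rotamer_change_count(ref, cur) == 0

    def test_boundary_inclusive(self):
        # raw difference 310 degrees wraps to exactly 50 -> counts as changed
        assert circular_difference(0.0, 310.0) == pytest.approx(50.0)
        assert rotamer_change_count([np.array([0.0])], [np.array([310.0])]) == 1

    def test_incongruent_sets_rejected(self):
        with pytest.raises(ValueError):
            rotamer_change_count([np.array([0.0])], [])
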