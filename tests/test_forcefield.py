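"""Pairwise energy function, pair lists and score assembly."""

import itertools

import numpy as np
import pytest

from flexdock.fixtures import (make_butane_ligand, make_pocket_system,
                               make_single_atom_ligand)
from flexdock.forcefield import (build_pair_list, pair_energy,
                                 set_receptor_weight, Scorer)
from flexdock.grids import compute_maps
from flexdock.io_formats import Atom, Branch, LigandTopology
from flexdock.params import UnknownAtomTypeError


class TestPairEnergy:
    def test_vdw_minimum_at_equilibrium(self, params):
        """The 12-6 term reaches -w_vdw * eps at r = Rij with zero slope."""
        rec = params.record("C")
        r_eq = rec.Rii
        pe = pair_energy("C", "C", 0.0, 0.0, r_eq, params)
        assert pe.vdw == pytest.approx(-params.w_vdw * rec.epsii, rel=1e-12)
        h = 1e-5
        slope = (pair_energy("C", "C", 0, 0, r_eq + h, params).vdw
                 - pair_energy("C", "C", 0, 0, r_eq - h, params).vdw) / (2 * h)
        assert abs(slope) < 1e-6

    def test_zero_charge_zero_electrostatics(self, params):
        assert pair_energy("C", "OA", 0.0, 0.35, 3.0, params).elec == 0.0
        assert pair_energy("C", "OA", -0.2, 0.0, 3.0, params).elec == 0.0

    @pytest.mark.parametrize("ti,tj,qi,qj,r", [
        ("C", "C", 0.0, 0.0, 4.0),
        ("C", "OA", 0.2, -0.4, 3.1),
        ("HD", "OA", 0.21, -0.39, 1.9),    # hydrogen-bonding pair
        ("N", "SA", -0.1, 0.05, 2.5),
    ])
    def test_against_independent_transcription(self, params, ti, tj, qi, qj, r):
        """Term-by-term re-transcription of the energy model, written
        independently of the vectorized implementation."""
        ri, rj = params.record(ti), params.record(tj)
        hb = (ri.is_donor_h and rj.is_acceptor) or (rj.is_donor_h and ri.is_acceptor)
        if hb:
            acc = rj if rj.is_acceptor else ri
            c = 5.0 * acc.epsij_hb * acc.Rij_hb**12
            d = 6.0 * acc.epsij_hb * acc.Rij_hb**10
            vdw = params.w_hbond * (c / r**12 - d / r**10)
        else:
            req = (ri.Rii + rj.Rii) / 2.0
            eps = np.sqrt(ri.epsii * rj.epsii)
            vdw = params.w_vdw * (eps * req**12 / r**12 - 2 * eps * req**6 / r**6)
        B = params.diel_eps0 - params.diel_A
        eps_r = params.diel_A + B / (1 + params.diel_k * np.exp(-params.diel_lambda * B * r))
        elec = params.w_elec * 332.06363 * qi * qj / (eps_r * r)
        si = ri.solpar + params.qsolpar * abs(qi)
        sj = rj.solpar + params.qsolpar * abs(qj)
        desolv = params.w_sol * (si * rj.vol + sj * ri.vol) * np.exp(-r**2 / (2 * 3.6**2))
        pe = pair_energy(ti, tj, qi, qj, r, params)
        assert pe.vdw == pytest.approx(vdw, rel=1e-12)
        assert pe.elec == pytest.approx(elec, rel=1e-12)
        assert pe.desolv == pytest.approx(desolv, rel=1e-12)

    def test_clash_ceiling(self, params):
        assert pair_energy("C", "C", 0, 0, 0.05, params).vdw == params.vdw_clamp

    def test_unparameterized_type(self, params):
        with pytest.raises(UnknownAtomTypeError):
            pair_energy("C", "QQ", 0, 0, 3.0, params)

    def test_decay_and_tail_monotonicity(self, params):
        """All terms vanish at long range; the vdW term decays monotonically
        beyond twice the equilibrium distance."""
        far = pair_energy("C", "OA", 0.3, -0.3, 60.0, params)
        assert abs(far.vdw) < 1e-8 and abs(far.elec) < 1e-3 and abs(far.desolv) < 1e-12
        r_eq = 0.5 * (params.record("C").Rii + params.record("OA").Rii)
        rs = np.linspace(2 * r_eq, 5 * r_eq, 50)
        vals = [pair_energy("C", "OA", 0, 0, r, params).vdw for r in rs]
        assert np.all(np.diff(vals) > 0)   # rising toward zero from below
        assert vals[0] < 0


class TestReceptorWeight:
    @pytest.mark.parametrize("nfs,expected", [(12, 1 / 12), (1, 1.0), (4, 0.25)])
    def test_one_over_nfs(self, nfs, expected):
        assert set_receptor_weight(nfs) == pytest.approx(expected)

    def test_override_reproduces_unweighted(self):
        assert set_receptor_weight(12, override=1.0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            set_receptor_weight(-1)


def _branched_octane():
    """8 heavy atoms, two rotatable bonds, one branch point."""
    from flexdock.geom import place_atom
    c = [np.array([0.0, 0.0, 0.0]), np.array([1.53, 0.0, 0.0])]
    c.append(place_atom(c[0] + [0, 1, 0], c[0], c[1], 1.53, 112.0, 60.0))
    c.append(place_atom(c[0], c[1], c[2], 1.53, 112.0, 180.0))
    c.append(place_atom(c[1], c[2], c[3], 1.53, 112.0, 180.0))
    c.append(place_atom(c[1], c[2], c[3], 1.53, 112.0, 60.0))
    c.append(place_atom(c[2], c[3], c[4], 1.53, 112.0, -65.0))
    c.append(place_atom(c[3], c[4], c[6], 1.53, 112.0, 170.0))
    atoms = [Atom(i + 1, f"C{i+1}", "LIG", 1, "L", "C", p, 0.01 * (-1) ** i)
             for i, p in enumerate(c)]
    branches = [
        Branch(parent=2, child=3, moved=frozenset({3, 4, 5, 6, 7})),
        Branch(parent=3, child=4, moved=frozenset({4, 6, 7})),
    ]
    return LigandTopology(atoms, root_atom=0, branches=branches, torsdof=2)


class TestPairList:
    def test_butane_rotatable_14_included(self):
        lig = make_butane_ligand()
        pl = build_pair_list(lig)
        assert pl.pairs_of("L-L") == [(0, 3)]

    def test_butane_rigid_14_excluded(self):
        lig = make_butane_ligand()
        rigid = LigandTopology([a.copy() for a in lig.atoms], 0, [], 0)
        pl = build_pair_list(rigid)
        assert pl.pairs_of("L-L") == []
        assert any(why == "rigid 1-4" for *_, why in pl.excluded)

    def test_branched_fixture_matches_bruteforce(self):
        """Pair list equals an exhaustive scan excluding graph-distance <= 2
        pairs and 1-4 pairs without a rotatable central bond."""
        lig = _branched_octane()
        pl = build_pair_list(lig)
        bonds = set(map(frozenset, lig.bonds))
        rot = lig.rotatable_bond_set()
        n = len(lig.atoms)
        adj = {i: set() for i in range(n)}
        for b in bonds:
            i, j = tuple(b)
            adj[i].add(j)
            adj[j].add(i)

        def dist(i, j):
            seen, frontier, d = {i}, {i}, 0
            while frontier:
                if j in frontier:
                    return d
                d += 1
                frontier = {v for u in frontier for v in adj[u]} - seen
                seen |= frontier
            return np.inf

        expected = set()
        for i, j in itertools.combinations(range(n), 2):
            d = dist(i, j)
            if d <= 2:
                continue
            if d == 3:
                mediated = any(frozenset((a, b)) in rot
                               for a in adj[i] for b in adj[j]
                               if frozenset((a, b)) in bonds and a != j and b != i)
                if not mediated:
                    continue
            expected.add((i, j))
        assert set(pl.pairs_of("L-L")) == expected

    def test_disconnected_ligand_raises(self):
        atoms = [Atom(1, "C1", "LIG", 1, "L", "C", np.zeros(3), 0.0),
                 Atom(2, "C2", "LIG", 1, "L", "C", np.array([9.0, 0, 0]), 0.0)]
        lig = LigandTopology(atoms, 0, [], 0)
        with pytest.raises(ValueError, match="disconnected"):
            build_pair_list(lig)

    def test_flexible_residue_categories(self, apo_clash):
        pl = build_pair_list(apo_clash.ligand, apo_clash.receptor)
        # single-atom ligand vs OG and HG
        assert len(pl.pairs_of("L-FR")) == 2
        # OG-HG is a 1-2 pair, so no same-residue FR-FR pairs survive
        assert pl.pairs_of("FR-FR") == []
        assert pl.fr_rigid_exclusions   # bonded side-chain/backbone pairs


class TestScoring:
    def test_rigid_breakdown_only_first_two_terms(self, open_pocket):
        scorer = open_pocket.scorer()
        lig = open_pocket.ligand.coords + np.array([0.3, -0.2, 0.4])
        s = scorer.score(lig)
        assert s.e_lfr == 0.0 and s.e_frfr == 0.0 and s.e_frrr == 0.0
        assert s.e_lrr != 0.0

    def test_determinism(self, apo_clash):
        from flexdock.conformation import PhenotypeBuilder, Individual
        b = PhenotypeBuilder(apo_clash.ligand, apo_clash.receptor)
        g = b.initial_genotype()
        g[:3] = (0.4, -0.3, 0.9)
        lig, fr = b.build(Individual(g))
        s1 = apo_clash.scorer().score(lig, fr)
        s2 = apo_clash.scorer().score(lig.copy(), fr.copy())
        assert s1 == s2   # bit-identical breakdown

    def test_total_identity(self, two_flex, rng):
        """total = E_LL + E_LRR + E_LFR + w_rec (E_FRFR + E_FRRR) on random
        phenotypes."""
        from flexdock.conformation import PhenotypeBuilder, Individual
        b = PhenotypeBuilder(two_flex.ligand, two_flex.receptor)
        scorer = two_flex.scorer()
        for _ in range(20):
            g = b.initial_genotype()
            g[:3] += rng.normal(scale=1.0, size=3)
            g[7] = rng.uniform(-180, 180)
            g[8] = rng.uniform(-180, 180)
            lig, fr = b.build(Individual(g))
            s = scorer.score(lig, fr)
            assert s.total == pytest.approx(
                s.e_ll + s.e_lrr + s.e_lfr + s.w_rec * (s.e_frfr + s.e_frrr), rel=1e-12)

    def test_map_interpolation_matches_explicit_sum_on_nodes(self, params, rng):
        """E_L-RR interpolated at grid nodes equals the direct pairwise sum
        against the rigid atoms the maps were built from (raw maps)."""
        system = make_pocket_system("open-pocket", seed=4, build=False)
        rigid = system.receptor.rigid_atoms
        mapset = compute_maps(rigid, system.center, system.npts, system.spacing,
                              ["C"], params)
        lig = make_single_atom_ligand("C", charge=0.17)
        scorer = Scorer(lig, system.receptor, mapset, params=params)
        axes = mapset.axis_coords()
        for _ in range(200):
            idx = rng.integers(0, system.npts, size=3)
            pos = np.array([axes[0][idx[0]], axes[1][idx[1]], axes[2][idx[2]]])
            e_map = scorer.score(pos[None, :]).e_lrr
            e_explicit = 0.0
            for a in rigid:
                r = np.linalg.norm(pos - a.position)
                if 0 < r <= params.nb_cutoff:
                    e_explicit += pair_energy("C", a.ad_type, 0.17, a.charge,
                                              r, params).total
            assert e_map == pytest.approx(e_explicit, abs=1e-6)

    def test_outside_box_penalty(self, open_pocket):
        scorer = open_pocket.scorer()
        inside = scorer.score(np.zeros((1, 3)))
        outside = scorer.score(np.array([[40.0, 0.0, 0.0]]))
        assert outside.total > inside.total + 100.0
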