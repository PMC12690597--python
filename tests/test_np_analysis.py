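"""Nanoparticle detection and per-NP observables against closed forms."""

import math

import numpy as np
import pytest

from polyplexmd.model_core import ReducedUnitSystem, Species
from polyplexmd.np_analysis import (analyze_frame, find_nanoparticles,
                                    gyration_metrics, hydrodynamic_radius,
                                    manning_fraction, manning_theory,
                                    np_charge, radius_of_gyration_direct,
                                    unwrap_cluster, zeta_potential)


def straight_chain(start, direction, n, spacing=1.0):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    return np.asarray(start, float) + spacing * direction * np.arange(n)[:, None]


class TestClustering:
    @pytest.mark.parametrize("gap, expected_nps", [(3.4, 1), (3.6, 2)])
    def test_linking_cutoff(self, make_frame, gap, expected_nps):
        a = straight_chain([5, 5, 5], [1, 0, 0], 5)
        b = a + [0, gap, 0]
        frame = make_frame(30.0, chains=[(Species.RNA, a), (Species.PEI, b)])
        assert len(find_nanoparticles(frame)) == expected_nps

    def test_transitive_linkage(self, make_frame):
        a = straight_chain([5, 5, 5], [1, 0, 0], 4)
        b = a + [0, 3.0, 0]
        c = a + [0, 6.0, 0]   # 3 sigma from b, 6 from a
        frame = make_frame(40.0, chains=[(Species.RNA, a), (Species.PEI, b),
                                         (Species.PEI, c)])
        nps = find_nanoparticles(frame)
        assert len(nps) == 1
        assert nps[0].n_chains == 3
        assert nps[0].n_rna_chains == 1
        assert nps[0].n_pei_chains == 2

    def test_isolated_chain_is_single_chain_np(self, make_frame):
        frame = make_frame(30.0, chains=[(Species.RNA,
                                          straight_chain([5, 5, 5], [1, 0, 0], 6))])
        nps = find_nanoparticles(frame)
        assert len(nps) == 1 and nps[0].n_chains == 1

    def test_ion_attachment(self, make_frame):
        chain = straight_chain([10, 10, 10], [1, 0, 0], 5)
        frame = make_frame(30.0, chains=[(Species.RNA, chain)],
                           ions=[(Species.COUNTERION, [[10, 12, 10]]),   # 2.0
                                 (Species.COUNTERION, [[10, 18, 10]])])  # 8.0
        nps = find_nanoparticles(frame)
        assert len(nps[0].attached_ion_indices) == 1

    def test_enumeration_order_invariance(self, make_frame):
        a = straight_chain([3, 3, 3], [1, 0, 0], 5)
        b = a + [0, 2.0, 0]
        c = straight_chain([15, 15, 15], [0, 1, 0], 5)
        f1 = make_frame(30.0, chains=[(Species.RNA, a), (Species.PEI, b),
                                      (Species.RNA, c)])
        f2 = make_frame(30.0, chains=[(Species.RNA, c), (Species.PEI, b),
                                      (Species.RNA, a)])
        sizes1 = sorted(p.n_chains for p in find_nanoparticles(f1))
        sizes2 = sorted(p.n_chains for p in find_nanoparticles(f2))
        assert sizes1 == sizes2 == [1, 2]

    def test_translation_across_boundary_invariance(self, make_frame):
        """Clusters and their metrics survive wrapping through the box."""
        a = straight_chain([5, 5, 5], [1, 0, 0], 6)
        b = a + [0, 2.0, 0]
        f_ref = make_frame(20.0, chains=[(Species.RNA, a), (Species.PEI, b)])
        nps_ref = find_nanoparticles(f_ref)
        _, rg_ref, k2_ref = gyration_metrics(nps_ref[0], f_ref)
        rh_ref = hydrodynamic_radius(nps_ref[0], f_ref)
        shift = np.array([17.3, 19.1, 11.8])  # pushes cluster across edges
        f_sh = make_frame(20.0, chains=[(Species.RNA, a + shift),
                                        (Species.PEI, b + shift)])
        nps_sh = find_nanoparticles(f_sh)
        assert len(nps_sh) == len(nps_ref) == 1
        _, rg_sh, k2_sh = gyration_metrics(nps_sh[0], f_sh)
        assert rg_sh == pytest.approx(rg_ref, rel=1e-10)
        assert k2_sh == pytest.approx(k2_ref, rel=1e-10)
        assert hydrodynamic_radius(nps_sh[0], f_sh) == pytest.approx(
            rh_ref, rel=1e-10)


class TestGyration:
    def test_collinear_beads_have_kappa2_one(self, make_frame):
        frame = make_frame(50.0, chains=[(Species.RNA,
                                          straight_chain([10, 10, 10], [1, 1, 1], 10))])
        np_ = find_nanoparticles(frame)[0]
        eig, r_g, kappa2 = gyration_metrics(np_, frame)
        assert kappa2 == pytest.approx(1.0, abs=1e-12)
        assert eig[1] == pytest.approx(0.0, abs=1e-12)

    def test_cube_vertices_have_kappa2_zero(self, make_frame):
        cube = np.array([(x, y, z) for x in (0, 1) for y in (0, 1)
                         for z in (0, 1)], dtype=float) + 10.0
        # degenerate gyration tensor: treat the 8 vertices as one chain
        frame = make_frame(50.0, chains=[(Species.RNA, cube)])
        np_ = find_nanoparticles(frame)[0]
        eig, r_g, kappa2 = gyration_metrics(np_, frame)
        assert kappa2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(eig, eig[0])

    def test_two_beads_rg_is_half_distance(self, make_frame):
        d = 1.0
        frame = make_frame(30.0, chains=[(Species.PEI,
                                          [[5, 5, 5], [5 + d, 5, 5]])])
        np_ = find_nanoparticles(frame)[0]
        _, r_g, _ = gyration_metrics(np_, frame)
        assert r_g == pytest.approx(d / 2)

    def test_single_bead_flagged(self, make_frame):
        frame = make_frame(30.0, chains=[(Species.PEI, [[5, 5, 5]])])
        np_ = find_nanoparticles(frame)[0]
        _, r_g, kappa2 = gyration_metrics(np_, frame)
        assert r_g == 0.0
        assert math.isnan(kappa2)

    def test_eigenvalue_and_direct_routes_agree(self, make_frame):
        """R_g from the gyration tensor equals the mean-square-distance form."""
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=1.0, size=(40, 3)).cumsum(axis=0) * 0.3 + 25
        frame = make_frame(50.0, chains=[(Species.RNA, coords)])
        np_ = find_nanoparticles(frame)[0]
        _, r_g, _ = gyration_metrics(np_, frame)
        unwrapped, _ = unwrap_cluster(frame, np_)
        assert r_g == pytest.approx(radius_of_gyration_direct(unwrapped),
                                    rel=1e-12)


class TestHydrodynamicRadius:
    def test_two_bead_closed_form(self, make_frame):
        d = 2.5
        frame = make_frame(30.0, chains=[(Species.PEI,
                                          [[5, 5, 5], [5 + d, 5, 5]])])
        np_ = find_nanoparticles(frame)[0]
        assert hydrodynamic_radius(np_, frame) == pytest.approx(d)

    def test_equilateral_triangle_closed_form(self, make_frame):
        d = 2.0
        tri = np.array([[0, 0, 0], [d, 0, 0], [d / 2, d * math.sqrt(3) / 2, 0]])
        frame = make_frame(30.0, chains=[(Species.PEI, tri + 10)])
        np_ = find_nanoparticles(frame)[0]
        assert hydrodynamic_radius(np_, frame) == pytest.approx(d)

    def test_homogeneous_scaling(self, make_frame):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 2, (6, 3))
        c = 1.7
        f1 = make_frame(40.0, chains=[(Species.RNA, coords + 10)])
        f2 = make_frame(40.0, chains=[(Species.RNA, coords * c + 10)])
        np1 = find_nanoparticles(f1, cutoff=10)[0]
        np2 = find_nanoparticles(f2, cutoff=10)[0]
        assert hydrodynamic_radius(np2, f2, cutoff=10) == pytest.approx(
            c * hydrodynamic_radius(np1, f1, cutoff=10))

    def test_below_two_items_flagged(self, make_frame):
        frame = make_frame(30.0, chains=[(Species.PEI, [[5, 5, 5]])])
        np_ = find_nanoparticles(frame)[0]
        assert math.isnan(hydrodynamic_radius(np_, frame))


class TestCharge:
    def test_rna_with_full_counterion_shell_is_neutral(self, make_frame):
        chain = straight_chain([10, 10, 10], [1, 0, 0], 4)
        ions = chain + [0, 1.5, 0]
        frame = make_frame(30.0, chains=[(Species.RNA, chain)],
                           ions=[(Species.COUNTERION, ions)])
        np_ = find_nanoparticles(frame)[0]
        total, parts = np_charge(np_, frame)
        assert total == 0
        assert parts == {"polymer": -4, "counterion": 4, "coion": 0}

    def test_isoelectric_np_without_ions_is_neutral(self, make_frame):
        rna = straight_chain([10, 10, 10], [1, 0, 0], 4)
        pei = rna + [0, 1.2, 0]
        frame = make_frame(30.0, chains=[(Species.RNA, rna),
                                         (Species.PEI, pei)])
        np_ = find_nanoparticles(frame)[0]
        total, parts = np_charge(np_, frame)
        assert total == 0
        assert sum(parts.values()) == total


class TestZetaPotential:
    def _central_charge_frame(self, make_frame, box=120.0, extra_ions=()):
        # two +e beads nearly coincident at the box centre: Q = +2
        pei = np.array([[0, 0, 0], [0.02, 0, 0]]) + box / 2
        return make_frame(box, chains=[(Species.PEI, pei)], ions=extra_ions)

    def test_central_point_charge_closed_form(self, make_frame, units):
        frame = self._central_charge_frame(make_frame)
        np_ = find_nanoparticles(frame)[0]
        r_h = hydrodynamic_radius(np_, frame)
        zeta = zeta_potential(np_, frame, units)
        expected = units.bjerrum_length * 2 * (1 / r_h - 1 / 50.0)
        assert zeta == pytest.approx(expected, rel=1e-9)

    def test_neutral_pair_at_same_radius_leaves_zeta_unchanged(
            self, make_frame, units):
        f0 = self._central_charge_frame(make_frame)
        com = np.array([60.01, 60.0, 60.0])  # centre of the two +e beads
        pair = [(Species.COUNTERION, [com + [10, 0, 0]]),
                (Species.COION, [com + [0, 10, 0]])]
        f1 = self._central_charge_frame(make_frame, extra_ions=pair)
        z0 = zeta_potential(find_nanoparticles(f0)[0], f0, units)
        z1 = zeta_potential(find_nanoparticles(f1)[0], f1, units)
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_neutral_shell_outside_shear_surface_contributes_zero(
            self, make_frame, units):
        """Gauss: a spherically neutral shell adds nothing to zeta."""
        rng = np.random.default_rng(2)
        com = np.array([60.01, 60.0, 60.0])  # centre of the two +e beads
        n_shell = 10
        dirs = rng.normal(size=(2 * n_shell, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        shell = com + 20.0 * dirs
        f1 = self._central_charge_frame(
            make_frame,
            extra_ions=[(Species.COUNTERION, shell[:n_shell]),
                        (Species.COION, shell[n_shell:])])
        f0 = self._central_charge_frame(make_frame)
        z0 = zeta_potential(find_nanoparticles(f0)[0], f0, units)
        z1 = zeta_potential(find_nanoparticles(f1)[0], f1, units)
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_all_charge_inside_shear_surface_gives_zero(self, make_frame,
                                                        units):
        rna = straight_chain([60, 60, 60], [1, 0, 0], 3)
        counter = rna + [0, 0.5, 0]
        frame = make_frame(120.0, chains=[(Species.RNA, rna)],
                           ions=[(Species.COUNTERION, counter)])
        np_ = find_nanoparticles(frame)[0]
        # net charge zero and everything well within the shear radius
        zeta = zeta_potential(np_, frame, units, shear_radius=10.0)
        assert zeta == pytest.approx(0.0, abs=1e-12)

    def test_shear_radius_beyond_integration_range_rejected(self, make_frame,
                                                            units):
        frame = self._central_charge_frame(make_frame)
        np_ = find_nanoparticles(frame)[0]
        with pytest.raises(ValueError):
            zeta_potential(np_, frame, units, r_max=50.0, shear_radius=60.0)

    def test_quadrature_oracle(self, make_frame, units):
        """Piecewise-exact integration matches numerical quadrature."""
        from scipy.integrate import quad
        rng = np.random.default_rng(3)
        c = 60.0
        ions = c + rng.uniform(-20, 20, (12, 3))
        frame = self._central_charge_frame(
            make_frame, extra_ions=[(Species.COUNTERION, ions[:6]),
                                    (Species.COION, ions[6:])])
        np_ = find_nanoparticles(frame)[0]
        r_h = hydrodynamic_radius(np_, frame)
        zeta = zeta_potential(np_, frame, units)
        pos = np.mod(frame.beads.positions, frame.box_edge)
        com = pos[np_.member_bead_indices].mean(axis=0)
        d = np.linalg.norm(pos - com, axis=1)
        qs = frame.beads.charge

        def q_of_r(r):
            return float(qs[d <= r].sum())

        val, _ = quad(lambda r: q_of_r(r) / r ** 2, r_h, 50.0,
                      points=np.sort(d[d < 50.0]), limit=200)
        assert zeta == pytest.approx(units.bjerrum_length * val, rel=1e-6)


class TestManning:
    def test_no_ions_within_cutoff(self, make_frame):
        chain = straight_chain([10, 10, 10], [1, 0, 0], 5)
        frame = make_frame(40.0, chains=[(Species.RNA, chain)],
                           ions=[(Species.COUNTERION,
                                  chain + [0, 20.0, 0])])
        assert manning_fraction(frame) == 0.0

    def test_fully_paired_chain(self, make_frame):
        chain = straight_chain([10, 10, 10], [1, 0, 0], 5)
        frame = make_frame(40.0, chains=[(Species.RNA, chain)],
                           ions=[(Species.COUNTERION, chain + [0, 1.0, 0])])
        assert manning_fraction(frame) == 1.0

    def test_theory_value(self, units):
        assert manning_theory(units) == pytest.approx(1 - 1 / 1.168)


class TestAnalyzeFrame:
    def test_tidy_table_contents(self, make_frame, units):
        a = straight_chain([5, 5, 5], [1, 0, 0], 5)
        b = a + [0, 2.0, 0]
        c = straight_chain([20, 20, 20], [0, 1, 0], 5)
        frame = make_frame(40.0, chains=[(Species.RNA, a), (Species.PEI, b),
                                         (Species.RNA, c)])
        nps, table = analyze_frame(frame, units)
        assert len(table) == 2
        assert set(table["n_chains"]) == {1, 2}
        assert (table["charge_total"]
                == table[["charge_polymer", "charge_counterion",
                          "charge_coion"]].sum(axis=1)).all()
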