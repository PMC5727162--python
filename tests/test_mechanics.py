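"""Hinge mechanics: WLC model, energy landscapes, angle prediction,
stiffness estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modori import (
    AngleObservation,
    HingeGeometry,
    TorsionalHinge,
    WLCParams,
    adjuster_extension,
    boltzmann_stats,
    energy_landscape,
    estimate_stiffness,
    pca_stiffness,
    predict_angle,
    predict_angle_ds,
    wlc_energy,
    wlc_force,
)
from modori.mechanics import KT_PN_NM, MechanicsError, stiffness_from_observation

GEOM = HingeGeometry()  # symmetric reference geometry, r1 = r2 = 85.68 nm


class TestWLC:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, WLCParams(1.0, 100.0)) == 0.0

    def test_half_contour_force(self):
        """F(Lc/2) = 1.25 kT/Lp by direct substitution."""
        p = WLCParams(1.0, 100.0)
        assert wlc_force(50.0, p) == pytest.approx(1.25 * p.kT / p.persistence_nm)

    @given(st.floats(0.01, 0.95), st.floats(0.3, 3.0), st.floats(50.0, 400.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_energy_derivative_is_force(self, frac, lp, lc):
        """dE/dx = F to 1e-6 relative, everywhere tested."""
        p = WLCParams(lp, lc)
        x = frac * lc
        h = 1e-6 * lc
        dEdx = (wlc_energy(min(x + h, lc * (1 - 1e-9)), p)
                - wlc_energy(x - h, p)) / (min(x + h, lc * (1 - 1e-9)) - (x - h))
        assert dEdx == pytest.approx(wlc_force(x, p), rel=1e-5)

    def test_force_strictly_increasing(self):
        p = WLCParams(1.0, 100.0)
        x = np.linspace(0, 99, 200)
        assert np.all(np.diff(wlc_force(x, p)) > 0)

    def test_energy_monotone_and_zero_at_origin(self):
        p = WLCParams(1.0, 100.0)
        x = np.linspace(0, 99, 200)
        e = wlc_energy(x, p)
        assert e[0] == 0.0
        assert np.all(np.diff(e) > 0)

    def test_overstretched_rejected(self):
        with pytest.raises(MechanicsError):
            wlc_force(100.0, WLCParams(1.0, 100.0))


class TestExtension:
    def test_straight_angle_gives_anchor_sum(self):
        g = HingeGeometry(5.0, 5.0)
        assert adjuster_extension(180.0, g) == pytest.approx(10.0)

    def test_closed_angle_gives_anchor_difference(self):
        assert adjuster_extension(0.0, HingeGeometry(5.0, 5.0)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_right_angle_pythagoras(self):
        assert adjuster_extension(90.0, HingeGeometry(3.0, 4.0)) == \
            pytest.approx(5.0)

    @given(st.floats(0.0, 180.0), st.floats(1.0, 100.0), st.floats(1.0, 100.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_triangle_inequality(self, theta, r1, r2):
        x = adjuster_extension(theta, HingeGeometry(r1, r2))
        assert abs(r1 - r2) - 1e-9 <= x <= r1 + r2 + 1e-9


class TestLandscape:
    def test_total_is_sum_of_terms(self):
        land = energy_landscape(TorsionalHinge(25.3), GEOM,
                                WLCParams.for_ss_adjuster(252))
        feas = land.feasible
        assert np.allclose(land.e_total[feas],
                           land.e_hinge[feas] + land.e_adjuster[feas])

    def test_zero_stiffness_leaves_only_adjuster_energy(self):
        land = energy_landscape(TorsionalHinge(0.0), GEOM,
                                WLCParams.for_ss_adjuster(252))
        assert np.allclose(land.e_total[land.feasible],
                           land.e_adjuster[land.feasible])

    def test_infeasible_points_flagged(self):
        # a 150-nt ssDNA adjuster (94.5 nm) cannot span wide-open angles
        land = energy_landscape(TorsionalHinge(25.3), GEOM,
                                WLCParams.for_ss_adjuster(150))
        assert land.feasible.any() and (~land.feasible).any()
        assert np.all(np.isinf(land.e_total[~land.feasible]))

    def test_predicted_angle_sits_at_grid_minimum(self):
        hinge = TorsionalHinge(25.3)
        wlc = WLCParams.for_ss_adjuster(252)
        theta = predict_angle(hinge, GEOM, wlc)
        land = energy_landscape(hinge, GEOM, wlc)
        e = land.e_total[land.feasible]
        t = land.theta_deg[land.feasible]
        assert abs(t[np.argmin(e)] - theta) < 0.1


class TestPredictAngle:
    def test_slack_adjuster_rests_at_rest_angle(self):
        """With the adjuster contour longer than the anchor separation the
        tension's moment arm vanishes at theta0 = 180 and the hinge wins."""
        wlc = WLCParams.for_ss_adjuster(504)  # 317.5 nm >> r1 + r2
        assert predict_angle(TorsionalHinge(500.0), GEOM, wlc) == \
            pytest.approx(180.0, abs=0.1)

    def test_stiff_limit_approaches_rest_angle(self):
        # contour (214 nm) comfortably exceeds the anchor separation, so
        # theta0 is geometrically reachable and a stiff hinge wins
        wlc = WLCParams.for_ss_adjuster(340)
        angles = [predict_angle(TorsionalHinge(k), GEOM, wlc)
                  for k in (10.0, 100.0, 1000.0, 10000.0)]
        assert all(b > a for a, b in zip(angles, angles[1:]))
        assert angles[-1] > 170.0

    def test_angle_decreases_with_shorter_adjuster(self):
        """Grid-search oracle: at fixed k = 25.3 pN nm/rad the equilibrium
        angle decreases strictly with the adjuster contour length."""
        hinge = TorsionalHinge(25.3)
        angles = []
        for n_nt in (336, 294, 252, 210, 168):
            wlc = WLCParams.for_ss_adjuster(n_nt)
            grid = np.arange(0.5, 180.0, 0.05)
            x = adjuster_extension(grid, GEOM)
            ok = x < wlc.contour_nm * (1 - 1e-9)
            e = (0.5 * 25.3 * (np.radians(grid[ok]) - math.pi) ** 2
                 + wlc_energy(x[ok], wlc))
            oracle = grid[ok][np.argmin(e)]
            theta = predict_angle(hinge, GEOM, wlc)
            assert theta == pytest.approx(oracle, abs=0.1)
            angles.append(theta)
        assert all(b < a for a, b in zip(angles, angles[1:]))

    def test_angle_increases_with_stiffness(self):
        wlc = WLCParams.for_ss_adjuster(252)
        ks = (25.3, 33.8, 49.6)
        angles = [predict_angle(TorsionalHinge(k), GEOM, wlc) for k in ks]
        assert angles[0] < angles[1] < angles[2]


class TestPredictAngleDs:
    def test_full_reach_gives_straight(self):
        n = round((GEOM.r1 + GEOM.r2) / 0.34)
        assert predict_angle_ds(n, GEOM) == pytest.approx(180.0, abs=0.5)

    def test_zero_reach_gives_closed(self):
        assert predict_angle_ds(1, HingeGeometry(50.0, 50.0)) == \
            pytest.approx(0.0, abs=1.0)

    def test_independent_of_stiffness_by_construction(self):
        # the geometric relation involves no hinge parameter at all; the
        # same lengths fed through the energy model with a rigid strut term
        # would give the same angle for any k
        assert predict_angle_ds(357, GEOM) == predict_angle_ds(357, GEOM)

    def test_overlong_adjuster_rejected(self):
        with pytest.raises(MechanicsError):
            predict_angle_ds(600, GEOM)


class TestBoltzmann:
    def test_harmonic_sd_matches_equipartition(self):
        """For a pure harmonic landscape, sd = sqrt(kT/k) radians."""
        k = 300.0
        grid = np.arange(0.05, 180.0 + 1e-9, 0.05)
        th = np.radians(grid)
        e_h = 0.5 * k * (th - math.radians(90.0)) ** 2
        from modori.mechanics import EnergyLandscape
        land = EnergyLandscape(grid, e_h, np.zeros_like(grid),
                               np.ones_like(grid, dtype=bool))
        mean, sd = boltzmann_stats(land)
        assert mean == pytest.approx(90.0, abs=0.1)
        assert math.radians(sd) == pytest.approx(math.sqrt(KT_PN_NM / k),
                                                 rel=1e-3)

    def test_distribution_normalised(self):
        land = energy_landscape(TorsionalHinge(25.3), GEOM,
                                WLCParams.for_ss_adjuster(252))
        feas = land.feasible
        e = land.e_total[feas]
        w = np.exp(-(e - e.min()) / KT_PN_NM)
        p = w / w.sum()
        assert p.sum() == pytest.approx(1.0)

    def test_ds_adjuster_is_sharper_than_ss(self):
        """A strut-bound adjuster pins the angle; the ssDNA-adjusted
        landscape at the same mean has a wider thermal distribution."""
        hinge = TorsionalHinge(25.3)
        wlc = WLCParams.for_ss_adjuster(252)
        theta_ss = predict_angle(hinge, GEOM, wlc)
        _, sd_ss = boltzmann_stats(energy_landscape(hinge, GEOM, wlc))
        # rigid-strut adjuster: model as a very stiff harmonic well at the
        # same mean angle
        grid = np.arange(0.05, 180.0 + 1e-9, 0.05)
        k_strut = 5000.0
        e = 0.5 * k_strut * (np.radians(grid) - math.radians(theta_ss)) ** 2
        from modori.mechanics import EnergyLandscape
        land_ds = EnergyLandscape(grid, e, np.zeros_like(grid),
                                  np.ones_like(grid, dtype=bool))
        _, sd_ds = boltzmann_stats(land_ds)
        assert sd_ds < sd_ss


class TestStiffnessEstimation:
    def test_roundtrip_recovers_k_exactly(self):
        """estimate_stiffness(predict_angle(k)) == k (noise-free)."""
        k_true = 25.3
        obs = []
        for n_nt in (168, 210, 252, 294, 336):
            theta = predict_angle(TorsionalHinge(k_true), GEOM,
                                  WLCParams.for_ss_adjuster(n_nt))
            obs.append(AngleObservation(n_nt, theta))
        est = estimate_stiffness(obs, GEOM)
        assert est.mean == pytest.approx(k_true, rel=0.01)
        assert est.min <= est.mean <= est.max

    @pytest.mark.parametrize("k_true", [25.3, 33.8, 49.6])
    def test_roundtrip_across_operating_points(self, k_true):
        obs = [AngleObservation(n, predict_angle(
            TorsionalHinge(k_true), GEOM, WLCParams.for_ss_adjuster(n)))
            for n in (210, 252, 294)]
        assert estimate_stiffness(obs, GEOM).mean == \
            pytest.approx(k_true, rel=0.01)

    def test_observation_at_rest_angle_rejected(self):
        with pytest.raises(MechanicsError, match="rest angle"):
            estimate_stiffness([AngleObservation(252, 180.0)], GEOM)

    def test_overstretched_observation_skipped(self):
        # a 210-nt chain (132 nm contour) cannot span a 170-deg chord
        est = estimate_stiffness(
            [AngleObservation(210, 170.0),
             AngleObservation(252, 60.0)], GEOM)
        assert len(est.skipped) == 1
        assert len(est.per_observation) == 1

    def test_noisy_recovery_within_ten_percent(self):
        """sd = 5 deg per particle, n = 250 particles per design."""
        k_true = 25.3
        rng = np.random.default_rng(42)
        obs = []
        for n_nt in (168, 210, 252, 294, 336):
            theta = predict_angle(TorsionalHinge(k_true), GEOM,
                                  WLCParams.for_ss_adjuster(n_nt))
            sample = rng.normal(theta, 5.0, size=250)
            obs.append(AngleObservation(n_nt, float(sample.mean()), 5.0, 250))
        assert estimate_stiffness(obs, GEOM).mean == \
            pytest.approx(k_true, rel=0.10)

    def test_torque_balance_formula(self):
        # hand-computed: theta=90, r1=r2=10 -> x=14.142, moment arm 7.071
        geom = HingeGeometry(10.0, 10.0)
        wlc = WLCParams(1.0, 50.0)
        f = wlc_force(adjuster_extension(90.0, geom), wlc)
        expected = f * 10 * 10 * math.sin(math.pi / 2) / \
            adjuster_extension(90.0, geom) / math.radians(90.0)
        assert stiffness_from_observation(90.0, geom, wlc) == \
            pytest.approx(expected)


class TestPcaStiffness:
    def test_gaussian_recovery(self):
        k_true = 30.0
        rng = np.random.default_rng(0)
        traj = np.degrees(rng.normal(0.0, math.sqrt(KT_PN_NM / k_true), 10_000))
        assert pca_stiffness(traj) == pytest.approx(k_true, rel=0.05)

    def test_constant_trajectory_flags_infinite(self):
        assert pca_stiffness(np.full(500, 42.0)) == math.inf

    def test_multivariate_mode_ordering(self):
        rng = np.random.default_rng(1)
        soft = rng.normal(0, 2.0, 5000)
        stiff = rng.normal(0, 0.5, 5000)
        ks = pca_stiffness(np.degrees(np.column_stack([soft, stiff])))
        assert ks[0] <= ks[1]

    def test_short_trajectory_rejected(self):
        with pytest.raises(MechanicsError):
            pca_stiffness(np.zeros(50))
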