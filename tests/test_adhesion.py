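import math

import numpy as np
import pytest

from clawmech import (AdhesionGeometry, can_attach, force_distribution,
                      k_closed_form, limit_load_angle, load_angle,
                      pressure_angle_double, pressure_angle_single, sweep)


def deg(x):
    return math.degrees(x)


class TestLoadAngle:
    @pytest.mark.parametrize("mu", np.arange(0.1, 1.51, 0.1))
    def test_self_locking_boundary_is_exact_zero(self, mu):
        # at the pressure angle alpha = arctan(mu) the claw cannot
        # self-lock: the load angle vanishes identically
        assert load_angle(math.atan(mu), mu) == 0.0

    def test_closed_forms(self):
        assert deg(load_angle(0.0, 1.0)) == pytest.approx(45.0)
        assert deg(load_angle(math.radians(10), 0.5)) == pytest.approx(
            16.565, abs=1e-3)

    def test_agrees_with_equilibrium_ratio_form(self):
        # the single-contact equilibrium gives
        # tan(theta) = (mu cos a - sin a)/(cos a + mu sin a), whose
        # regular closed form is theta = arctan(mu) - a
        for mu in (0.2, 0.5, 1.2):
            for a_deg in (5, 20, 40, 60):
                a = math.radians(a_deg)
                th = load_angle(a, mu)
                rhs = ((mu * math.cos(a) - math.sin(a))
                       / (math.cos(a) + mu * math.sin(a)))
                assert math.tan(th) == pytest.approx(rhs, abs=1e-12)

    def test_monotonicity(self):
        alphas = np.radians(np.linspace(0, 80, 50))
        thetas = [load_angle(a, 0.5) for a in alphas]
        assert np.all(np.diff(thetas) < 0)
        mus = np.linspace(0.05, 2.0, 50)
        thetas = [load_angle(math.radians(30), m) for m in mus]
        assert np.all(np.diff(thetas) > 0)


class TestPressureAngles:
    def test_single_contact_closed_forms(self):
        assert deg(pressure_angle_single(1.0, 1.0, 1.0)) == pytest.approx(90.0)
        assert deg(pressure_angle_single(1.0, 1.0, 0.0)) == pytest.approx(30.0)
        assert deg(pressure_angle_single(0.1, 1.0, 0.2)) == pytest.approx(
            math.degrees(math.asin(0.3 / 1.1)), abs=1e-9)

    def test_single_contact_invalid_depth(self):
        with pytest.raises(ValueError):
            pressure_angle_single(1.0, 1.0, 1.5)

    def test_double_contact_closed_forms(self):
        assert pressure_angle_double(1.0, 1.0, 4.0) == 0.0
        assert deg(pressure_angle_double(1.0, 1.0, 2.0)) == pytest.approx(60.0)
        assert deg(pressure_angle_double(1.0, 1.0, 1e-9)) == pytest.approx(
            90.0, abs=1e-6)

    def test_double_contact_wrong_regime(self):
        with pytest.raises(ValueError):
            pressure_angle_double(1.0, 1.0, 5.0)

    def test_monotonicity_alpha_vs_d_and_r(self):
        ds = np.linspace(0.5, 3.9, 40)
        alphas = [pressure_angle_double(1.0, 1.0, d) for d in ds]
        assert np.all(np.diff(alphas) < 0)
        rs = np.linspace(0.1, 2.0, 30)
        alphas = [pressure_angle_single(r, 1.0, 0.2) for r in rs]
        assert np.all(np.diff(alphas) > 0)


class TestCanAttach:
    def test_threshold_comparison(self):
        # alpha = 20 deg < arctan(0.5) = 26.57 deg -> attaches
        g = AdhesionGeometry(tip_radius=0.1, particle_radius=1.0,
                             particle_spacing=2.0 * 1.1 * math.cos(
                                 math.radians(20)),
                             friction_coefficient=0.5)
        assert deg(g.pressure_angle()) == pytest.approx(20.0)
        assert can_attach(g)

    def test_boundary_is_non_attaching(self):
        mu = 0.5
        alpha = math.atan(mu)
        d = 2.0 * 1.1 * math.cos(alpha)
        g = AdhesionGeometry(0.1, 1.0, d, friction_coefficient=mu)
        assert deg(g.pressure_angle()) == pytest.approx(deg(alpha))
        assert not can_attach(g)

    def test_frictionless_never_attaches(self):
        g = AdhesionGeometry(0.1, 1.0, 2.0, friction_coefficient=0.0)
        assert not can_attach(g)

    def test_equivalent_to_positive_load_angle(self):
        for mu in (0.2, 0.6, 1.0):
            for d in (0.8, 1.5, 2.1):
                g = AdhesionGeometry(0.1, 1.0, d, friction_coefficient=mu)
                assert can_attach(g) == (
                    load_angle(g.pressure_angle(), mu) > 0)


class TestForceDistribution:
    def test_vertical_embed_theta_zero(self):
        fb = force_distribution(3.0, 0.0, math.radians(45), 0.5)
        assert fb.Fp == 0.0
        assert fb.Fv == pytest.approx(3.0)
        assert fb.N1 == pytest.approx(fb.N2)

    def test_horizontal_load_no_vertical_support(self):
        fb = force_distribution(3.0, math.radians(90), math.radians(45), 0.5)
        assert fb.Fv == pytest.approx(0.0, abs=1e-15)

    def test_matches_independent_linear_solve(self):
        # brute-force 2x2 solve of the equilibrium system
        F, th, a, mu = 3.0, math.radians(10), math.radians(45), 0.5
        cp = mu * math.cos(a) - math.sin(a)
        cv = mu * math.sin(a) + math.cos(a)
        A = np.array([[cp, -cp], [cv, cv]])
        b = np.array([F * math.sin(th), F * math.cos(th)])
        n1, n2 = np.linalg.solve(A, b)
        fb = force_distribution(F, th, a, mu)
        assert fb.N1 == pytest.approx(n1, rel=1e-12)
        assert fb.N2 == pytest.approx(n2, rel=1e-12)

    def test_k_matches_printed_closed_form(self):
        for th_deg in (5, 10, 25, 40):
            fb = force_distribution(3.0, math.radians(th_deg),
                                    math.radians(45), 0.5)
            assert fb.k == pytest.approx(
                k_closed_form(math.radians(th_deg), math.radians(45), 0.5),
                rel=1e-10)

    def test_equilibrium_residuals_tiny_on_grid(self):
        F = 3.0
        worst = 0.0
        for th in np.radians(np.linspace(0, 89, 90)):
            for a in np.radians(np.linspace(0, 89, 90)):
                if abs(0.5 * math.cos(a) - math.sin(a)) < 1e-6:
                    continue
                fb = force_distribution(F, th, a, 0.5)
                worst = max(worst, float(np.abs(fb.residuals()).max()))
        assert worst <= 1e-10 * F

    def test_driving_force_decomposition_conserved(self):
        for th in np.radians(np.linspace(0, 90, 19)):
            fb = force_distribution(3.0, th, math.radians(30), 0.5)
            assert math.hypot(fb.Fp, fb.Fv) == pytest.approx(3.0, rel=1e-12)
            assert fb.Ff1 == fb.mu * fb.N1 and fb.Ff2 == fb.mu * fb.N2

    def test_friction_cone_boundary_is_singular(self):
        mu = 0.5
        with pytest.raises(ValueError):
            force_distribution(3.0, 0.1, math.atan(mu), mu)

    def test_sign_reversal_flagged_beyond_limit(self):
        a, mu = math.radians(45), 0.5
        th_lim = limit_load_angle(a, mu)
        below = force_distribution(3.0, th_lim - 0.05, a, mu)
        above = force_distribution(3.0, th_lim + 0.05, a, mu)
        assert below.N1 > 0 and not below.beyond_limit
        assert above.N1 < 0 and above.beyond_limit


class TestLimitLoadAngle:
    def test_closed_forms(self):
        assert deg(limit_load_angle(math.radians(45), 0.0)) == pytest.approx(45.0)
        assert deg(limit_load_angle(math.radians(45), 0.5)) == pytest.approx(
            18.435, abs=1e-3)

    def test_no_root_when_friction_dominates(self):
        with pytest.raises(ValueError):
            limit_load_angle(math.radians(20), 0.5)  # tan 20 < 0.5

    def test_limit_vanishes_as_mu_approaches_tan_alpha(self):
        a = math.radians(45)
        assert limit_load_angle(a, math.tan(a) - 1e-9) == pytest.approx(
            0.0, abs=1e-8)

    def test_agrees_with_bisection_on_N1(self):
        a, mu = math.radians(45), 0.5

        def n1(th):
            return force_distribution(3.0, th, a, mu).N1

        lo, hi = math.radians(1e-6), math.radians(89.0)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if n1(lo) * n1(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert limit_load_angle(a, mu) == pytest.approx(0.5 * (lo + hi),
                                                        abs=1e-8)


class TestSweep:
    def test_theta_decreases_with_alpha(self):
        df = sweep("theta_vs_alpha_mu",
                   {"alpha_deg": np.linspace(0, 80, 30), "mu": [0.5]})
        assert np.all(np.diff(df["theta_deg"]) < 0)

    def test_alpha_decreases_with_spacing(self):
        df = sweep("alpha_vs_d_R_r", {"d": np.linspace(0.5, 3.9, 30)},
                   {"r": 1.0, "R": 1.0})
        assert np.all(np.diff(df["alpha_deg"].dropna()) < 0)

    def test_forces_follow_the_worked_case(self):
        """alpha 45 deg, mu 0.5, F 3 N: N2 rises monotonically with theta
        while N1 falls through zero at the limit load angle."""
        df = sweep("forces_vs_theta", {"theta_deg": np.arange(0, 90, 1.0)})
        # N2 rises throughout the grasping range discussed for the claw
        # (it analytically peaks at arctan(cv/|cp|) ~ 71.6 deg)
        rising = df["theta_deg"] <= 60
        assert np.all(np.diff(df.loc[rising, "N2_N"]) > 0)
        assert np.all(np.diff(df["N1_N"]) < 0)
        sign_change = np.nonzero(np.diff(np.sign(df["N1_N"])) < 0)[0]
        assert len(sign_change) == 1
        th_cross = df["theta_deg"].iloc[sign_change[0]]
        th_lim = deg(limit_load_angle(math.radians(45), 0.5))
        assert abs(th_cross - th_lim) <= 1.0
        # Fp grows and Fv shrinks over the sweep
        assert np.all(np.diff(df["Fp_N"]) > 0)
        assert np.all(np.diff(df["Fv_N"]) < 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep("forces_vs_theta", {"theta_deg": []})
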