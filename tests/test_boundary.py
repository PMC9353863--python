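import numpy as np
import pytest

from clawmech import (CLAW_FEATURE_CURVES, BoundaryPointSet, FourierModel,
                      Gaussian2Model, PolynomialModel, curvature_profile,
                      evaluate_model, extract_boundary, fit_curve, goodness,
                      multiscale_edge_detect, sample_boundary_points,
                      segment_curves, select_model, split_x_monotone,
                      suggest_breakpoints)


class TestGoodness:
    def test_hand_computed(self):
        y = np.array([1.0, 2.0, 3.0])
        sse, sst, r2 = goodness(y, np.array([1.0, 2.0, 4.0]))
        assert (sse, sst, r2) == (1.0, 2.0, 0.5)

    def test_perfect_and_null_fits(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert goodness(y, y) == (0.0, 5.0, 1.0)
        _, _, r2 = goodness(y, np.full(4, y.mean()))
        assert r2 == 0.0

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            goodness(np.full(5, 2.0), np.zeros(5))

    def test_r2_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        yhat = y + rng.normal(0, 0.3, 50)
        sse1, _, r21 = goodness(y, yhat)
        sse2, _, r22 = goodness(3 * y + 7, 3 * yhat + 7)
        assert r22 == pytest.approx(r21, abs=1e-12)
        assert sse2 == pytest.approx(9 * sse1, rel=1e-12)


class TestEvaluateModel:
    def test_fourier_closed_forms_at_zero(self):
        m = FourierModel(a0=1.0, a1=2.0, b1=3.0, a2=4.0, b2=5.0, w=0.5)
        y, y1, y2 = evaluate_model(m, 0.0)
        assert y == pytest.approx(m.a0 + m.a1 + m.a2)
        assert y1 == pytest.approx(m.w * (m.b1 + 2 * m.b2))
        assert y2 == pytest.approx(-m.w ** 2 * (m.a1 + 4 * m.a2))

    def test_poly2_second_derivative_constant(self):
        m = PolynomialModel((1.0, -2.0, 3.0))
        x = np.linspace(-5, 5, 11)
        _, _, y2 = evaluate_model(m, x)
        assert np.allclose(y2, 6.0)

    def test_reference_claw_curve1_concave_at_origin(self):
        # the first feature curve of the claw outline is concave near x=0
        _, _, y2 = evaluate_model(CLAW_FEATURE_CURVES[1], 0.0)
        assert y2 < 0

    def test_gaussian_derivatives_match_finite_differences(self):
        m = Gaussian2Model(2.0, 1.0, 0.7, -1.0, 3.0, 1.2)
        x = np.linspace(-1, 5, 25)
        h = 1e-6
        y1_fd = (m.value(x + h) - m.value(x - h)) / (2 * h)
        y2_fd = (m.value(x + h) - 2 * m.value(x) + m.value(x - h)) / h ** 2
        assert np.allclose(m.deriv1(x), y1_fd, atol=1e-6)
        assert np.allclose(m.deriv2(x), y2_fd, atol=1e-3)


class TestCurvature:
    def test_circle_line_parabola_closed_forms(self):
        # circle arc of radius 10 µm near the apex: K = 1/R
        class Circle:
            def value(self, x):
                return np.sqrt(100.0 - np.asarray(x, float) ** 2)

            def deriv1(self, x):
                x = np.asarray(x, float)
                return -x / np.sqrt(100.0 - x ** 2)

            def deriv2(self, x):
                x = np.asarray(x, float)
                return -100.0 / (100.0 - x ** 2) ** 1.5

        prof = curvature_profile(Circle(), (-1.0, 1.0), 101)
        assert np.allclose(prof.K, 0.1, atol=1e-9)

        line = PolynomialModel((3.0, 2.0))
        prof = curvature_profile(line, (0.0, 10.0), 50)
        assert np.allclose(prof.K, 0.0, atol=1e-15)

        para = PolynomialModel((0.0, 0.0, 1.0))
        prof = curvature_profile(para, (-1e-9, 1e-9), 3)
        assert prof.K[1] == pytest.approx(2.0, abs=1e-9)

    def test_curvature_invariant_under_rigid_translation(self):
        m = FourierModel(1.0, 2.0, -1.0, 0.5, 0.3, 0.8)
        shifted = FourierModel(m.a0 + 5.0, m.a1, m.b1, m.a2, m.b2, m.w)
        p1 = curvature_profile(m, (0.0, 4.0), 200)
        p2 = curvature_profile(shifted, (0.0, 4.0), 200)
        assert np.allclose(p1.K, p2.K, atol=1e-12)

    def test_classification_follows_sign(self):
        concave = PolynomialModel((0.0, 0.0, -1.0))
        convex = PolynomialModel((0.0, 0.0, 1.0))
        assert curvature_profile(concave, (-1, 1)).classification == "concave"
        assert curvature_profile(convex, (-1, 1)).classification == "convex"


class TestFitting:
    def test_exact_fourier_round_trip(self):
        truth = CLAW_FEATURE_CURVES[2]
        pts = sample_boundary_points(truth, (0, 250), 100, noise_sd=0.0)
        fit = fit_curve(pts, "fourier2")
        assert fit.success
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        for k, v in truth.coefficients().items():
            assert fit.coefficients()[k] == pytest.approx(v, rel=1e-6)

    def test_polynomial_exact_fit(self):
        x = np.linspace(0, 10, 30)
        pts = BoundaryPointSet(x, 1 + 2 * x - 0.5 * x ** 2)
        fit = fit_curve(pts, "poly2")
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.coefficients()["c2"] == pytest.approx(-0.5)

    def test_gaussian2_recovers_two_bumps(self):
        truth = Gaussian2Model(5.0, 3.0, 1.0, 3.0, 7.0, 1.5)
        x = np.linspace(0, 10, 120)
        fit = fit_curve(BoundaryPointSet(x, truth.value(x)), "gaussian2")
        assert fit.success
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_data_errors(self):
        pts = BoundaryPointSet(np.linspace(0, 1, 20), np.full(20, 3.0))
        with pytest.raises(ValueError):
            fit_curve(pts, "poly2")

    def test_too_few_points_rejected(self):
        pts = BoundaryPointSet([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        with pytest.raises(ValueError):
            fit_curve(pts, "fourier2")

    def test_unknown_family_rejected(self):
        pts = BoundaryPointSet(np.arange(10.0), np.arange(10.0) ** 2)
        with pytest.raises(ValueError):
            fit_curve(pts, "spline9")

    def test_noisy_parameter_recovery_within_3_se(self):
        """Fits to samples with 2% amplitude noise recover every
        coefficient within 3 standard errors in >=95% of replicates."""
        truth = CLAW_FEATURE_CURVES[2]
        tc = truth.coefficients()
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            pts = sample_boundary_points(truth, (0, 250), 200, noise_sd=2.0,
                                         seed=seed)
            fit = fit_curve(pts, "fourier2")
            ok += fit.success and all(
                abs(fit.coefficients()[k] - tc[k]) <= 3 * fit.stderr[k]
                for k in tc)
        assert ok >= 0.95 * n_rep

    def test_select_model_rules(self):
        def dummy(family, r2, n_par):
            from clawmech.boundary import FitResult

            class M:
                n_params = n_par

                def coefficients(self):
                    return {}

            return FitResult(family=family, model=M(), sse=1 - r2, sst=1.0,
                             r_squared=r2, yhat=np.zeros(3),
                             x_range=(0, 1), n_points=3)

        fits = [dummy("gaussian2", 0.95, 6), dummy("fourier2", 0.99, 6),
                dummy("poly2", 0.90, 3), dummy("poly3", 0.94, 4)]
        assert select_model(fits).family == "fourier2"
        # exact tie: fewer parameters wins
        tie = [dummy("poly3", 0.99, 4), dummy("poly2", 0.99, 3)]
        assert select_model(tie).family == "poly2"
        with pytest.raises(ValueError):
            bad = dummy("poly2", 0.5, 3)
            bad.success = False
            select_model([bad])

    def test_select_model_prefers_fourier_on_fourier_data(self):
        truth = CLAW_FEATURE_CURVES[2]
        wins = 0
        for seed in range(10):
            pts = sample_boundary_points(truth, (0, 250), 200, noise_sd=2.0,
                                         seed=seed)
            fits = [fit_curve(pts, f)
                    for f in ("fourier2", "poly2", "poly3", "gaussian2")]
            wins += select_model(fits).family == "fourier2"
        assert wins >= 9


class TestExtraction:
    def test_single_line_chain(self):
        em = np.zeros((9, 20), dtype=bool)
        em[4, 3:15] = True
        chains = extract_boundary(em, pixel_size=2.0)
        assert len(chains) == 1
        assert len(chains[0]) == 12
        assert np.allclose(chains[0].x, np.arange(3, 15) * 2.0)

    def test_two_disjoint_chains(self):
        em = np.zeros((30, 30), dtype=bool)
        em[5, 2:25] = True
        em[20, 2:25] = True
        assert len(extract_boundary(em, 1.0)) == 2

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            extract_boundary(np.zeros((10, 10), dtype=bool), 1.0)

    def test_disk_ring_traces_closed_and_splits_in_two(self, disk_image):
        em = multiscale_edge_detect(disk_image, [1])[1]
        chains = extract_boundary(em, 1.0)
        assert len(chains) == 1
        segs = split_x_monotone(chains[0], min_length=10)
        assert len(segs) == 2
        for seg in segs:
            assert np.all(np.diff(seg.x) > 0)


class TestSegmentation:
    def test_exhaustive_partition(self):
        pts = BoundaryPointSet(np.arange(100.0), np.sin(np.arange(100.0)))
        segs = segment_curves(pts, [25.0, 50.0, 75.0])
        assert [s.label for s in segs] == [1, 2, 3, 4]
        assert sum(len(s) for s in segs) == 100

    def test_point_on_breakpoint_goes_left(self):
        pts = BoundaryPointSet(np.arange(10.0), np.arange(10.0) ** 1.5)
        segs = segment_curves(pts, [3.0, 5.0, 7.0])
        assert 3.0 in segs[0].x and 3.0 not in segs[1].x

    @pytest.mark.parametrize("bad", [[5.0, 3.0, 7.0], [0.0, 3.0, 5.0],
                                     [3.0, 5.0, 99.0], [3.0, 5.0]])
    def test_invalid_breakpoints(self, bad):
        pts = BoundaryPointSet(np.arange(10.0), np.arange(10.0) ** 1.5)
        with pytest.raises(ValueError):
            segment_curves(pts, bad)

    def test_suggested_breakpoints_near_true_inflections(self):
        # quintic with inflections (y'' roots) at x = 2, 5, 8
        def y2_antideriv(x):
            # integrate (x-2)(x-5)(x-8) twice
            p = np.polynomial.polynomial.polyfromroots([2.0, 5.0, 8.0])
            for _ in range(2):
                p = np.polynomial.polynomial.polyint(p)
            return np.polynomial.polynomial.polyval(x, p)

        x = np.linspace(0, 10, 300)
        pts = BoundaryPointSet(x, y2_antideriv(x))
        bps = suggest_breakpoints(pts, n_breaks=3)
        assert len(bps) == 3
        for got, want in zip(bps, (2.0, 5.0, 8.0)):
            assert abs(got - want) <= 0.05 * 10.0  # within 5% of the span
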