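"""Multiplicative combination, MLE extraction, and relocation sweeps."""

import math

import numpy as np
import pytest

from landmark_homing import (
    DensityGrid,
    GridSpec,
    LandmarkConfiguration,
    Point2D,
    RidgeParams,
    circle_intersections,
    combine,
    default_grid_spec,
    exp1_configuration,
    exp2_base_configuration,
    predict_configuration,
    predicted_density,
    relocate,
    relocation_sweep,
    ring_density,
    summarize_density,
)
from landmark_homing.pipeline import compromise_point


def _grid(half=12.0, cell=0.2):
    n = 2 * int(round(half / cell)) + 1
    origin = Point2D(-(n // 2) * cell, -(n // 2) * cell)
    return GridSpec(origin=origin, cell_size=cell, n_rows=n, n_cols=n)


class TestCombine:
    def test_uniform_is_identity(self, gaussian_params):
        spec = _grid()
        g = ring_density(Point2D(0, 0), gaussian_params, spec)
        u = DensityGrid.uniform(spec)
        combined = combine([g, u])
        np.testing.assert_allclose(combined.values, g.values, atol=1e-12)

    def test_commutative(self, gaussian_params):
        spec = _grid(half=14.5)
        g1 = ring_density(Point2D(-4, 0), gaussian_params, spec)
        g2 = ring_density(Point2D(4, 0), gaussian_params, spec)
        np.testing.assert_array_equal(
            combine([g1, g2]).values, combine([g2, g1]).values
        )

    def test_mismatched_grids_rejected(self, gaussian_params):
        g1 = ring_density(Point2D(0, 0), gaussian_params, _grid(cell=0.2))
        g2 = ring_density(Point2D(0, 0), gaussian_params, _grid(cell=0.25))
        with pytest.raises(ValueError, match="mismatch"):
            combine([g1, g2])

    def test_total_conflict_rejected(self):
        spec = GridSpec(origin=Point2D(0, 0), cell_size=1.0, n_rows=3, n_cols=3)
        a = np.zeros((3, 3)); a[0, 0] = 1.0
        b = np.zeros((3, 3)); b[2, 2] = 1.0
        g1 = DensityGrid(spec, a).normalize()
        g2 = DensityGrid(spec, b).normalize()
        with pytest.raises(ValueError, match="conflict"):
            combine([g1, g2])

    def test_two_rings_peak_at_circle_intersections(self, gaussian_params):
        # landmarks 8 apart, ridge radius 6: the product must peak at the
        # analytic circle intersections (0, +-sqrt(20))
        spec = _grid(half=14.5, cell=0.2)
        g1 = ring_density(Point2D(-4, 0), gaussian_params, spec)
        g2 = ring_density(Point2D(4, 0), gaussian_params, spec)
        s = summarize_density(combine([g1, g2]), Point2D(0, 0))
        p, q = circle_intersections(Point2D(-4, 0), 6.0, Point2D(4, 0), 6.0)
        targets = sorted([(p.x, p.y), (q.x, q.y)], key=lambda t: t[1])
        assert abs(targets[1][1] - math.sqrt(20.0)) < 1e-12
        assert s.modality == "bimodal"
        found = sorted([(m.x, m.y) for m in s.modes], key=lambda t: t[1])
        for (fx, fy), (tx, ty) in zip(found, targets):
            assert math.hypot(fx - tx, fy - ty) <= spec.cell_size


class TestPredictConfiguration:
    def test_three_landmarks_unimodal_at_home(self, gaussian_params, visual_3lm):
        s = predict_configuration(visual_3lm, gaussian_params)
        assert s.modality == "unimodal"
        assert s.mle_accuracy <= gaussian_params.sigma_center / 5.0  # one cell

    def test_two_landmarks_bimodal_at_ring_intersections(self, gaussian_params):
        cfg = exp1_configuration("visual", 2)
        s = predict_configuration(cfg, gaussian_params)
        assert s.modality == "bimodal"
        l1, l2 = cfg.test_landmarks
        p, q = circle_intersections(l1, 6.0, l2, 6.0)
        cell = gaussian_params.sigma_center / 5.0
        dists = sorted(
            min(m.distance_to(p), m.distance_to(q)) for m in s.modes
        )
        assert all(d <= cell for d in dists)

    def test_single_landmark_accuracy_matches_quadrature(self, gaussian_params,
                                                         visual_1lm):
        # independent oracle: polar quadrature of the continuous ring
        # density over the same workspace
        s = predict_configuration(visual_1lm, gaussian_params)
        spec = default_grid_spec(visual_1lm, gaussian_params)
        xmin, xmax, ymin, ymax = spec.bounds
        L = visual_1lm.test_landmarks[0]
        rho = np.linspace(0.0, 6.0 + 6.0, 2001)
        th = np.linspace(0.0, 2 * np.pi, 2001)
        R, T = np.meshgrid(rho, th)
        X, Y = L.x + R * np.cos(T), L.y + R * np.sin(T)
        inside = (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
        W = np.exp(-((R - 6.0) ** 2) / 2.0) * R * inside
        D = np.hypot(X, Y)
        z = np.trapezoid(np.trapezoid(W, rho, axis=1), th)
        oracle = np.trapezoid(np.trapezoid(W * D, rho, axis=1), th) / z
        assert s.expected_accuracy == pytest.approx(oracle, rel=1e-3)

    def test_summary_matches_brute_force_summation(self, gaussian_params,
                                                   visual_3lm):
        # oracle equivalence: argmax and moments recomputed by direct
        # per-cell summation, independent of the summary implementation
        density = predicted_density(visual_3lm, gaussian_params)
        s = summarize_density(density, visual_3lm.home)
        p = density.values * density.cell_area
        xs = density.spec.x_centers
        ys = density.spec.y_centers
        best, best_val = None, -1.0
        mean = np.zeros(2)
        acc = 0.0
        for i in range(density.spec.n_rows):
            for j in range(density.spec.n_cols):
                if density.values[i, j] > best_val:
                    best_val, best = density.values[i, j], (xs[j], ys[i])
                mean += p[i, j] * np.array([xs[j], ys[i]])
                acc += p[i, j] * math.hypot(xs[j], ys[i])
        cov = np.zeros((2, 2))
        for i in range(density.spec.n_rows):
            for j in range(density.spec.n_cols):
                d = np.array([xs[j], ys[i]]) - mean
                cov += p[i, j] * np.outer(d, d)
        assert (s.mle.x, s.mle.y) == best
        assert s.expected_accuracy == pytest.approx(acc, abs=1e-9)
        np.testing.assert_allclose(s.covariance, cov, atol=1e-9)
        assert s.total_variance == pytest.approx(np.trace(cov), abs=1e-9)
        assert s.ellipse_area_95 == pytest.approx(
            math.pi * 5.991464547107979 * math.sqrt(np.linalg.det(cov)), abs=1e-9
        )

    def test_modes_contain_mle(self, mixture_params):
        cfg = relocate(exp2_base_configuration(), 6.0)
        s = predict_configuration(cfg, mixture_params)
        assert any(m == s.mle for m in s.modes)

    def test_mirror_symmetry(self, gaussian_params):
        # reflecting the configuration about the x axis reflects the modes
        # and leaves every scalar summary unchanged
        cfg = LandmarkConfiguration(
            home=Point2D(0, 0),
            training_landmarks=(Point2D(2, 3), Point2D(-3, 4)),
            test_landmarks=(Point2D(2, 3), Point2D(-3, 4)),
        )
        params = RidgeParams(ridge_radius=5.0, sigma_center=1.0, variant="gaussian")
        refl = LandmarkConfiguration(
            home=Point2D(0, 0),
            training_landmarks=(Point2D(2, -3), Point2D(-3, -4)),
            test_landmarks=(Point2D(2, -3), Point2D(-3, -4)),
        )
        s0 = predict_configuration(cfg, params)
        s1 = predict_configuration(refl, params)
        assert s0.expected_accuracy == pytest.approx(s1.expected_accuracy, abs=1e-9)
        assert s0.total_variance == pytest.approx(s1.total_variance, abs=1e-9)
        assert s0.ellipse_area_95 == pytest.approx(s1.ellipse_area_95, abs=1e-9)
        m0 = sorted((m.x, -m.y) for m in s0.modes)
        m1 = sorted((m.x, m.y) for m in s1.modes)
        np.testing.assert_allclose(m0, m1, atol=1e-9)


class TestVarianceAndAccuracyMonotonicity:
    @pytest.mark.parametrize("geometry", ["auditory", "visual"])
    def test_more_landmarks_tighter_and_more_accurate(self, geometry):
        r = {"auditory": 2.0, "visual": 6.0}[geometry]
        params = RidgeParams(ridge_radius=r, sigma_center=r / 6.0, variant="gaussian")
        summaries = [
            predict_configuration(exp1_configuration(geometry, n), params)
            for n in (1, 2, 3)
        ]
        accs = [s.expected_accuracy for s in summaries]
        variances = [s.total_variance for s in summaries]
        assert accs[0] > accs[1] > accs[2]
        assert variances[0] > variances[1] > variances[2]


class TestRelocationSweep:
    def test_zero_relocation_identity(self, mixture_params):
        base = exp2_base_configuration()
        recs = relocation_sweep(base, [0.0], mixture_params)
        for rec in recs:
            direct = predict_configuration(
                base, mixture_params.with_variant(rec["variant"])
            )
            s = rec["summary"]
            assert s.expected_accuracy == direct.expected_accuracy
            assert (s.mle.x, s.mle.y) == (direct.mle.x, direct.mle.y)

    def test_relocation_moves_deviant_orthogonally(self):
        base = exp2_base_configuration()
        cfg = relocate(base, 1.5)
        moved = cfg.test_landmarks[0]
        orig = base.training_landmarks[0]
        assert moved.x == pytest.approx(orig.x, abs=1e-9)
        assert moved.y == pytest.approx(orig.y + 1.5, abs=1e-9)
        # the other two stay put and training geometry is untouched
        assert cfg.test_landmarks[1:] == base.training_landmarks[1:]
        assert cfg.training_landmarks == base.training_landmarks

    def test_gaussian_tracks_mixture_jumps(self, mixture_params):
        # the plain Gaussian MLE follows the shifted compromise point for
        # every relocation; the heavy-tailed variant abandons it and
        # returns near the stationary-pair intersection (the trained home)
        base = exp2_base_configuration()
        recs = relocation_sweep(base, [0.0, 1.5, 3.0, 4.5, 6.0], mixture_params)
        sig = mixture_params.sigma_center
        jumps = []
        for rec in recs:
            cp = compromise_point(rec["config"], mixture_params.ridge_radius)
            d_cp = rec["summary"].mle.distance_to(cp)
            if rec["variant"] == "gaussian":
                assert d_cp <= 2 * sig
            else:
                jumps.append((rec["relocation"], d_cp > 2 * sig))
        assert any(flag for _, flag in jumps)

    def test_retained_mode_dominates_mirror(self, mixture_params):
        # after breakdown the mode on the deviant landmark's side carries
        # more density than its mirror below the stationary pair
        from landmark_homing import stationary_pair_intersections

        base = exp2_base_configuration()
        recs = relocation_sweep(base, [6.0], mixture_params, variants=("mixture",))
        s = recs[0]["summary"]
        near, far = stationary_pair_intersections(recs[0]["config"])
        assert s.modality == "bimodal"
        by_side = sorted(
            zip(s.modes, s.mode_densities),
            key=lambda md: md[0].distance_to(near),
        )
        assert by_side[0][1] > by_side[1][1]

    def test_relocation_outside_fixed_grid_rejected(self, mixture_params):
        base = exp2_base_configuration()
        small = GridSpec(origin=Point2D(-8, -8), cell_size=0.2, n_rows=81, n_cols=81)
        with pytest.raises(ValueError, match="outside the grid"):
            relocation_sweep(base, [6.0], mixture_params, grid_spec=small)


def test_circle_intersections_oracle():
    p, q = circle_intersections(Point2D(-4, 0), 6.0, Point2D(4, 0), 6.0)
    ys = sorted([p.y, q.y])
    assert ys[0] == pytest.approx(-math.sqrt(20.0), abs=1e-12)
    assert ys[1] == pytest.approx(math.sqrt(20.0), abs=1e-12)
    with pytest.raises(ValueError):
        circle_intersections(Point2D(0, 0), 1.0, Point2D(10, 0), 1.0)
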