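"""Ring-likelihood construction: profiles, grids, symmetry, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landmark_homing import (
    DensityGrid,
    GridSpec,
    LandmarkConfiguration,
    Point2D,
    RidgeParams,
    default_grid_spec,
    radial_profile,
    ring_density,
    tail_sigma,
)


class TestRadialProfile:
    @pytest.mark.parametrize(
        "d, variant, expected",
        [
            (6.0, "gaussian", 1.0),  # ridge peak
            (7.0, "gaussian", math.exp(-0.5)),  # one-sigma ratio
            (6.0, "mixture", 1.12),  # both components peak at the ridge
        ],
    )
    def test_profile_values(self, d, variant, expected):
        params = RidgeParams(ridge_radius=6.0, sigma_center=1.0, variant=variant)
        assert radial_profile(d, params) == pytest.approx(expected, abs=1e-12)

    def test_far_tail_decays(self, mixture_params):
        d = mixture_params.ridge_radius + 8 * mixture_params.sigma_tail
        peak = radial_profile(mixture_params.ridge_radius, mixture_params)
        assert radial_profile(d, mixture_params) < 1e-10 * peak

    def test_negative_distance_rejected(self, gaussian_params):
        with pytest.raises(ValueError):
            radial_profile(-0.1, gaussian_params)

    def test_central_component_dominates_near_ridge(self):
        # tail_amplitude 0.12, sigma_tail = 10 sigma_center: within one
        # sigma of the ridge the central Gaussian carries >= 80% of the profile
        params = RidgeParams(
            ridge_radius=6.0, sigma_center=1.0, sigma_tail=10.0,
            tail_amplitude=0.12, variant="mixture",
        )
        for d in np.linspace(5.0, 7.0, 41):
            total = radial_profile(d, params)
            central = math.exp(-((d - 6.0) ** 2) / 2.0)
            assert central / total >= 0.8

    def test_gaussian_limit_of_mixture(self):
        gauss = RidgeParams(ridge_radius=6.0, sigma_center=1.0, variant="gaussian")
        almost = RidgeParams(
            ridge_radius=6.0, sigma_center=1.0, sigma_tail=10.0,
            tail_amplitude=1e-15, variant="mixture",
        )
        d = np.linspace(0.0, 20.0, 501)
        np.testing.assert_allclose(
            radial_profile(d, almost), radial_profile(d, gauss), atol=1e-12
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RidgeParams(ridge_radius=-1.0, sigma_center=1.0)
        with pytest.raises(ValueError):
            RidgeParams(ridge_radius=6.0, sigma_center=0.0)
        with pytest.raises(ValueError):
            # mixture needs sigma_tail > sigma_center
            RidgeParams(ridge_radius=6.0, sigma_center=2.0, sigma_tail=1.0,
                        variant="mixture")
        with pytest.raises(ValueError):
            RidgeParams(ridge_radius=float("nan"), sigma_center=1.0)


class TestRingDensity:
    def _centered_grid(self, params, half_cells=80, cell=0.2):
        n = 2 * half_cells + 1
        origin = Point2D(-half_cells * cell, -half_cells * cell)
        return GridSpec(origin=origin, cell_size=cell, n_rows=n, n_cols=n)

    def test_normalization(self, gaussian_params):
        spec = self._centered_grid(gaussian_params)
        grid = ring_density(Point2D(0, 0), gaussian_params, spec)
        assert grid.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_rotational_symmetry_quarter_turns(self, gaussian_params):
        # a landmark at the grid center: 90-degree rotations map cell
        # centers to cell centers and must leave the density unchanged
        spec = self._centered_grid(gaussian_params)
        grid = ring_density(Point2D(0, 0), gaussian_params, spec)
        for k in (1, 2, 3):
            np.testing.assert_allclose(
                np.rot90(grid.values, k), grid.values, atol=1e-12
            )

    def test_equidistant_cells_equal_density(self, gaussian_params):
        spec = self._centered_grid(gaussian_params)
        grid = ring_density(Point2D(0, 0), gaussian_params, spec)
        xx, yy = spec.meshgrid()
        d = np.hypot(xx, yy)
        # mirror pairs across the x axis are exactly equidistant
        np.testing.assert_allclose(grid.values, grid.values[::-1, :], atol=1e-12)
        assert d.shape == grid.values.shape

    def test_argmax_is_nearest_to_ridge(self, gaussian_params):
        # brute-force oracle: the densest cell must be a cell whose center
        # distance is (jointly) closest to the ridge radius
        spec = self._centered_grid(gaussian_params)
        grid = ring_density(Point2D(0, 0), gaussian_params, spec)
        xx, yy = spec.meshgrid()
        miss = np.abs(np.hypot(xx, yy) - gaussian_params.ridge_radius)
        best = np.argmax(grid.values)
        assert miss.ravel()[best] <= miss.min() + 1e-12

    def test_grid_too_small_errors_with_extent(self, gaussian_params):
        spec = GridSpec(origin=Point2D(-2, -2), cell_size=0.5, n_rows=9, n_cols=9)
        with pytest.raises(ValueError, match="needs to cover"):
            ring_density(Point2D(0, 0), gaussian_params, spec)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        dx=st.floats(-50, 50, allow_nan=False),
        dy=st.floats(-50, 50, allow_nan=False),
    )
    def test_translation_equivariance(self, dx, dy):
        # moving landmark and grid together leaves the density unchanged
        params = RidgeParams(ridge_radius=3.0, sigma_center=0.5, variant="gaussian")
        spec0 = GridSpec(origin=Point2D(-6, -6), cell_size=0.25, n_rows=49, n_cols=49)
        spec1 = GridSpec(
            origin=Point2D(-6 + dx, -6 + dy), cell_size=0.25, n_rows=49, n_cols=49
        )
        g0 = ring_density(Point2D(0, 0), params, spec0)
        g1 = ring_density(Point2D(dx, dy), params, spec1)
        np.testing.assert_allclose(g0.values, g1.values, rtol=0, atol=1e-9)


class TestGridAndConfigIO:
    def test_density_grid_roundtrip(self, tmp_path, gaussian_params, visual_1lm):
        spec = default_grid_spec(visual_1lm, gaussian_params)
        grid = ring_density(visual_1lm.test_landmarks[0], gaussian_params, spec)
        grid.save(tmp_path / "grid.csv")
        back = DensityGrid.load(tmp_path / "grid.csv")
        assert back.spec == grid.spec
        np.testing.assert_allclose(back.values, grid.values, rtol=1e-12)

    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_configuration_roundtrip(self, tmp_path, visual_3lm, ext):
        path = tmp_path / f"config.{ext}"
        visual_3lm.save(path)
        back = LandmarkConfiguration.load(path)
        assert back == visual_3lm

    def test_configuration_invariants(self):
        with pytest.raises(ValueError):
            LandmarkConfiguration(home=Point2D(0, 0), training_landmarks=(),
                                  test_landmarks=())
        with pytest.raises(ValueError):
            LandmarkConfiguration(
                home=Point2D(0, 0),
                training_landmarks=(Point2D(1, 0), Point2D(0, 1)),
                test_landmarks=(Point2D(1, 0),),
            )


def test_tail_sigma_readings():
    # "ten times" can be read on the sigma or the variance scale; both are
    # floored so the pedestal stays near-flat over the workspace
    assert tail_sigma(2.0, factor=10, scale="sigma", floor=0.0) == 20.0
    assert tail_sigma(2.0, factor=10, scale="variance", floor=0.0) == pytest.approx(
        2.0 * math.sqrt(10.0)
    )
    assert tail_sigma(0.5, factor=10, scale="sigma", floor=10.0) == 10.0


def test_default_grid_covers_all_ridges(mixture_params):
    # a relocated landmark far from home enlarges the workspace so its
    # central ridge still fits
    cfg = LandmarkConfiguration(
        home=Point2D(0, 0),
        training_landmarks=(Point2D(0, 6), Point2D(-5.2, -3), Point2D(5.2, -3)),
        test_landmarks=(Point2D(0, 12), Point2D(-5.2, -3), Point2D(5.2, -3)),
    )
    spec = default_grid_spec(cfg, mixture_params)
    ring_density(Point2D(0, 12), mixture_params, spec)  # must not raise
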