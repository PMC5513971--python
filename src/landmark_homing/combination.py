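"""Multiplicative cue combination and maximum-likelihood prediction.

Per-landmark ring likelihoods are combined by pointwise multiplication;
the maximum of the normalized product is the maximum-likelihood estimate
of the home position.  From the product density we read off the paper
quantities of interest for a homing experiment:

* accuracy - the expected distance to home under the predicted density
  (and, separately, the distance of the MLE itself to home);
* precision - the trace of the density's covariance, plus SD- and
  95%-covariance-ellipse areas;
* modality - the number of well-separated density peaks, which is what
  distinguishes integrated (unimodal) from broken-down (bimodal)
  predictions under cue conflict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .model_core import (
    DensityGrid,
    GridSpec,
    LandmarkConfiguration,
    Point2D,
    RidgeParams,
    default_grid_spec,
    ring_density,
)

__all__ = [
    "PredictionSummary",
    "combine",
    "summarize_density",
    "predict_configuration",
    "relocation_sweep",
    "circle_intersections",
]

# chi-square(2 df) quantile at 0.95; scales the covariance ellipse that
# contains 95% of a bivariate Gaussian.
CHI2_95_2DF = 5.991464547107979

#: Local density maxima below this fraction of the global maximum are not
#: counted as modes.
DEFAULT_MODE_THRESHOLD = 0.5


@dataclass
class PredictionSummary:
    """Model outputs for one landmark configuration."""

    mle: Point2D
    modes: list[Point2D]
    mode_densities: list[float]
    expected_accuracy: float
    mle_accuracy: float
    mean: Point2D
    covariance: np.ndarray
    total_variance: float
    sd_ellipse_area: float
    ellipse_area_95: float
    modality: str
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mle": [self.mle.x, self.mle.y],
            "modes": [[p.x, p.y] for p in self.modes],
            "mode_densities": list(self.mode_densities),
            "expected_accuracy": self.expected_accuracy,
            "mle_accuracy": self.mle_accuracy,
            "mean": [self.mean.x, self.mean.y],
            "covariance": self.covariance.tolist(),
            "total_variance": self.total_variance,
            "sd_ellipse_area": self.sd_ellipse_area,
            "ellipse_area_95": self.ellipse_area_95,
            "modality": self.modality,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _check_compatible(grids: Sequence[DensityGrid]) -> GridSpec:
    spec = grids[0].spec
    for g in grids[1:]:
        s = g.spec
        if (
            s.n_rows != spec.n_rows
            or s.n_cols != spec.n_cols
            or abs(s.cell_size - spec.cell_size) > 1e-9 * spec.cell_size
            or abs(s.origin.x - spec.origin.x) > 1e-9 * max(1.0, abs(spec.origin.x))
            or abs(s.origin.y - spec.origin.y) > 1e-9 * max(1.0, abs(spec.origin.y))
        ):
            raise ValueError("cannot combine grids with mismatched geometry")
    return spec


def combine(grids: Sequence[DensityGrid]) -> DensityGrid:
    """Pointwise product of densities, renormalized to integrate to one.

    The product is computed in log space so that deeply conflicting
    (nearly non-overlapping) likelihoods do not underflow before their
    overlap can be seen.  If the product is zero everywhere the cues are
    in total conflict and no estimate exists.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("need at least one grid to combine")
    spec = _check_compatible(grids)
    with np.errstate(divide="ignore"):
        log_prod = np.zeros((spec.n_rows, spec.n_cols))
        for g in grids:
            log_prod += np.log(g.values)
    peak = log_prod.max()
    if not np.isfinite(peak):
        raise ValueError("total conflict: combined density is zero everywhere")
    values = np.exp(log_prod - peak)
    return DensityGrid(spec, values).normalize()


def _find_modes(
    grid: DensityGrid, threshold: float
) -> tuple[list[tuple[int, int]], list[float]]:
    """Density peaks: 8-neighborhood local maxima above the threshold.

    A cell is a candidate if no 8-neighbor exceeds it and it reaches
    ``threshold`` x the global maximum.  Discretization plateaus (runs of
    equal-valued adjacent maxima) are deduplicated by 8-connected
    grouping, each group contributing one peak (ties broken at the lowest
    row-major index).  Distinct peaks stay distinct even when a
    sub-threshold-free saddle channel connects their surroundings.
    """
    vmax = grid.values.max()
    neighborhood_max = ndimage.maximum_filter(grid.values, size=3, mode="constant")
    is_max = (grid.values >= neighborhood_max) & (grid.values >= threshold * vmax)
    labels, n_comp = ndimage.label(is_max, structure=np.ones((3, 3), dtype=int))
    peaks: list[tuple[int, int]] = []
    dens: list[float] = []
    for comp in range(1, n_comp + 1):
        idx = np.flatnonzero(labels.ravel() == comp)
        comp_vals = grid.values.ravel()[idx]
        best = idx[np.argmax(comp_vals)]  # argmax returns first max: lowest row-major
        peaks.append((best // grid.spec.n_cols, best % grid.spec.n_cols))
        dens.append(float(grid.values.ravel()[best]))
    order = np.argsort([-d for d in dens], kind="stable")
    return [peaks[i] for i in order], [dens[i] for i in order]


def summarize_density(
    grid: DensityGrid,
    home: Point2D,
    mode_threshold: float = DEFAULT_MODE_THRESHOLD,
    label: str = "",
) -> PredictionSummary:
    """Accuracy, precision, and modality read off a normalized density."""
    if not grid.normalized:
        grid = grid.normalize()
    p = grid.cell_probabilities()
    xx, yy = grid.spec.meshgrid()

    flat_idx = int(np.argmax(grid.values))  # lowest row-major index on ties
    mle = Point2D(xx.ravel()[flat_idx], yy.ravel()[flat_idx])

    mean_x = float(np.sum(p * xx))
    mean_y = float(np.sum(p * yy))
    dx, dy = xx - mean_x, yy - mean_y
    cov = np.array(
        [
            [float(np.sum(p * dx * dx)), float(np.sum(p * dx * dy))],
            [float(np.sum(p * dx * dy)), float(np.sum(p * dy * dy))],
        ]
    )
    dist_home = np.hypot(xx - home.x, yy - home.y)
    expected_accuracy = float(np.sum(p * dist_home))
    total_variance = float(np.trace(cov))
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    sd_ellipse_area = float(math.pi * math.sqrt(eigvals[0] * eigvals[1]))
    ellipse_area_95 = float(math.pi * CHI2_95_2DF * math.sqrt(max(np.linalg.det(cov), 0.0)))

    mode_idx, mode_dens = _find_modes(grid, mode_threshold)
    modes = [
        Point2D(grid.spec.x_centers[c], grid.spec.y_centers[r]) for r, c in mode_idx
    ]
    modality = {1: "unimodal", 2: "bimodal"}.get(len(modes), "multimodal")
    return PredictionSummary(
        mle=mle,
        modes=modes,
        mode_densities=mode_dens,
        expected_accuracy=expected_accuracy,
        mle_accuracy=home.distance_to(mle),
        mean=Point2D(mean_x, mean_y),
        covariance=cov,
        total_variance=total_variance,
        sd_ellipse_area=sd_ellipse_area,
        ellipse_area_95=ellipse_area_95,
        modality=modality,
        label=label,
    )


def predicted_density(
    config: LandmarkConfiguration,
    params: RidgeParams,
    grid_spec: GridSpec | None = None,
) -> DensityGrid:
    """Product of the per-landmark ring likelihoods for a configuration.

    Rings are centred on the *test* positions but keep the remembered
    (fitted) home-landmark distance: a relocated landmark still evokes
    the ridge radius learned at training time.
    """
    if grid_spec is None:
        grid_spec = default_grid_spec(config, params)
    rings = [ring_density(lm, params, grid_spec) for lm in config.test_landmarks]
    return combine(rings)


def predict_configuration(
    config: LandmarkConfiguration,
    params: RidgeParams,
    grid_spec: GridSpec | None = None,
    mode_threshold: float = DEFAULT_MODE_THRESHOLD,
) -> PredictionSummary:
    """Parameter-free model prediction for one configuration."""
    if grid_spec is None:
        grid_spec = default_grid_spec(config, params)
    density = predicted_density(config, params, grid_spec)
    return summarize_density(density, config.home, mode_threshold, label=config.label)


def relocate(
    config: LandmarkConfiguration, relocation: float, deviant_index: int = 0
) -> LandmarkConfiguration:
    """Move one landmark outward, orthogonally to the other two.

    The deviant landmark's test position is displaced along the direction
    perpendicular to the line through the remaining two landmarks, on the
    deviant landmark's side (i.e. away from the stationary pair).
    Training positions are untouched.
    """
    if config.n_landmarks != 3:
        raise ValueError("relocation requires a 3-landmark configuration")
    deviant_index = deviant_index % 3
    others = [p for i, p in enumerate(config.training_landmarks) if i != deviant_index]
    base = config.training_landmarks[deviant_index]
    along = others[1].as_array() - others[0].as_array()
    normal = np.array([-along[1], along[0]])
    normal /= np.linalg.norm(normal)
    midpoint = (others[0].as_array() + others[1].as_array()) / 2.0
    if np.dot(normal, base.as_array() - midpoint) < 0:
        normal = -normal
    moved = base.as_array() + relocation * normal
    test = list(config.training_landmarks)
    test[deviant_index] = Point2D(moved[0], moved[1])
    return LandmarkConfiguration(
        home=config.home,
        training_landmarks=config.training_landmarks,
        test_landmarks=tuple(test),
        label=f"{config.label}+reloc{relocation:g}" if config.label else f"reloc{relocation:g}",
    )


def relocation_sweep(
    base_config: LandmarkConfiguration,
    relocations: Sequence[float],
    params: RidgeParams,
    grid_spec: GridSpec | None = None,
    deviant_index: int = 0,
    variants: Sequence[str] = ("gaussian", "mixture"),
    mode_threshold: float = DEFAULT_MODE_THRESHOLD,
) -> list[dict]:
    """Predictions for a sweep of landmark relocations, for both variants.

    Returns one record per (relocation, variant) with the relocated
    configuration and its PredictionSummary.  If no grid is given, each
    relocated configuration gets the default grid for its own extent.
    """
    records = []
    for variant in variants:
        vparams = params.with_variant(variant)
        for delta in relocations:
            cfg = relocate(base_config, float(delta), deviant_index)
            if grid_spec is not None:
                for lm in cfg.test_landmarks:
                    if not grid_spec.contains(lm):
                        raise ValueError(
                            f"relocation {delta} moves the landmark to "
                            f"({lm.x:.3f}, {lm.y:.3f}), outside the grid {grid_spec.bounds}"
                        )
            summary = predict_configuration(cfg, vparams, grid_spec, mode_threshold)
            records.append(
                {
                    "relocation": float(delta),
                    "variant": variant,
                    "config": cfg,
                    "summary": summary,
                }
            )
    return records


def circle_intersections(
    c1: Point2D, r1: float, c2: Point2D, r2: float
) -> tuple[Point2D, Point2D]:
    """Intersection points of two circles (geometry oracle for ring products)."""
    d = c1.distance_to(c2)
    if d == 0 or d > r1 + r2 or d < abs(r1 - r2):
        raise ValueError("circles do not intersect at two points")
    a = (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r1**2 - a**2
    h = math.sqrt(max(h2, 0.0))
    ex = (c2.x - c1.x) / d
    ey = (c2.y - c1.y) / d
    px, py = c1.x + a * ex, c1.y + a * ey
    return (
        Point2D(px - h * ey, py + h * ex),
        Point2D(px + h * ey, py - h * ex),
    )
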