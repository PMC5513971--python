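"""Estimating ridge parameters from single-landmark homing endpoints.

The single-landmark condition is the calibration condition: endpoints are
converted to polar coordinates with the landmark at the origin and
collapsed over direction onto the distance axis, where a Gaussian is fit.
Its mean and standard deviation become the ridge radius and central
spread.  Multi-landmark and relocation conditions are then parameter-free
predictions; the pedestal parameters of the mixture variant are fixed by
convention, never fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_TAIL_AMPLITUDE,
    DEFAULT_TAIL_FACTOR,
    DEFAULT_TAIL_FLOOR,
    Point2D,
    RidgeParams,
    tail_sigma,
)

__all__ = [
    "EndpointSet",
    "polar_collapse",
    "fit_radial_gaussian",
    "fit_single_landmark_condition",
    "fit_per_participant",
]

ENDPOINT_COLUMNS = ["participant_id", "condition_id", "x", "y"]


@dataclass
class EndpointSet:
    """Homing endpoints tagged by participant and condition.

    Thin wrapper around a DataFrame with columns participant_id,
    condition_id, x, y.  ``provenance`` records whether the table holds
    empirical or synthetic data.
    """

    data: pd.DataFrame
    provenance: str = "empirical"

    def __post_init__(self) -> None:
        missing = [c for c in ENDPOINT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"endpoint table missing columns {missing}")
        if len(self.data) == 0:
            raise ValueError("endpoint set must contain at least one record")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("endpoint coordinates must be finite")
        if self.provenance not in ("empirical", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def points(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def participants(self) -> list[str]:
        return list(pd.unique(self.data["participant_id"]))

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.data["condition_id"]))

    def subset(self, participant_id=None, condition_id=None) -> "EndpointSet":
        df = self.data
        if participant_id is not None:
            df = df[df["participant_id"] == participant_id]
        if condition_id is not None:
            df = df[df["condition_id"] == condition_id]
        if len(df) == 0:
            raise ValueError(
                f"no endpoints for participant={participant_id!r} condition={condition_id!r}"
            )
        return EndpointSet(df.reset_index(drop=True), provenance=self.provenance)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]], provenance: str = "empirical"
    ) -> "EndpointSet":
        df = pd.DataFrame(records, columns=ENDPOINT_COLUMNS)
        return cls(df, provenance=provenance)

    def save(self, path: str | Path) -> None:
        self.data[ENDPOINT_COLUMNS].to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, provenance: str = "empirical") -> "EndpointSet":
        return cls(pd.read_csv(path, dtype={"participant_id": str, "condition_id": str}),
                   provenance=provenance)


def polar_collapse(endpoints: EndpointSet, landmark: Point2D) -> np.ndarray:
    """Distances of every endpoint to the landmark (order-preserving).

    This is the polar-coordinate collapse: with the landmark at the
    origin, the angular coordinate is discarded and only the radial one
    kept.
    """
    pts = endpoints.points()
    return np.hypot(pts[:, 0] - landmark.x, pts[:, 1] - landmark.y)


def fit_radial_gaussian(distances) -> tuple[float, float]:
    """Fit a Gaussian on the collapsed distance axis.

    Returns (mean, SD) of the distances with the n-1 denominator; the
    mean estimates the ridge radius and the SD the central spread.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) < 3:
        raise ValueError(f"need at least 3 distances to fit, got {d.size}")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError(
            "distances have zero spread; the radial Gaussian is degenerate "
            "(consider applying a sigma floor)"
        )
    return mean, sd


def _invert_ring_moments(m: float, s: float) -> tuple[float, float]:
    """Ridge parameters whose ring density has collapsed moments (m, s).

    Collapsing a 2D ring density p(x, y) propto phi_sigma(d - r) onto the
    distance axis picks up the polar area element, so distances follow
    phi_sigma(d - r) * d with mean r + sigma^2/r and variance
    sigma^2 - sigma^4/r^2.  Reading the sample mean/SD directly as
    (r, sigma) therefore overestimates the radius by sigma^2/r; this
    fixed-point inversion removes that tilt (it converges in a few steps
    whenever sigma << r, and falls back to the raw moments otherwise).
    """
    r, var = m, s**2
    for _ in range(8):
        var_new = s**2 + var**2 / r**2
        r_new = m - var_new / r
        if r_new <= 0 or var_new >= r_new**2:  # tilt beyond the model's regime
            return m, s
        r, var = r_new, var_new
    return r, math.sqrt(var)


def fit_single_landmark_condition(
    endpoints: EndpointSet,
    landmark: Point2D,
    variant: str = "gaussian",
    tail_amplitude: float = DEFAULT_TAIL_AMPLITUDE,
    tail_factor: float = DEFAULT_TAIL_FACTOR,
    tail_scale: str = "sigma",
    tail_floor: float = DEFAULT_TAIL_FLOOR,
    tail_amplitude_mode: str = "peak",
    sigma_floor: float = 0.0,
    jacobian_correction: bool = True,
) -> RidgeParams:
    """Calibrate ridge parameters from one-landmark endpoints.

    Pools all records (collapse, then mean/SD), then - by default -
    applies the polar-Jacobian consistency correction so the parameters
    describe the 2D ring density the endpoints were scattered from rather
    than the tilted 1D distance distribution.  The pedestal parameters
    are attached by rule, not fit: sigma_tail = tail_factor * sigma_center
    (floored so the pedestal is near-flat over the workspace) and a fixed
    peak-amplitude ratio.
    """
    radius, sigma = fit_radial_gaussian(polar_collapse(endpoints, landmark))
    if jacobian_correction:
        radius, sigma = _invert_ring_moments(radius, sigma)
    sigma = max(sigma, sigma_floor)
    if variant == "gaussian":
        return RidgeParams(ridge_radius=radius, sigma_center=sigma, variant="gaussian")
    return RidgeParams(
        ridge_radius=radius,
        sigma_center=sigma,
        sigma_tail=tail_sigma(sigma, factor=tail_factor, scale=tail_scale, floor=tail_floor),
        tail_amplitude=tail_amplitude,
        variant="mixture",
        tail_amplitude_mode=tail_amplitude_mode,
    )


def fit_per_participant(
    endpoints: EndpointSet, landmark: Point2D, **kwargs
) -> dict[str, RidgeParams]:
    """One ridge fit per participant (used for the slope-style analyses)."""
    return {
        pid: fit_single_landmark_condition(endpoints.subset(participant_id=pid), landmark, **kwargs)
        for pid in endpoints.participants
    }


def save_params(params: RidgeParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def load_params(path: str | Path) -> RidgeParams:
    return RidgeParams.from_dict(json.loads(Path(path).read_text()))
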