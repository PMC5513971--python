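"""Empirical summaries and model-vs-data comparisons.

Accuracy is the mean Euclidean distance of responses to the home
location; precision is the spread of responses around their own mean -
reported as the trace of the sample covariance, the SD-ellipse area
(pi * sigma_major * sigma_minor), and the 95% covariance-ellipse area
(pi * chi2_{2,0.95} * sqrt(det Sigma)).  Per-participant regression
slopes of accuracy (or variance) against the number of landmarks, and
one-sample / paired t-tests, mirror the standard analysis of this kind
of homing experiment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .combination import CHI2_95_2DF
from .fitting import EndpointSet
from .model_core import Point2D

__all__ = [
    "empirical_accuracy",
    "empirical_precision",
    "slope_per_participant",
    "slope_ttest",
    "paired_model_vs_data",
]


def empirical_accuracy(endpoints: EndpointSet, home: Point2D) -> float:
    """Mean distance of all responses from the home location."""
    pts = endpoints.points()
    return float(np.mean(np.hypot(pts[:, 0] - home.x, pts[:, 1] - home.y)))


def empirical_precision(endpoints: EndpointSet) -> tuple[float, float, float]:
    """(total_variance, sd_ellipse_area, ellipse_area_95) of the response cloud.

    Uses the sample covariance (n-1 denominator).  Collinear clouds have
    a zero-determinant covariance and hence zero ellipse areas.
    """
    pts = endpoints.points()
    if len(pts) < 3:
        raise ValueError("precision needs at least 3 points")
    cov = np.cov(pts.T, ddof=1)
    total_variance = float(np.trace(cov))
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    sd_ellipse_area = float(math.pi * math.sqrt(eigvals[0] * eigvals[1]))
    ellipse_area_95 = float(math.pi * CHI2_95_2DF * math.sqrt(max(np.linalg.det(cov), 0.0)))
    return total_variance, sd_ellipse_area, ellipse_area_95


def slope_per_participant(
    endpoints: EndpointSet,
    home: Point2D,
    condition_counts: dict[str, int],
    measure: str = "accuracy",
) -> pd.Series:
    """OLS slope of a per-condition summary vs. number of landmarks.

    ``condition_counts`` maps condition ids to landmark counts (e.g.
    {"lm1": 1, "lm2": 2, "lm3": 3}).  For each participant the summary
    (mean distance to home, or total variance) is computed per condition
    and a straight line is fit to the (count, summary) pairs; the series
    of slopes is indexed by participant.
    """
    if measure not in ("accuracy", "variance"):
        raise ValueError(f"unknown measure {measure!r}")
    slopes = {}
    for pid in endpoints.participants:
        counts, values = [], []
        for cond, n_lm in condition_counts.items():
            try:
                sub = endpoints.subset(participant_id=pid, condition_id=cond)
            except ValueError:
                raise ValueError(f"participant {pid!r} is missing condition {cond!r}")
            if measure == "accuracy":
                values.append(empirical_accuracy(sub, home))
            else:
                values.append(empirical_precision(sub)[0])
            counts.append(n_lm)
        slopes[pid] = float(np.polyfit(counts, values, 1)[0])
    return pd.Series(slopes, name=f"slope_{measure}")


def _one_sample_t(values: np.ndarray, alternative: str) -> tuple[float, float]:
    n = values.size
    if n < 2:
        raise ValueError("t-test needs at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0.0:
        if values.mean() == 0.0:
            # no effect and no variability: conventionally t = 0, p = 1
            return 0.0, 1.0
        raise ValueError(
            "t statistic undefined: values have zero variance but a nonzero mean"
        )
    res = sps.ttest_1samp(values, popmean=0.0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def slope_ttest(slopes, alternative: str = "two-sided") -> tuple[float, float]:
    """One-sample t-test of regression slopes against zero (df = n - 1)."""
    return _one_sample_t(np.asarray(slopes, dtype=float), alternative)


def paired_model_vs_data(
    model_values, data_values, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired t-test on the hypothesis that model - data differences are zero."""
    model = np.asarray(model_values, dtype=float)
    data = np.asarray(data_values, dtype=float)
    if model.shape != data.shape:
        raise ValueError("model and data value lists must have equal length")
    return _one_sample_t(model - data, alternative)
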