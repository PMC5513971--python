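"""End-to-end experiment loops: simulate -> fit -> predict -> compare.

Both loops follow the same logic as the behavioral study: every model
parameter is calibrated on the single-landmark condition only, and the
multi-landmark and relocation conditions are parameter-free predictions
that are then compared against the (here: synthetic) data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import designs
from .combination import (
    PredictionSummary,
    predict_configuration,
    relocation_sweep,
)
from .fitting import (
    EndpointSet,
    fit_per_participant,
    fit_single_landmark_condition,
)
from .model_core import LandmarkConfiguration, Point2D, RidgeParams
from .stats import (
    empirical_accuracy,
    empirical_precision,
    paired_model_vs_data,
    slope_per_participant,
    slope_ttest,
)
from .synthetic import generate_experiment1, generate_experiment2

__all__ = [
    "Experiment1Result",
    "Experiment2Result",
    "run_experiment1",
    "run_experiment2",
    "compromise_point",
    "detect_breakdown",
]

EXP1_CONDITION_COUNTS = {"lm1": 1, "lm2": 2, "lm3": 3}
VARIANTS = ("gaussian", "mixture")


def compromise_point(config: LandmarkConfiguration, ridge_radius: float) -> Point2D:
    """Least-squares intersection of the remembered distance constraints.

    The point minimizing sum_i (||p - L_i|| - r)^2 over the test
    landmarks: the integrated ("weighted average") home estimate that a
    plain Gaussian observer converges to.  Serves as a model-independent
    reference for where the shifted configuration center lies.
    """
    landmarks = np.array([[lm.x, lm.y] for lm in config.test_landmarks])

    def cost(p):
        d = np.hypot(landmarks[:, 0] - p[0], landmarks[:, 1] - p[1])
        return np.sum((d - ridge_radius) ** 2)

    x0 = np.array([config.home.x, config.home.y])
    res = optimize.minimize(cost, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    return Point2D(float(res.x[0]), float(res.x[1]))


@dataclass
class Experiment1Result:
    endpoints: EndpointSet
    metadata: dict
    pooled_params: dict[str, RidgeParams]
    per_participant_params: dict[str, dict[str, RidgeParams]]
    condition_summary: pd.DataFrame
    participant_summary: pd.DataFrame
    slopes: pd.DataFrame
    tests: pd.DataFrame
    predictions: dict[tuple[str, str], PredictionSummary]


def run_experiment1(
    seed: int = 0,
    geometry: str = "visual",
    n_participants: int = 10,
    trials_per_condition: int = 40,
    sigma_base: float = 1.0,
    sigma_dispersion: float = 0.2,
    generator_variant: str = "gaussian",
    endpoints: EndpointSet | None = None,
    metadata: dict | None = None,
) -> Experiment1Result:
    """The number-of-landmarks experiment, end to end.

    Simulates the three conditions (unless an endpoint table is passed
    in), fits ridge parameters from the 1-landmark condition - pooled
    across participants for the headline prediction, and per participant
    for the slope and paired analyses - then predicts accuracy and
    precision for all conditions under both model variants and compares
    them with the empirical summaries.
    """
    if endpoints is None:
        endpoints, metadata = generate_experiment1(
            geometry=geometry,
            n_participants=n_participants,
            trials_per_condition=trials_per_condition,
            sigma_base=sigma_base,
            sigma_dispersion=sigma_dispersion,
            seed=seed,
            variant=generator_variant,
        )
    metadata = metadata or {}
    home = Point2D(0.0, 0.0)
    landmark = designs.exp1_configuration(geometry, 1).test_landmarks[0]
    calib = endpoints.subset(condition_id="lm1")

    pooled = {
        v: fit_single_landmark_condition(calib, landmark, variant=v) for v in VARIANTS
    }
    per_part = {
        v: fit_per_participant(calib, landmark, variant=v) for v in VARIANTS
    }

    predictions: dict[tuple[str, str], PredictionSummary] = {}
    cond_rows = []
    for cond, n_lm in EXP1_CONDITION_COUNTS.items():
        config = designs.exp1_configuration(geometry, n_lm)
        sub = endpoints.subset(condition_id=cond)
        tv, sd_area, area95 = empirical_precision(sub)
        row = {
            "condition": cond,
            "n_landmarks": n_lm,
            "empirical_accuracy": empirical_accuracy(sub, home),
            "empirical_variance": tv,
            "empirical_ellipse_area_95": area95,
        }
        for v in VARIANTS:
            summary = predict_configuration(config, pooled[v])
            predictions[(cond, v)] = summary
            row[f"{v}_accuracy"] = summary.expected_accuracy
            row[f"{v}_variance"] = summary.total_variance
            row[f"{v}_modality"] = summary.modality
        cond_rows.append(row)
    condition_summary = pd.DataFrame(cond_rows)

    # per-participant empirical summaries and per-participant (own-fit) predictions
    part_rows = []
    for pid in endpoints.participants:
        for cond, n_lm in EXP1_CONDITION_COUNTS.items():
            config = designs.exp1_configuration(geometry, n_lm)
            sub = endpoints.subset(participant_id=pid, condition_id=cond)
            tv, _, _ = empirical_precision(sub)
            row = {
                "participant_id": pid,
                "condition": cond,
                "n_landmarks": n_lm,
                "empirical_accuracy": empirical_accuracy(sub, home),
                "empirical_variance": tv,
            }
            for v in VARIANTS:
                summary = predict_configuration(config, per_part[v][pid])
                row[f"{v}_accuracy"] = summary.expected_accuracy
                row[f"{v}_variance"] = summary.total_variance
            part_rows.append(row)
    participant_summary = pd.DataFrame(part_rows)

    slope_acc = slope_per_participant(endpoints, home, EXP1_CONDITION_COUNTS, "accuracy")
    slope_var = slope_per_participant(endpoints, home, EXP1_CONDITION_COUNTS, "variance")
    slopes = pd.DataFrame({"accuracy": slope_acc, "variance": slope_var})

    test_rows = []
    t, p = slope_ttest(slope_acc.to_numpy())
    test_rows.append({"test": "slope_accuracy_vs_0", "condition": "all",
                      "t": t, "p": p, "df": len(slope_acc) - 1})
    t, p = slope_ttest(slope_var.to_numpy())
    test_rows.append({"test": "slope_variance_vs_0", "condition": "all",
                      "t": t, "p": p, "df": len(slope_var) - 1})
    # paired across participants: each participant's own parameter-free
    # prediction (from their single-landmark fit) against their empirical
    # summary, so fit noise is independent across pairs and enters the SE
    for v in VARIANTS:
        for cond in EXP1_CONDITION_COUNTS:
            sub = participant_summary[participant_summary["condition"] == cond]
            for measure in ("accuracy", "variance"):
                t, p = paired_model_vs_data(
                    sub[f"{v}_{measure}"].to_numpy(),
                    sub[f"empirical_{measure}"].to_numpy(),
                )
                test_rows.append(
                    {"test": f"{v}_model_vs_data_{measure}", "condition": cond,
                     "t": t, "p": p, "df": len(sub) - 1}
                )
    tests = pd.DataFrame(test_rows)

    return Experiment1Result(
        endpoints=endpoints,
        metadata=metadata,
        pooled_params=pooled,
        per_participant_params=per_part,
        condition_summary=condition_summary,
        participant_summary=participant_summary,
        slopes=slopes,
        tests=tests,
        predictions=predictions,
    )


@dataclass
class Experiment2Result:
    endpoints: EndpointSet
    metadata: dict
    pooled_params: dict[str, RidgeParams]
    sweep: pd.DataFrame
    sweep_records: list[dict]
    condition_summary: pd.DataFrame
    tests: pd.DataFrame
    breakdown_relocation: float | None


def sweep_table(records: list[dict]) -> pd.DataFrame:
    rows = []
    for rec in records:
        s: PredictionSummary = rec["summary"]
        rows.append(
            {
                "relocation": rec["relocation"],
                "variant": rec["variant"],
                "mle_x": s.mle.x,
                "mle_y": s.mle.y,
                "expected_accuracy": s.expected_accuracy,
                "mle_accuracy": s.mle_accuracy,
                "total_variance": s.total_variance,
                "sd_ellipse_area": s.sd_ellipse_area,
                "ellipse_area_95": s.ellipse_area_95,
                "modality": s.modality,
            }
        )
    return pd.DataFrame(rows)


def detect_breakdown(
    records: list[dict],
    params: RidgeParams,
    variant: str = "mixture",
    factor: float = 2.0,
) -> float | None:
    """Smallest relocation at which the MLE abandons the shifted center.

    Breakdown means the variant's MLE is within ``factor * sigma_center``
    of the stationary-pair ring intersection on the deviant landmark's
    side (i.e. near the trained home) while sitting more than that far
    from the integrated compromise location.  Returns None if the sweep
    never breaks down (the plain Gaussian variant by construction).
    """
    tol = factor * params.sigma_center
    for rec in sorted(
        (r for r in records if r["variant"] == variant), key=lambda r: r["relocation"]
    ):
        cfg = rec["config"]
        near, _far = designs.stationary_pair_intersections(cfg)
        center = compromise_point(cfg, params.ridge_radius)
        mle = rec["summary"].mle
        if mle.distance_to(near) <= tol and mle.distance_to(center) > tol:
            return rec["relocation"]
    return None


def run_experiment2(
    seed: int = 0,
    relocations=designs.RELOCATIONS,
    n_participants: int = 10,
    trials_per_condition: int = 40,
    sigma_base: float = 1.0,
    sigma_dispersion: float = 0.2,
    endpoints: EndpointSet | None = None,
    metadata: dict | None = None,
) -> Experiment2Result:
    """The relocation (cue-conflict) experiment, end to end.

    Simulates calibration plus relocation conditions, fits pooled ridge
    parameters from the calibration condition, runs the relocation sweep
    for both variants, and compares each variant's predicted accuracy and
    precision against the per-condition empirical summaries with paired
    t-tests across relocations.
    """
    if endpoints is None:
        endpoints, metadata = generate_experiment2(
            relocations=relocations,
            n_participants=n_participants,
            trials_per_condition=trials_per_condition,
            sigma_base=sigma_base,
            sigma_dispersion=sigma_dispersion,
            seed=seed,
        )
    metadata = metadata or {}
    home = Point2D(0.0, 0.0)
    landmark = designs.exp1_configuration("visual", 1).test_landmarks[0]
    calib = endpoints.subset(condition_id="lm1")
    pooled = {
        v: fit_single_landmark_condition(calib, landmark, variant=v) for v in VARIANTS
    }
    per_part = {v: fit_per_participant(calib, landmark, variant=v) for v in VARIANTS}

    base = designs.exp2_base_configuration()
    records = relocation_sweep(
        base, relocations, pooled["mixture"], deviant_index=designs.DEVIANT_INDEX
    )
    sweep = sweep_table(records)

    # model values for the data comparison: per-participant parameter-free
    # predictions (each from that participant's own calibration fit),
    # averaged across participants - the out-of-sample counterpart of the
    # pooled empirical cloud per condition
    cond_rows = []
    for rec in records:
        delta, variant = rec["relocation"], rec["variant"]
        cfg = rec["config"]
        sub = endpoints.subset(condition_id=f"reloc{delta:g}")
        tv, sd_area, area95 = empirical_precision(sub)
        s = rec["summary"]
        preds = [
            predict_configuration(cfg, per_part[variant][pid])
            for pid in endpoints.participants
        ]
        cond_rows.append(
            {
                "relocation": delta,
                "variant": variant,
                "empirical_accuracy": empirical_accuracy(sub, home),
                "empirical_variance": tv,
                "empirical_sd_ellipse_area": sd_area,
                "empirical_ellipse_area_95": area95,
                "model_accuracy": float(np.mean([p.expected_accuracy for p in preds])),
                "model_variance": float(np.mean([p.total_variance for p in preds])),
                "model_sd_ellipse_area": float(np.mean([p.sd_ellipse_area for p in preds])),
                "model_ellipse_area_95": float(np.mean([p.ellipse_area_95 for p in preds])),
                "pooled_model_accuracy": s.expected_accuracy,
                "pooled_model_variance": s.total_variance,
                "model_modality": s.modality,
            }
        )
    condition_summary = pd.DataFrame(cond_rows)

    test_rows = []
    for v in VARIANTS:
        sub = condition_summary[condition_summary["variant"] == v]
        for measure, model_col, data_col in (
            ("accuracy", "model_accuracy", "empirical_accuracy"),
            ("variance", "model_variance", "empirical_variance"),
            ("ellipse_area_95", "model_ellipse_area_95", "empirical_ellipse_area_95"),
        ):
            t, p = paired_model_vs_data(
                sub[model_col].to_numpy(), sub[data_col].to_numpy()
            )
            test_rows.append(
                {"test": f"{v}_model_vs_data_{measure}", "t": t, "p": p,
                 "df": len(sub) - 1}
            )
    tests = pd.DataFrame(test_rows)

    breakdown = detect_breakdown(records, pooled["mixture"], "mixture")

    return Experiment2Result(
        endpoints=endpoints,
        metadata=metadata,
        pooled_params=pooled,
        sweep=sweep,
        sweep_records=records,
        condition_summary=condition_summary,
        tests=tests,
        breakdown_relocation=breakdown,
    )
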