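"""Seeded synthetic-participant generator.

The study's behavioral endpoints are not public, so every downstream
stage is exercised on synthetic participants drawn from the model itself
(an ideal-observer generator): each participant gets an individual
central spread drawn from a lognormal population distribution, and their
endpoints for every condition are sampled from the model density of that
condition.  The generator emulates the statistical structure the analysis
assumes - a ring-shaped cloud for one landmark, bimodal clusters for two,
a unimodal cluster at the configuration center for three - not the
trajectories that produced it.

Participant streams are seed-isolated: participant k's rows depend only
on (seed, k), so any participant can be regenerated alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import designs
from .combination import predicted_density, relocate
from .fitting import ENDPOINT_COLUMNS, EndpointSet
from .model_core import (
    DensityGrid,
    LandmarkConfiguration,
    Point2D,
    RidgeParams,
    tail_sigma,
)

__all__ = [
    "sample_from_grid",
    "generate_experiment1",
    "generate_experiment2",
    "participant_rng",
]

#: Population median of the per-participant central spread (length units).
DEFAULT_SIGMA_BASE = 1.0
#: Lognormal dispersion (SD of log sigma) across participants.
DEFAULT_SIGMA_DISPERSION = 0.2

DEFAULT_N_PARTICIPANTS = 10
DEFAULT_TRIALS = 40


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_points(grid: DensityGrid, n: int, rng) -> np.ndarray:
    """Draw n points from a normalized density grid.

    A cell is drawn with probability equal to its mass, then the point is
    jittered uniformly within the cell.
    """
    if not grid.normalized:
        raise ValueError("sampling requires a normalized grid")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng)
    p = grid.cell_probabilities().ravel()
    p = p / p.sum()  # mop up rounding so probabilities sum to one exactly
    idx = rng.choice(p.size, size=n, p=p)
    rows, cols = idx // grid.spec.n_cols, idx % grid.spec.n_cols
    jitter = (rng.random((n, 2)) - 0.5) * grid.cell_size
    x = grid.spec.x_centers[cols] + jitter[:, 0]
    y = grid.spec.y_centers[rows] + jitter[:, 1]
    return np.column_stack([x, y])


def sample_from_grid(
    grid: DensityGrid,
    n: int,
    seed,
    participant_id: str = "p00",
    condition_id: str = "c0",
) -> EndpointSet:
    """EndpointSet wrapper around :func:`sample_points` (synthetic provenance)."""
    pts = sample_points(grid, n, seed)
    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "condition_id": condition_id,
            "x": pts[:, 0],
            "y": pts[:, 1],
        }
    )
    return EndpointSet(df, provenance="synthetic")


def participant_rng(seed: int, k: int) -> np.random.Generator:
    """Independent, reproducible stream for participant k under a master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(k),)))


def _participant_sigma(rng, sigma_base: float, sigma_dispersion: float) -> float:
    return float(sigma_base * np.exp(sigma_dispersion * rng.standard_normal()))


def _participant_params(
    sigma: float,
    radius: float,
    variant: str,
    tail_amplitude: float,
    tail_factor: float,
) -> RidgeParams:
    if variant == "gaussian":
        return RidgeParams(ridge_radius=radius, sigma_center=sigma, variant="gaussian")
    return RidgeParams(
        ridge_radius=radius,
        sigma_center=sigma,
        sigma_tail=tail_sigma(sigma, factor=tail_factor),
        tail_amplitude=tail_amplitude,
        variant="mixture",
    )


def _pair_subconfig(config: LandmarkConfiguration, drop: int) -> LandmarkConfiguration:
    keep = [i for i in range(config.n_landmarks) if i != drop]
    return LandmarkConfiguration(
        home=config.home,
        training_landmarks=tuple(config.training_landmarks[i] for i in keep),
        test_landmarks=tuple(config.test_landmarks[i] for i in keep),
        label=config.label + f"-pair{drop}",
    )


def generate_experiment1(
    geometry: str = "visual",
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    trials_per_condition: int = DEFAULT_TRIALS,
    sigma_base: float = DEFAULT_SIGMA_BASE,
    sigma_dispersion: float = DEFAULT_SIGMA_DISPERSION,
    seed: int = 0,
    variant: str = "gaussian",
    tail_amplitude: float = 0.12,
    tail_factor: float = 10.0,
    p_confusion: float = 0.0,
    participants: Sequence[int] | None = None,
) -> tuple[EndpointSet, dict]:
    """Synthetic endpoints for the 1/2/3-landmark experiment.

    Each participant's endpoints in condition ``lm{n}`` are drawn from
    the model density of the n-landmark layout with that participant's
    own spread.  The default generating variant is the plain Gaussian
    ridge: empirical no-conflict response clouds are clean rings and
    clusters, and the flat pedestal of the mixture variant is a device
    for predicting conflict behavior, not a feature of response scatter
    (a mixture-generated cloud would put over half its mass in a uniform
    halo, which also breaks the collapse-then-fit calibration).
    ``p_confusion`` optionally emulates the auditory
    segmentation failure in the 3-landmark condition: with that
    probability a trial is answered from a random landmark *pair* density
    instead (off by default).  ``participants`` restricts generation to a
    subset of participant indices without changing their streams.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if trials_per_condition < 1:
        raise ValueError("need at least 1 trial per condition")
    if not 0.0 <= p_confusion <= 1.0:
        raise ValueError("p_confusion must be in [0, 1]")
    radius = designs.landmark_radius(geometry)
    indices = range(n_participants) if participants is None else participants

    frames = []
    sigmas: dict[str, float] = {}
    for k in indices:
        rng = participant_rng(seed, k)
        pid = f"p{k:02d}"
        sigma = _participant_sigma(rng, sigma_base, sigma_dispersion)
        sigmas[pid] = sigma
        params = _participant_params(sigma, radius, variant, tail_amplitude, tail_factor)
        for n_lm in (1, 2, 3):
            config = designs.exp1_configuration(geometry, n_lm)
            density = predicted_density(config, params)
            pts = sample_points(density, trials_per_condition, rng)
            if p_confusion > 0.0 and n_lm == 3:
                confused = rng.random(trials_per_condition) < p_confusion
                n_conf = int(confused.sum())
                if n_conf:
                    pair_densities = [
                        predicted_density(_pair_subconfig(config, d), params) for d in range(3)
                    ]
                    which = rng.integers(0, 3, size=n_conf)
                    repl = np.array(
                        [sample_points(pair_densities[w], 1, rng)[0] for w in which]
                    )
                    pts[confused] = repl
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "condition_id": f"lm{n_lm}",
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                    }
                )
            )
    endpoints = EndpointSet(pd.concat(frames, ignore_index=True), provenance="synthetic")
    metadata = {
        "experiment": "exp1",
        "geometry": geometry,
        "ridge_radius": radius,
        "n_participants": n_participants,
        "trials_per_condition": trials_per_condition,
        "sigma_base": sigma_base,
        "sigma_dispersion": sigma_dispersion,
        "participant_sigmas": sigmas,
        "seed": int(seed),
        "generating_variant": variant,
        "tail_amplitude": tail_amplitude,
        "tail_factor": tail_factor,
        "p_confusion": p_confusion,
        "conditions": ["lm1", "lm2", "lm3"],
    }
    return endpoints, metadata


def generate_experiment2(
    relocations: Sequence[float] = designs.RELOCATIONS,
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    trials_per_condition: int = DEFAULT_TRIALS,
    sigma_base: float = DEFAULT_SIGMA_BASE,
    sigma_dispersion: float = DEFAULT_SIGMA_DISPERSION,
    seed: int = 0,
    tail_amplitude: float = 0.12,
    tail_factor: float = 10.0,
    include_calibration: bool = True,
    participants: Sequence[int] | None = None,
) -> tuple[EndpointSet, dict]:
    """Synthetic endpoints for the relocation (cue-conflict) experiment.

    Endpoints of condition ``reloc{d}`` are drawn from the mixture-variant
    model density of the test configuration with the deviant landmark
    displaced by d; the training geometry (and hence every ridge radius)
    stays fixed.  When ``include_calibration`` is set, a single-landmark
    condition ``lm1`` is emitted as well so the full
    fit-then-predict-parameter-free loop can run on this dataset alone;
    calibration endpoints are drawn from the central (gaussian) ridge,
    since the collapse-then-fit calibration assumes a clean ring cloud.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if trials_per_condition < 1:
        raise ValueError("need at least 1 trial per condition")
    radius = designs.VISUAL_RADIUS
    base = designs.exp2_base_configuration()
    indices = range(n_participants) if participants is None else participants

    frames = []
    sigmas: dict[str, float] = {}
    for k in indices:
        rng = participant_rng(seed, k)
        pid = f"p{k:02d}"
        sigma = _participant_sigma(rng, sigma_base, sigma_dispersion)
        sigmas[pid] = sigma
        params = _participant_params(sigma, radius, "mixture", tail_amplitude, tail_factor)
        if include_calibration:
            config1 = designs.exp1_configuration("visual", 1)
            calib_params = _participant_params(sigma, radius, "gaussian", 0.0, 0.0)
            pts = sample_points(
                predicted_density(config1, calib_params), trials_per_condition, rng
            )
            frames.append(
                pd.DataFrame(
                    {"participant_id": pid, "condition_id": "lm1", "x": pts[:, 0], "y": pts[:, 1]}
                )
            )
        for delta in relocations:
            config = relocate(base, float(delta), designs.DEVIANT_INDEX)
            density = predicted_density(config, params)
            pts = sample_points(density, trials_per_condition, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "condition_id": f"reloc{delta:g}",
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                    }
                )
            )
    endpoints = EndpointSet(pd.concat(frames, ignore_index=True), provenance="synthetic")
    metadata = {
        "experiment": "exp2",
        "geometry": "visual",
        "ridge_radius": radius,
        "relocations": [float(d) for d in relocations],
        "n_participants": n_participants,
        "trials_per_condition": trials_per_condition,
        "sigma_base": sigma_base,
        "sigma_dispersion": sigma_dispersion,
        "participant_sigmas": sigmas,
        "seed": int(seed),
        "generating_variant": "mixture",
        "calibration_variant": "gaussian",
        "tail_amplitude": tail_amplitude,
        "tail_factor": tail_factor,
        "include_calibration": include_calibration,
        "conditions": (["lm1"] if include_calibration else [])
        + [f"reloc{d:g}" for d in relocations],
    }
    return endpoints, metadata


def save_metadata(metadata: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2))
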