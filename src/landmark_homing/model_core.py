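"""Core domain types and single-landmark ring ("donut") likelihoods.

A uniform, omnidirectional landmark informs a navigator only about its
distance to the remembered home location.  The likelihood of a response
position given one such landmark is therefore a circular ridge centred on
the landmark, with radius equal to the trained home-landmark distance and
Gaussian radial spread.  Two ridge variants are supported:

* ``gaussian`` - a plain Gaussian ridge.
* ``mixture``  - the same central ridge plus a broad, low-amplitude
  "pedestal" Gaussian (heavy tails).  The pedestal is what lets products
  of widely separated ridges become bimodal, i.e. it models the breakdown
  of cue integration under large cue conflict.

Lengths are abstract spatial units: meters (auditory arena) and virtual
meters (VR treadmill) are treated identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import yaml

__all__ = [
    "Point2D",
    "LandmarkConfiguration",
    "RidgeParams",
    "GridSpec",
    "DensityGrid",
    "radial_profile",
    "ring_density",
    "default_grid_spec",
    "tail_sigma",
]

#: Peak-height ratio of the pedestal to the central ridge.  Chosen so the
#: tails carry enough mass to break integration while the central Gaussian
#: stays dominant; the exact value is not critical.
DEFAULT_TAIL_AMPLITUDE = 0.12

#: The pedestal spread defaults to this multiple of the central spread.
DEFAULT_TAIL_FACTOR = 10.0

#: Minimum pedestal spread (length units), so the tails stay effectively
#: flat across a typical workspace even when the central spread is small.
DEFAULT_TAIL_FLOOR = 10.0

#: Half-width floor (length units) of the default home-centred workspace.
DEFAULT_HALFWIDTH_FLOOR = 10.0


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class Point2D:
    """A position in the (abstract-length) plane."""

    x: float
    y: float

    def __post_init__(self) -> None:
        _require_finite("Point2D coordinates", self.x, self.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def __add__(self, other: "Point2D") -> "Point2D":
        return Point2D(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "Point2D") -> "Point2D":
        return Point2D(self.x - other.x, self.y - other.y)


def _as_point(p) -> Point2D:
    if isinstance(p, Point2D):
        return p
    x, y = p
    return Point2D(float(x), float(y))


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One experimental condition: home plus 1-3 landmarks.

    ``training_landmarks`` are the positions present while home was
    learned; ``test_landmarks`` are the positions at test time.  Index i
    refers to the same physical landmark in both lists, so a relocation
    is expressed by moving entry i of the test list only.  The trained
    home-landmark distances (and hence the ridge radii) always come from
    the training geometry.
    """

    home: Point2D
    training_landmarks: tuple[Point2D, ...]
    test_landmarks: tuple[Point2D, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "home", _as_point(self.home))
        object.__setattr__(
            self, "training_landmarks", tuple(_as_point(p) for p in self.training_landmarks)
        )
        object.__setattr__(
            self, "test_landmarks", tuple(_as_point(p) for p in self.test_landmarks)
        )
        n = len(self.training_landmarks)
        if not 1 <= n <= 3:
            raise ValueError(f"need 1-3 landmarks, got {n}")
        if len(self.test_landmarks) != n:
            raise ValueError("training and test landmark lists must have equal length")

    @property
    def n_landmarks(self) -> int:
        return len(self.training_landmarks)

    def trained_radii(self) -> tuple[float, ...]:
        """Home-landmark distances learned at training time."""
        return tuple(self.home.distance_to(p) for p in self.training_landmarks)

    def to_dict(self) -> dict:
        return {
            "home": [self.home.x, self.home.y],
            "training_landmarks": [[p.x, p.y] for p in self.training_landmarks],
            "test_landmarks": [[p.x, p.y] for p in self.test_landmarks],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkConfiguration":
        training = d["training_landmarks"]
        return cls(
            home=_as_point(d["home"]),
            training_landmarks=tuple(_as_point(p) for p in training),
            test_landmarks=tuple(_as_point(p) for p in d.get("test_landmarks", training)),
            label=str(d.get("label", "")),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkConfiguration":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)


def tail_sigma(
    sigma_center: float,
    factor: float = DEFAULT_TAIL_FACTOR,
    scale: str = "sigma",
    floor: float = DEFAULT_TAIL_FLOOR,
) -> float:
    """Pedestal spread derived from the central spread.

    ``scale='sigma'`` reads "10 times" as a spread scaling (sigma_tail =
    factor * sigma_center, the default); ``scale='variance'`` reads it as a
    variance scaling (sigma_tail = sqrt(factor) * sigma_center).  Either
    way the result is floored so the pedestal stays near-flat over the
    workspace.
    """
    if scale == "sigma":
        st = factor * sigma_center
    elif scale == "variance":
        st = math.sqrt(factor) * sigma_center
    else:
        raise ValueError(f"unknown tail scale {scale!r}")
    return max(st, floor)


@dataclass(frozen=True)
class RidgeParams:
    """Radial likelihood parameters for one landmark.

    ``tail_amplitude`` is, by default, the peak-height ratio of the
    pedestal to the central Gaussian (both components are evaluated as
    unit-peak Gaussians, summed, and the 2D density is normalized
    afterwards).  Setting ``tail_amplitude_mode='weight'`` instead treats
    it as a probability weight on area-normalized 1D components.
    """

    ridge_radius: float
    sigma_center: float
    sigma_tail: float | None = None
    tail_amplitude: float = DEFAULT_TAIL_AMPLITUDE
    variant: str = "gaussian"
    tail_amplitude_mode: str = "peak"

    def __post_init__(self) -> None:
        _require_finite("ridge_radius/sigma_center", self.ridge_radius, self.sigma_center)
        if self.ridge_radius <= 0:
            raise ValueError(f"ridge_radius must be > 0, got {self.ridge_radius}")
        if self.sigma_center <= 0:
            raise ValueError(f"sigma_center must be > 0, got {self.sigma_center}")
        if self.variant not in ("gaussian", "mixture"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.tail_amplitude_mode not in ("peak", "weight"):
            raise ValueError(f"unknown tail_amplitude_mode {self.tail_amplitude_mode!r}")
        if self.variant == "mixture":
            if self.sigma_tail is None:
                object.__setattr__(self, "sigma_tail", tail_sigma(self.sigma_center))
            _require_finite("sigma_tail/tail_amplitude", self.sigma_tail, self.tail_amplitude)
            if self.sigma_tail <= self.sigma_center:
                raise ValueError("mixture variant requires sigma_tail > sigma_center")
            if not 0 < self.tail_amplitude <= 1:
                raise ValueError("mixture variant requires tail_amplitude in (0, 1]")

    def with_variant(self, variant: str) -> "RidgeParams":
        if variant == self.variant:
            return self
        if variant == "mixture" and self.sigma_tail is None:
            return replace(self, variant=variant, sigma_tail=tail_sigma(self.sigma_center))
        return replace(self, variant=variant)

    def to_dict(self) -> dict:
        return {
            "ridge_radius": self.ridge_radius,
            "sigma_center": self.sigma_center,
            "sigma_tail": self.sigma_tail,
            "tail_amplitude": self.tail_amplitude,
            "variant": self.variant,
            "tail_amplitude_mode": self.tail_amplitude_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeParams":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


def radial_profile(d, params: RidgeParams):
    """Unnormalized ridge profile as a function of distance to the landmark.

    Gaussian variant: exp(-(d - r)^2 / (2 sigma_c^2)).  Mixture variant
    adds the pedestal term; both components peak at d = r, so the profile
    peaks at 1 + tail_amplitude there (peak-height mode).  Accepts scalars
    or arrays; negative distances are rejected.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    z = d - params.ridge_radius
    central = np.exp(-(z**2) / (2.0 * params.sigma_center**2))
    if params.variant == "gaussian":
        out = central
    else:
        pedestal = np.exp(-(z**2) / (2.0 * params.sigma_tail**2))
        if params.tail_amplitude_mode == "peak":
            out = central + params.tail_amplitude * pedestal
        else:
            a = params.tail_amplitude
            out = (1.0 - a) * central / params.sigma_center + a * pedestal / params.sigma_tail
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular evaluation grid.

    ``origin`` is the *center* of the cell at row 0, column 0; rows index
    y, columns index x, both increasing.
    """

    origin: Point2D
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin.x + self.cell_size * np.arange(self.n_cols)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin.y + self.cell_size * np.arange(self.n_rows)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered area, cell edges included."""
        h = self.cell_size / 2.0
        return (
            self.origin.x - h,
            self.origin.x + self.cell_size * (self.n_cols - 1) + h,
            self.origin.y - h,
            self.origin.y + self.cell_size * (self.n_rows - 1) + h,
        )

    def contains(self, p: Point2D) -> bool:
        xmin, xmax, ymin, ymax = self.bounds
        return xmin <= p.x <= xmax and ymin <= p.y <= ymax


@dataclass
class DensityGrid:
    """A discretized 2D probability density over a rectangular region."""

    spec: GridSpec
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite and non-negative")

    @property
    def cell_size(self) -> float:
        return self.spec.cell_size

    @property
    def cell_area(self) -> float:
        return self.spec.cell_size**2

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def normalize(self) -> "DensityGrid":
        total = self.total_mass()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero density grid")
        return DensityGrid(self.spec, self.values / total, normalized=True)

    def cell_probabilities(self) -> np.ndarray:
        """Per-cell probability mass (values * cell area)."""
        if not self.normalized:
            raise ValueError("grid is not normalized")
        return self.values * self.cell_area

    @classmethod
    def uniform(cls, spec: GridSpec) -> "DensityGrid":
        n = spec.n_rows * spec.n_cols
        values = np.full((spec.n_rows, spec.n_cols), 1.0 / (n * spec.cell_size**2))
        return cls(spec, values, normalized=True)

    def save(self, csv_path: str | Path) -> None:
        """Write the value matrix as CSV plus a JSON geometry sidecar."""
        csv_path = Path(csv_path)
        np.savetxt(csv_path, self.values, delimiter=",")
        sidecar = {
            "origin": [self.spec.origin.x, self.spec.origin.y],
            "cell_size": self.spec.cell_size,
            "n_rows": self.spec.n_rows,
            "n_cols": self.spec.n_cols,
            "normalized": self.normalized,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "DensityGrid":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        spec = GridSpec(
            origin=Point2D(*meta["origin"]),
            cell_size=meta["cell_size"],
            n_rows=meta["n_rows"],
            n_cols=meta["n_cols"],
        )
        return cls(spec, values, normalized=bool(meta.get("normalized", False)))


def default_grid_spec(
    config: LandmarkConfiguration,
    params: RidgeParams,
    cell_size: float | None = None,
    halfwidth_floor: float = DEFAULT_HALFWIDTH_FLOOR,
) -> GridSpec:
    """Square workspace centred on home, sized to contain every ridge.

    The half-width is ridge_radius + max(6 sigma_center, floor), enlarged
    if necessary so that every test landmark's ridge (radius + 4 sigma)
    fits; the cell size defaults to sigma_center / 5 so the ridge is
    sampled by >= 5 cells across its width.  Home falls exactly on a cell
    center, which keeps symmetric configurations symmetric on the grid.
    """
    if cell_size is None:
        cell_size = params.sigma_center / 5.0
    half = params.ridge_radius + max(6.0 * params.sigma_center, halfwidth_floor)
    for lm in config.test_landmarks:
        need = config.home.distance_to(lm) + params.ridge_radius + 4.0 * params.sigma_center
        half = max(half, need)
    n_half = int(math.ceil(half / cell_size))
    n = 2 * n_half + 1
    origin = Point2D(config.home.x - n_half * cell_size, config.home.y - n_half * cell_size)
    return GridSpec(origin=origin, cell_size=cell_size, n_rows=n, n_cols=n)


def ring_density(
    landmark: Point2D,
    params: RidgeParams,
    grid_spec: GridSpec,
) -> DensityGrid:
    """Normalized ring likelihood around one landmark on a grid.

    Each cell holds the radial profile evaluated at the cell center's
    distance to the landmark; the grid is then renormalized to integrate
    to one.  The density is rotationally symmetric about the landmark up
    to discretization.  The grid must contain the central ridge
    (ridge_radius + 4 sigma_center around the landmark); the pedestal of
    the mixture variant is allowed to be clipped by the workspace.
    """
    landmark = _as_point(landmark)
    reach = params.ridge_radius + 4.0 * params.sigma_center
    xmin, xmax, ymin, ymax = grid_spec.bounds
    if (
        landmark.x - reach < xmin
        or landmark.x + reach > xmax
        or landmark.y - reach < ymin
        or landmark.y + reach > ymax
    ):
        raise ValueError(
            f"grid {grid_spec.bounds} too small: needs to cover +/-{reach:.3f} "
            f"around landmark ({landmark.x}, {landmark.y})"
        )
    xx, yy = grid_spec.meshgrid()
    dist = np.hypot(xx - landmark.x, yy - landmark.y)
    values = radial_profile(dist, params)
    return DensityGrid(grid_spec, values).normalize()
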