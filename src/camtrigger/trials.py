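"""Detection-trial data model, factorial design generation, CSV I/O and summaries.

A *detection trial* is one experimental pass of a body-size proxy through a
camera's field of view, scored 0/1 (missed/triggered), together with the
deployment covariates that plausibly shape trigger probability: distance to
the camera, proxy body-size class, camera model, lens height, aiming
distance, vertical camera angle, movement speed, and sun position.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BODY_SIZE_LEVELS",
    "CAMERA_MODEL_LEVELS",
    "CSV_COLUMNS",
    "DetectionTrial",
    "TrialDesign",
    "InvalidDesignError",
    "TrialValidationError",
    "paper_design_factors",
    "generate_design",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "as_frame",
    "detection_position_density",
]

#: Declared body-size proxy classes (human stand-ins for wildlife size classes:
#: medium ~ fox/lynx, large ~ wolf/deer, large_ungulate ~ moose/elk).
BODY_SIZE_LEVELS = ("medium", "large", "large_ungulate")

#: Camera models used in the trigger-probability experiment.
CAMERA_MODEL_LEVELS = ("HP2X", "PC900")

#: Canonical CSV schema, one row per trial.
CSV_COLUMNS = [
    "outcome",
    "distance_m",
    "body_size",
    "camera_model",
    "lens_height_cm",
    "aiming_distance_m",
    "vertical_angle_deg",
    "speed_mps",
    "sun_altitude_rad",
    "sun_azimuth_rad",
    "first_x_m",
    "first_y_m",
]

# dataclass attribute -> CSV column
_FIELD_TO_COLUMN = {
    "outcome": "outcome",
    "distance": "distance_m",
    "body_size": "body_size",
    "camera_model": "camera_model",
    "lens_height": "lens_height_cm",
    "aiming_distance": "aiming_distance_m",
    "vertical_angle": "vertical_angle_deg",
    "speed": "speed_mps",
    "sun_altitude": "sun_altitude_rad",
    "sun_azimuth": "sun_azimuth_rad",
    "first_detection_x": "first_x_m",
    "first_detection_y": "first_y_m",
}


class InvalidDesignError(ValueError):
    """Raised for malformed factorial design specifications."""


class TrialValidationError(ValueError):
    """Raised when trial records violate the declared schema or invariants."""


@dataclass
class DetectionTrial:
    """One experimental pass with covariates and a binary trigger outcome.

    Units follow the field conventions: metres for distances, centimetres
    for lens height, degrees for the vertical camera angle (relative to the
    ground surface), metres per second for speed, and radians for the sun
    angles.
    """

    outcome: int
    distance: float
    body_size: str
    camera_model: str
    lens_height: float
    aiming_distance: float
    vertical_angle: float
    speed: float
    sun_altitude: float
    sun_azimuth: float
    first_detection_x: float | None = None
    first_detection_y: float | None = None

    def validate(
        self,
        body_size_levels: Sequence[str] = BODY_SIZE_LEVELS,
        camera_model_levels: Sequence[str] = CAMERA_MODEL_LEVELS,
    ) -> None:
        if self.outcome not in (0, 1):
            raise TrialValidationError(f"outcome must be 0 or 1, got {self.outcome!r}")
        if not self.distance > 0:
            raise TrialValidationError(f"distance must be positive, got {self.distance!r}")
        if not self.lens_height > 0:
            raise TrialValidationError(f"lens_height must be positive, got {self.lens_height!r}")
        if self.speed < 0:
            raise TrialValidationError(f"speed must be nonnegative, got {self.speed!r}")
        if not -math.pi / 2 - 1e-12 <= self.sun_altitude <= math.pi / 2 + 1e-12:
            raise TrialValidationError(
                f"sun_altitude must lie in [-pi/2, pi/2], got {self.sun_altitude!r}"
            )
        if self.body_size not in body_size_levels:
            raise TrialValidationError(
                f"unknown body_size level {self.body_size!r}; declared levels: {tuple(body_size_levels)}"
            )
        if self.camera_model not in camera_model_levels:
            raise TrialValidationError(
                f"unknown camera_model level {self.camera_model!r}; declared levels: {tuple(camera_model_levels)}"
            )


@dataclass
class TrialDesign:
    """Full-factorial experimental layout: factor levels times replicates."""

    factors: dict[str, tuple]
    replicates: int

    def __post_init__(self) -> None:
        if not self.factors:
            raise InvalidDesignError("design needs at least one factor")
        for name, levels in self.factors.items():
            if len(tuple(levels)) == 0:
                raise InvalidDesignError(f"factor {name!r} has an empty level list")
        if self.replicates < 1:
            raise InvalidDesignError(f"replicates must be >= 1, got {self.replicates}")
        self.factors = {k: tuple(v) for k, v in self.factors.items()}

    @property
    def n_rows(self) -> int:
        return self.replicates * math.prod(len(v) for v in self.factors.values())

    def to_frame(self) -> pd.DataFrame:
        return generate_design(self.factors, self.replicates)


def paper_design_factors() -> dict[str, tuple]:
    """The balanced 3780-trial factorial layout of the underlying experiment.

    3 body-size proxies x 2 camera models x 3 lens heights (cm) x 3 aiming
    distances (m) x 7 trial distances (m), ten replicates of each cell.
    """
    return {
        "body_size": ("medium", "large", "large_ungulate"),
        "camera_model": ("PC900", "HP2X"),
        "lens_height_cm": (86, 116, 146),
        "aiming_distance_m": (5, 10, 15),
        "distance_m": (2, 4, 6, 8, 10, 12, 15),
    }


def generate_design(factors: Mapping[str, Sequence], replicates: int) -> pd.DataFrame:
    """Expand a factor->levels map into the full factorial grid of trial stubs.

    Rows are ordered lexicographically by the declared factor order, each
    combination repeated ``replicates`` consecutive times, so generated
    designs are deterministic and seed-reproducible downstream.
    """
    design = TrialDesign({k: tuple(v) for k, v in factors.items()}, replicates)
    names = list(design.factors)
    rows = []
    for combo in itertools.product(*design.factors.values()):
        rows.extend([combo] * design.replicates)
    frame = pd.DataFrame(rows, columns=names)
    assert len(frame) == design.n_rows
    return frame


# ---------------------------------------------------------------------------
# CSV I/O


_REQUIRED_COLUMNS = CSV_COLUMNS[:10]  # first_x_m / first_y_m are optional


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_trials(
    path: str | Path,
    body_size_levels: Sequence[str] = BODY_SIZE_LEVELS,
    camera_model_levels: Sequence[str] = CAMERA_MODEL_LEVELS,
) -> list[DetectionTrial]:
    """Read and validate trials from the canonical CSV schema.

    Raises :class:`TrialValidationError` naming the offending 1-based data
    row for any invariant violation; unknown categorical levels are rejected
    unless passed in via the level arguments.
    """
    frame = pd.read_csv(path, dtype={"body_size": str, "camera_model": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialValidationError(f"missing required column(s): {', '.join(missing)}")
    trials: list[DetectionTrial] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        try:
            outcome_raw = record["outcome"]
            if not float(outcome_raw) == int(outcome_raw):
                raise TrialValidationError(f"non-integer outcome {outcome_raw!r}")
            trial = DetectionTrial(
                outcome=int(outcome_raw),
                distance=float(record["distance_m"]),
                body_size=str(record["body_size"]),
                camera_model=str(record["camera_model"]),
                lens_height=float(record["lens_height_cm"]),
                aiming_distance=float(record["aiming_distance_m"]),
                vertical_angle=float(record["vertical_angle_deg"]),
                speed=float(record["speed_mps"]),
                sun_altitude=float(record["sun_altitude_rad"]),
                sun_azimuth=float(record["sun_azimuth_rad"]),
                first_detection_x=_parse_optional_float(record.get("first_x_m")),
                first_detection_y=_parse_optional_float(record.get("first_y_m")),
            )
            trial.validate(body_size_levels, camera_model_levels)
        except (TrialValidationError, ValueError, TypeError) as exc:
            raise TrialValidationError(f"row {i}: {exc}") from exc
        trials.append(trial)
    return trials


def trials_to_frame(trials: Iterable[DetectionTrial]) -> pd.DataFrame:
    """Convert trial records to a DataFrame in the canonical CSV column order."""
    records = []
    for t in trials:
        records.append({col: getattr(t, attr) for attr, col in _FIELD_TO_COLUMN.items()})
    frame = pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
    return frame


def as_frame(trials) -> pd.DataFrame:
    """Coerce a trial list or DataFrame to the canonical DataFrame schema."""
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def write_trials(trials, path: str | Path) -> None:
    """Write trials to CSV (UTF-8, '.' decimal, empty string for missing)."""
    frame = as_frame(trials).copy()
    frame.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Detection-position density (first-trigger location maps)


def detection_position_density(
    points: Sequence[tuple[float, float]],
    bandwidth: float = 1.5,
    extent: tuple[float, float, float, float] = (-8.0, 8.0, 0.0, 15.0),
    step: float = 0.1,
):
    """Gaussian kernel density of mapped first-detection positions.

    Evaluates an isotropic Gaussian KDE (default bandwidth 1.5 m) on a
    regular grid covering the staked experimental plot: x in [-8, 8] m
    across the camera axis, y in [0, 15] m along it.

    Returns ``(x_grid, y_grid, density)`` where ``density[i, j]`` is the
    probability density at ``(x_grid[j], y_grid[i])``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("detection_position_density needs at least one point")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) metres")
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth!r}")

    from sklearn.neighbors import KernelDensity

    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(pts)
    x_grid = np.arange(extent[0], extent[1] + step / 2, step)
    y_grid = np.arange(extent[2], extent[3] + step / 2, step)
    xx, yy = np.meshgrid(x_grid, y_grid)
    density = np.exp(kde.score_samples(np.column_stack([xx.ravel(), yy.ravel()])))
    return x_grid, y_grid, density.reshape(xx.shape)
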