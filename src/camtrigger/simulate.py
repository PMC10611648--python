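"""Synthetic detection trials with the two-stage structure the analysis assumes.

Two generation modes share one config:

* covariate mode (``coefficients`` given) — each trial succeeds with
  probability ``inverse-logit(intercept + sum(coef * covariate) +
  beta_dist * p(y))``, where p(y) is a known ("true") stage-1 detection
  function at the trial's distance and covariates are built with exactly
  the same design-matrix construction the stage-2 regression uses;
* detection mode (``coefficients=None``) — each trial succeeds with
  probability ``p(y)`` itself, the parametric-bootstrap setting in which
  stage-1 family recovery is well posed.

The logit composite of covariate mode is *not* itself a member of any
detection-function family — the squashed distance curve is systematically
better approximated by the flexible hazard-rate mixture — so family
recovery is checked on detection-mode data and stage-2 coefficient
recovery on covariate-mode data.

Outcomes are Bernoulli draws from per-trial substreams keyed on
(seed, row index), so a fixed seed yields byte-identical trials regardless
of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import build_design_matrix
from .detection import DetectionFunctionSpec
from .solar import solar_position
from .trials import CSV_COLUMNS, TrialDesign, paper_design_factors

__all__ = [
    "DEFAULT_DETECTION_SPEC",
    "DEFAULT_COEFFICIENTS",
    "SimulationConfig",
    "default_simulation_config",
    "simulate_trials",
]

#: Default true stage-1 model: half-normal with a near-camera logistic dip.
DEFAULT_DETECTION_SPEC = DetectionFunctionSpec(
    family="half_normal", mixture=True, alpha=6.0, mix_location=1.5, mix_steepness=3.0
)

#: Default true stage-2 log-odds effects. Keys are design-matrix column
#: labels; magnitudes chosen to give a realistic decline of trigger
#: probability with distance, a near-camera dip, a strong body-size
#: penalty for the medium proxy, and moderate camera/speed/sun effects.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "Intercept": -2.5,
    "body_size[large]": -0.4,
    "body_size[medium]": -2.5,
    "camera_model[PC900]": -1.0,
    "distance_model": 6.5,
    "speed": -1.0,
    "sun_azimuth": -0.3,
    "body_size[medium]:distance_model": 2.5,
    "camera_model[PC900]:distance_model": 1.5,
}


@dataclass
class SimulationConfig:
    """Everything needed to generate one reproducible synthetic dataset."""

    design: TrialDesign
    detfun: DetectionFunctionSpec = DEFAULT_DETECTION_SPEC
    #: stage-2 log-odds effects; None switches to pure detection mode
    coefficients: Mapping[str, float] | None = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    speed_mean: float = 1.0          # m/s, truncated-normal trial speed
    speed_sd: float = 0.3
    sun_fixed: tuple[float, float] | None = None       # (altitude, azimuth) radians
    sun_site: tuple[float, float] | None = None        # (lat, lon) degrees for ephemeris draws
    sun_window: tuple[datetime, datetime] | None = None
    sun_altitude_range: tuple[float, float] = (0.1, 1.2)   # radians, uniform fallback
    sun_azimuth_range: tuple[float, float] = (0.7, 2.6)
    angle_noise_sd: float = 0.5      # degrees of jitter on the derived camera angle
    seed: int = 0


def default_simulation_config(seed: int = 0, replicates: int = 10) -> SimulationConfig:
    """The balanced factorial layout with the default true two-stage model."""
    return SimulationConfig(
        design=TrialDesign(paper_design_factors(), replicates), seed=seed
    )


def _terms_from_coefficients(coefficients: Mapping[str, float]) -> list[str]:
    terms: list[str] = []
    for key in coefficients:
        if key == "Intercept":
            continue
        term = ":".join(part.split("[")[0] for part in key.split(":"))
        if term not in terms:
            terms.append(term)
    return terms


def simulate_trials(config: SimulationConfig) -> pd.DataFrame:
    """Generate synthetic trials under a known two-stage model.

    Returns a DataFrame in the canonical trial CSV schema, one row per
    design cell x replicate, rows in the design's deterministic order.
    """
    frame = config.design.to_frame().copy()
    n = len(frame)
    if "distance_m" not in frame.columns:
        raise ValueError("simulation design must include a 'distance_m' factor")

    rngs = [np.random.default_rng([int(config.seed) & 0x7FFFFFFF, i]) for i in range(n)]

    # vertical camera angle follows geometrically from lens height and
    # aiming distance (camera tilted to centre the aiming gauge), plus jitter
    if "lens_height_cm" in frame.columns and "aiming_distance_m" in frame.columns:
        h = frame["lens_height_cm"].to_numpy(dtype=float) / 100.0
        aim = frame["aiming_distance_m"].to_numpy(dtype=float)
        base_angle = np.degrees(np.arctan2(h - 0.8, aim))
        noise = np.array([r.normal(0.0, config.angle_noise_sd) for r in rngs])
        frame["vertical_angle_deg"] = base_angle + noise
    elif "vertical_angle_deg" not in frame.columns:
        frame["vertical_angle_deg"] = 0.0

    # truncated-normal movement speed (resample below zero)
    speeds = np.empty(n)
    for i, r in enumerate(rngs):
        s = r.normal(config.speed_mean, config.speed_sd)
        while s < 0:
            s = r.normal(config.speed_mean, config.speed_sd)
        speeds[i] = s
    frame["speed_mps"] = speeds

    if config.sun_fixed is not None:
        frame["sun_altitude_rad"] = config.sun_fixed[0]
        frame["sun_azimuth_rad"] = config.sun_fixed[1]
    elif config.sun_site is not None and config.sun_window is not None:
        lat, lon = config.sun_site
        start, end = config.sun_window
        span = (end - start).total_seconds()
        alts = np.empty(n)
        azs = np.empty(n)
        for i, r in enumerate(rngs):
            when = start + timedelta(seconds=float(r.uniform(0.0, span)))
            alts[i], azs[i] = solar_position(when, lat, lon)
        frame["sun_altitude_rad"] = alts
        frame["sun_azimuth_rad"] = azs
    else:
        lo_a, hi_a = config.sun_altitude_range
        lo_z, hi_z = config.sun_azimuth_range
        frame["sun_altitude_rad"] = [r.uniform(lo_a, hi_a) for r in rngs]
        frame["sun_azimuth_rad"] = [r.uniform(lo_z, hi_z) for r in rngs]

    if config.coefficients is None:
        # detection mode: trigger probability is the detection function itself
        p = np.asarray(
            config.detfun.detection_probability(frame["distance_m"].to_numpy(dtype=float))
        )
    else:
        frame["outcome"] = 0  # placeholder so the canonical schema is complete
        terms = _terms_from_coefficients(config.coefficients)
        X, _ = build_design_matrix(frame, terms, config.detfun)
        unknown = [k for k in config.coefficients if k != "Intercept" and k not in X.columns]
        if unknown:
            raise ValueError(
                f"coefficient(s) reference unknown design column(s): {', '.join(unknown)}"
            )
        beta = np.array([config.coefficients.get(col, 0.0) for col in X.columns])
        p = expit(X.to_numpy(dtype=float) @ beta)
    frame["outcome"] = np.array([int(r.random() < pi) for r, pi in zip(rngs, p)])

    frame["first_x_m"] = np.nan
    frame["first_y_m"] = np.nan
    return frame[CSV_COLUMNS]
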