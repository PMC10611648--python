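"""Stage-1 core: binomial-response distance-sampling detection functions.

Detection trials are Bernoulli outcomes whose success probability declines
with distance ``y`` from the camera according to one of three monotone
families,

    exponential:  p(y) = exp(-y / alpha)
    half-normal:  p(y) = exp(-y^2 / (2 * alpha^2))
    hazard-rate:  p(y) = 1 - exp(-(y / alpha)^(-gamma))

optionally multiplied by a logistic-in-distance mixture term

    logistic((y - mix_location) * mix_steepness)

that lets detection drop immediately in front of the camera, where a
passing animal can slip beneath the PIR sensor cone. Each candidate is fit
by maximizing the Bernoulli log-likelihood; candidates are ranked by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .trials import as_frame

__all__ = [
    "FAMILIES",
    "DetectionFunctionSpec",
    "DetectionFunction",
    "eval_base",
    "eval_mixture",
    "negative_log_likelihood",
    "fit_detection_function",
    "aic",
    "select_model",
    "candidate_labels",
]

FAMILIES = ("exponential", "half_normal", "hazard")

#: Probability clamp for the Bernoulli likelihood; the hazard family reaches
#: p -> 1 as y -> 0, so log(1 - p) needs a floor.
_EPS = 1e-12

#: Deterministic multi-start grid over the scale parameter (metres).
_ALPHA_STARTS = (2.0, 5.0, 10.0, 15.0, 25.0)


@dataclass(frozen=True)
class DetectionFunctionSpec:
    """Parameterized detection function: family, mixture flag, parameters.

    ``alpha`` is the scale (metres) of all three families; ``gamma`` is the
    hazard-rate shape; ``mix_location`` (metres) and ``mix_steepness``
    (per metre) parameterize the near-camera logistic dip.
    """

    family: str
    mixture: bool = False
    alpha: float = 1.0
    gamma: float | None = None
    mix_location: float | None = None
    mix_steepness: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha!r}")
        if self.family == "hazard":
            if self.gamma is None or not self.gamma > 0:
                raise ValueError("hazard family needs gamma > 0")
        elif self.gamma is not None:
            raise ValueError("gamma is only meaningful for the hazard family")
        if self.mixture:
            if self.mix_location is None or self.mix_location < 0:
                raise ValueError("mixture needs mix_location >= 0")
            if self.mix_steepness is None or not self.mix_steepness > 0:
                raise ValueError("mixture needs mix_steepness > 0")
        elif self.mix_location is not None or self.mix_steepness is not None:
            raise ValueError("mixture parameters present but mixture=False")

    @property
    def k(self) -> int:
        """Number of free parameters (1 or 2 for the base, +2 with mixture)."""
        base = 2 if self.family == "hazard" else 1
        return base + (2 if self.mixture else 0)

    def detection_probability(self, y) -> np.ndarray:
        """p(y) for this spec, mixture included when present."""
        if self.mixture:
            return eval_mixture(self, y)
        return eval_base(self.family, self.alpha, y, self.gamma)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mixture": self.mixture,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "mix_location": self.mix_location,
            "mix_steepness": self.mix_steepness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionFunctionSpec":
        return cls(**{k: d.get(k) for k in ("family", "mixture", "alpha", "gamma", "mix_location", "mix_steepness")})


def eval_base(family: str, alpha: float, y, gamma: float | None = None) -> np.ndarray:
    """Evaluate a base (monotone) detection function at distance(s) ``y``.

    All families return 1 at y = 0 (for the hazard family as the y -> 0+
    limit) and decrease monotonically to 0 with distance.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("distances must be nonnegative")
    if family == "exponential":
        p = np.exp(-y / alpha)
    elif family == "half_normal":
        p = np.exp(-(y**2) / (2.0 * alpha**2))
    elif family == "hazard":
        if gamma is None or not gamma > 0:
            raise ValueError("hazard family needs gamma > 0")
        with np.errstate(divide="ignore", over="ignore"):
            p = -np.expm1(-((y / alpha) ** (-float(gamma))))
        p = np.where(y == 0, 1.0, p)
    else:
        raise ValueError(f"unknown family {family!r}; one of {FAMILIES}")
    return p if p.ndim else float(p)


def eval_mixture(spec: DetectionFunctionSpec, y) -> np.ndarray:
    """Base detection probability times the near-camera logistic term."""
    if not spec.mixture:
        raise ValueError("spec.mixture must be True for eval_mixture")
    base = eval_base(spec.family, spec.alpha, y, spec.gamma)
    y = np.asarray(y, dtype=float)
    weight = expit((y - spec.mix_location) * spec.mix_steepness)
    out = base * weight
    return out if np.ndim(out) else float(out)


def negative_log_likelihood(trials, spec: DetectionFunctionSpec) -> float:
    """Bernoulli negative log-likelihood of a detection-function spec.

    ``-sum_i [o_i log p(y_i) + (1 - o_i) log(1 - p(y_i))]`` with p clamped
    to [1e-12, 1 - 1e-12] so the sum stays finite at the boundaries.
    """
    frame = as_frame(trials)
    if len(frame) == 0:
        raise ValueError("negative_log_likelihood needs at least one trial")
    return _nll_arrays(
        frame["distance_m"].to_numpy(dtype=float),
        frame["outcome"].to_numpy(dtype=float),
        spec,
    )


def _nll_arrays(y: np.ndarray, outcome: np.ndarray, spec: DetectionFunctionSpec) -> float:
    p = np.clip(spec.detection_probability(y), _EPS, 1.0 - _EPS)
    return float(-np.sum(outcome * np.log(p) + (1.0 - outcome) * np.log1p(-p)))


def aic(k: int, log_likelihood: float) -> float:
    """Akaike information criterion, 2k - 2 LL."""
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    return 2.0 * k - 2.0 * log_likelihood


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _unpack(theta: np.ndarray, family: str, mixture: bool) -> DetectionFunctionSpec:
    # positive parameters live on the log scale during optimization
    vals = np.exp(np.clip(theta, -30.0, 30.0))
    i = 0
    alpha = vals[i]; i += 1
    gamma = None
    if family == "hazard":
        gamma = vals[i]; i += 1
    loc = steep = None
    if mixture:
        loc = vals[i]; i += 1
        steep = vals[i]; i += 1
    return DetectionFunctionSpec(
        family=family, mixture=mixture, alpha=alpha, gamma=gamma,
        mix_location=loc, mix_steepness=steep,
    )


class DetectionFunction(BaseEstimator):
    """Maximum-likelihood detection-function estimator (scikit-learn style).

    Parameters
    ----------
    family : {"exponential", "half_normal", "hazard"}
        Base monotone family.
    mixture : bool
        Whether to multiply by the near-camera logistic term.

    ``fit(X, y)`` takes distances (metres) in ``X`` and 0/1 trigger
    outcomes in ``y``. The likelihood surface can carry several local
    maxima, so the optimizer runs a deterministic multi-start grid over the
    scale parameter (Nelder-Mead, then a BFGS polish of the best start).

    Attributes
    ----------
    alpha_, gamma_, mix_location_, mix_steepness_ : fitted parameters
    spec_ : DetectionFunctionSpec with the fitted values
    log_likelihood_, k_, aic_, converged_, n_trials_ : fit summaries
    """

    def __init__(self, family: str = "half_normal", mixture: bool = False):
        self.family = family
        self.mixture = mixture

    # -- core API ----------------------------------------------------------
    def fit(self, X, y):
        distances = np.asarray(X, dtype=float).reshape(-1)
        outcomes = np.asarray(y, dtype=float).reshape(-1)
        if distances.shape != outcomes.shape:
            raise ValueError("X and y must have the same length")
        if distances.size == 0:
            raise ValueError("cannot fit a detection function to zero trials")
        if np.any(distances < 0):
            raise ValueError("distances must be nonnegative")
        if not set(np.unique(outcomes)) <= {0.0, 1.0}:
            raise ValueError("outcomes must be 0/1")

        one_class = outcomes.min() == outcomes.max()

        def objective(theta):
            try:
                spec = _unpack(theta, self.family, self.mixture)
            except ValueError:
                return np.inf
            return _nll_arrays(distances, outcomes, spec)

        starts = []
        for a in _ALPHA_STARTS:
            theta = [math.log(a)]
            if self.family == "hazard":
                theta.append(math.log(2.0))
            if self.mixture:
                theta.extend([math.log(1.0), math.log(2.0)])
            starts.append(np.array(theta))

        best = None
        for theta0 in starts:
            res = minimize(objective, theta0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        polish = minimize(objective, best.x, method="BFGS",
                          options={"gtol": 1e-5, "maxiter": 500})
        if polish.fun <= best.fun:
            best = polish
        if not np.isfinite(best.fun):
            raise RuntimeError(f"detection-function fit failed for {self.family} (all starts diverged)")

        spec = _unpack(best.x, self.family, self.mixture)
        self.spec_ = spec
        self.alpha_ = spec.alpha
        self.gamma_ = spec.gamma
        self.mix_location_ = spec.mix_location
        self.mix_steepness_ = spec.mix_steepness
        self.log_likelihood_ = -best.fun
        self.k_ = spec.k
        self.aic_ = aic(self.k_, self.log_likelihood_)
        self.n_trials_ = int(distances.size)
        if one_class:
            # all-detected or all-missed data push the scale to a boundary;
            # report the boundary rather than a spurious interior optimum
            self.converged_ = False
            self.boundary_diagnostic_ = (
                "all trials share one outcome; the scale parameter is not "
                "identified (likelihood maximized at a boundary)"
            )
        else:
            self.converged_ = bool(np.isfinite(best.fun))
            self.boundary_diagnostic_ = None
        return self

    def detection_probability(self, X) -> np.ndarray:
        """Fitted p(y) at distance(s) X (metres)."""
        self._check_fitted()
        return self.spec_.detection_probability(np.asarray(X, dtype=float).reshape(-1))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        p = self.detection_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.detection_probability(X) >= 0.5).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "spec_"):
            raise RuntimeError("DetectionFunction is not fitted yet; call fit first")

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            **self.spec_.to_dict(),
            "log_likelihood": self.log_likelihood_,
            "k": self.k_,
            "aic": self.aic_,
            "converged": self.converged_,
            "n_trials": self.n_trials_,
        }


def fit_detection_function(trials, family: str, mixture: bool = False) -> DetectionFunction:
    """Fit one detection-function candidate to trials by maximum likelihood."""
    frame = as_frame(trials)
    est = DetectionFunction(family=family, mixture=mixture)
    return est.fit(frame["distance_m"].to_numpy(dtype=float),
                   frame["outcome"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# AIC model selection


def candidate_labels() -> list[tuple[str, bool]]:
    """The default six-candidate set: each family with and without mixture."""
    return [(fam, mix) for fam in FAMILIES for mix in (False, True)]


def _fit_summary(fit) -> tuple[int, float]:
    if hasattr(fit, "k_"):
        return int(fit.k_), float(fit.log_likelihood_)
    if hasattr(fit, "k"):
        return int(fit.k), float(fit.log_likelihood)
    k, ll = fit  # (K, LL) pair
    return int(k), float(ll)


def select_model(fits: Sequence, labels: Iterable[str] | None = None):
    """Rank candidate fits by AIC into a selection table.

    ``fits`` may be fitted :class:`DetectionFunction` estimators, objects
    with ``k``/``log_likelihood`` attributes, or bare ``(K, LL)`` pairs.
    Returns a DataFrame with columns ``model, K, LL, AIC, dAIC`` sorted
    ascending by AIC (stable input-order tie-break); the first row is the
    selected model.
    """
    import pandas as pd

    fits = list(fits)
    if not fits:
        raise ValueError("select_model needs at least one candidate fit")
    if labels is None:
        labels = [getattr(f, "label", f"model_{i}") for i, f in enumerate(fits)]
    labels = list(labels)
    if len(labels) != len(fits):
        raise ValueError("labels and fits must align")
    rows = []
    for label, fit in zip(labels, fits):
        k, ll = _fit_summary(fit)
        rows.append({"model": label, "K": k, "LL": ll, "AIC": aic(k, ll)})
    table = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    return table
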