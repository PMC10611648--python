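"""Stage-2 inference: logit-link binomial regression of trigger outcomes.

The stage-1 detection function is collapsed into a single covariate — the
fitted detection probability p-hat(y) at each trial's distance, on the raw
[0, 1] scale — and trial outcomes are regressed on it together with the
experimental covariates (body size, camera model, lens height, aiming
distance, vertical angle, speed, sun position) and selected interactions.
Stage-1 parameters are held fixed at their MLEs (no joint refit), so
stage-2 standard errors do not carry stage-1 uncertainty.

Because the vertical camera angle is strongly rank-correlated with lens
height and aiming distance in this design, covariates are organised into
two model suites: one with the angle, one with height plus aiming distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from .detection import DetectionFunction, DetectionFunctionSpec
from .trials import BODY_SIZE_LEVELS, CAMERA_MODEL_LEVELS, as_frame

__all__ = [
    "ANGLE_SUITE_TERMS",
    "HEIGHT_SUITE_TERMS",
    "DEFAULT_REFERENCE_LEVELS",
    "LogitFit",
    "ROCResult",
    "TriggerGLM",
    "build_design_matrix",
    "fit_logit",
    "backward_stepwise",
    "predict_probability",
    "marginal_effects",
    "roc_auc",
    "collinearity_check",
    "combined_detection_probability",
]

# term name -> trial-frame column (distance_model is computed from stage 1)
_TERM_COLUMNS = {
    "distance_model": None,
    "distance": "distance_m",
    "body_size": "body_size",
    "camera_model": "camera_model",
    "lens_height": "lens_height_cm",
    "aiming_distance": "aiming_distance_m",
    "vertical_angle": "vertical_angle_deg",
    "speed": "speed_mps",
    "sun_altitude": "sun_altitude_rad",
    "sun_azimuth": "sun_azimuth_rad",
}

_CATEGORICAL_LEVELS = {
    "body_size": BODY_SIZE_LEVELS,
    "camera_model": CAMERA_MODEL_LEVELS,
}

#: Treatment-contrast baselines: the largest proxy and the HP2X camera.
DEFAULT_REFERENCE_LEVELS = {"body_size": "large_ungulate", "camera_model": "HP2X"}

#: Global model suite including the vertical camera angle.
ANGLE_SUITE_TERMS = (
    "vertical_angle", "body_size", "camera_model", "distance_model",
    "speed", "sun_altitude", "sun_azimuth",
    "body_size:distance_model", "camera_model:distance_model",
)

#: Global model suite including lens height and aiming distance instead.
HEIGHT_SUITE_TERMS = (
    "lens_height", "aiming_distance", "body_size", "camera_model",
    "distance_model", "speed", "sun_altitude", "sun_azimuth",
    "body_size:distance_model", "camera_model:distance_model",
)


def _resolve_spec(detfun) -> DetectionFunctionSpec | None:
    if detfun is None:
        return None
    if isinstance(detfun, DetectionFunctionSpec):
        return detfun
    if isinstance(detfun, DetectionFunction):
        return detfun.spec_
    raise TypeError(f"cannot interpret {type(detfun).__name__} as a detection function")


def _term_base_columns(
    term: str,
    frame: pd.DataFrame,
    detfun_spec: DetectionFunctionSpec | None,
    reference_levels: dict[str, str],
) -> dict[str, np.ndarray]:
    """Expand one main-effect term into labelled numeric columns."""
    if term == "distance_model":
        if detfun_spec is None:
            raise ValueError("term 'distance_model' needs a fitted stage-1 detection function")
        y = frame["distance_m"].to_numpy(dtype=float)
        return {"distance_model": np.asarray(detfun_spec.detection_probability(y), dtype=float)}
    if term not in _TERM_COLUMNS:
        raise ValueError(f"unknown model term {term!r}")
    col = _TERM_COLUMNS[term]
    if term in _CATEGORICAL_LEVELS:
        levels = _CATEGORICAL_LEVELS[term]
        ref = reference_levels.get(term, levels[-1])
        values = frame[col].astype(str)
        unseen = sorted(set(values) - set(levels))
        if unseen:
            raise ValueError(f"unseen {term} level(s): {', '.join(unseen)}")
        return {
            f"{term}[{lvl}]": (values == lvl).to_numpy(dtype=float)
            for lvl in levels
            if lvl != ref
        }
    return {term: frame[col].to_numpy(dtype=float)}


def build_design_matrix(
    trials,
    terms,
    detfun=None,
    reference_levels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build the numeric design matrix for a term list.

    Categorical covariates expand as treatment contrasts against the
    declared reference levels; interactions (``"A:B"``) are elementwise
    products of the component columns; the ``distance_model`` column is the
    stage-1 fitted detection probability at each trial's distance.

    Returns ``(X, term_map)`` where ``X`` has an ``Intercept`` column first
    and ``term_map`` maps each term to its design-matrix column labels.
    """
    frame = as_frame(trials)
    spec = _resolve_spec(detfun)
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)

    X = pd.DataFrame({"Intercept": np.ones(len(frame))})
    term_map: dict[str, list[str]] = {}
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            blocks = [_term_base_columns(p, frame, spec, refs) for p in parts]
            cols: dict[str, np.ndarray] = {}
            # cartesian product of component contrast columns
            def expand(i, label, values):
                if i == len(blocks):
                    cols[label] = values
                    return
                for sub_label, sub_values in blocks[i].items():
                    new_label = sub_label if not label else f"{label}:{sub_label}"
                    expand(i + 1, new_label, values * sub_values)
            expand(0, "", np.ones(len(frame)))
        else:
            cols = _term_base_columns(term, frame, spec, refs)
        for label, values in cols.items():
            X[label] = values
        term_map[term] = list(cols)
    return X, term_map


# ---------------------------------------------------------------------------
# Logit fitting


@dataclass
class LogitFit:
    """Fitted binomial GLM: coefficients, Wald inference, and likelihood."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    log_likelihood: float
    converged: bool
    n: int
    reference_levels: dict[str, str] = field(default_factory=dict)
    term_map: dict[str, list[str]] = field(default_factory=dict)
    diagnostic: str | None = None

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Covariate": self.params.index,
            "Estimate": self.params.to_numpy(),
            "SE": self.bse.to_numpy(),
            "z": self.zvalues.to_numpy(),
            "p": self.pvalues.to_numpy(),
        })

    def wald_block_test(self, columns: list[str]) -> tuple[float, int, float]:
        """Joint Wald chi-square test that a block of coefficients is zero."""
        b = self.params[columns].to_numpy()
        V = self.cov_params.loc[columns, columns].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(columns)
        return stat, df, float(stats.chi2.sf(stat, df))


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    from scipy.linalg import qr

    A = X.to_numpy(dtype=float)
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return [X.columns[i] for i in sorted(piv[rank:])]


def fit_logit(X: pd.DataFrame, outcomes, **fit_meta) -> LogitFit:
    """Maximize the Bernoulli log-likelihood of a logit-link linear model.

    Fitting is IRLS via statsmodels; standard errors come from the inverse
    observed information, with Wald z and two-sided normal p per column.
    Rank-deficient designs raise with the collinear columns named; complete
    separation is flagged on the returned fit rather than raised.
    """
    y = np.asarray(outcomes, dtype=float).reshape(-1)
    if len(X) == 0:
        raise ValueError("fit_logit needs at least one row")
    if len(X) != len(y):
        raise ValueError("design matrix and outcomes must align")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"rank-deficient design matrix; collinear column(s): {', '.join(bad)}")

    glm = sm.GLM(y, X, family=sm.families.Binomial())
    converged = True
    diagnostic = None
    try:
        res = glm.fit(maxiter=200)
        converged = bool(res.converged)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        res = glm.fit(maxiter=25, tol=1e-4)
        converged = False
        diagnostic = f"fit did not converge cleanly: {exc}"

    params = pd.Series(np.asarray(res.params), index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    z = params / bse
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=X.columns)

    # complete/quasi-complete separation: fitted probabilities saturate
    mu = np.asarray(res.fittedvalues)
    if converged and (np.abs(params).max() > 25 or np.all((mu > 0.999) == (y == 1))):
        if np.all(np.where(y == 1, mu > 1 - 1e-6, mu < 1e-6)):
            converged = False
            diagnostic = "complete separation: fitted probabilities saturate at 0/1"

    return LogitFit(
        params=params, bse=bse, zvalues=z, pvalues=p, cov_params=cov,
        log_likelihood=float(res.llf), converged=converged, n=len(y),
        diagnostic=diagnostic, **fit_meta,
    )


def _components(term: str) -> set[str]:
    return set(term.split(":"))


def backward_stepwise(
    trials,
    outcomes,
    terms,
    detfun=None,
    alpha: float = 0.05,
    reference_levels: dict[str, str] | None = None,
) -> tuple[LogitFit, list[str]]:
    """Backwards stepwise pruning of a logit model by Wald significance.

    Repeatedly refits after dropping the single least-significant eligible
    term with p > ``alpha``. Categorical-contrast blocks (and
    multi-column interaction blocks) are tested jointly with a Wald
    chi-square and removed as a block; a main effect is ineligible while
    any interaction containing it remains (marginality rule). Stops when
    every eligible term is significant; an emptied model returns the
    intercept-only fit.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    current = list(terms)
    while True:
        X, term_map = build_design_matrix(trials, current, detfun, reference_levels)
        fit = fit_logit(X, outcomes, term_map=term_map,
                        reference_levels=dict(DEFAULT_REFERENCE_LEVELS, **(reference_levels or {})))
        protected = set()
        for term in current:
            if ":" in term:
                protected |= _components(term)
        worst_term, worst_p = None, alpha
        for term in current:
            if ":" not in term and term in protected:
                continue
            _, _, p_block = fit.wald_block_test(term_map[term])
            if p_block > worst_p:
                worst_term, worst_p = term, p_block
        if worst_term is None:
            return fit, current
        current = [t for t in current if t != worst_term]


# ---------------------------------------------------------------------------
# Prediction and marginal effects


def predict_probability(fit: LogitFit, trials, detfun=None) -> np.ndarray:
    """Inverse-logit predictions on the fit's own design-matrix construction."""
    terms = list(fit.term_map)
    X, _ = build_design_matrix(trials, terms, detfun, fit.reference_levels)
    X = X[fit.params.index]
    return expit(X.to_numpy(dtype=float) @ fit.params.to_numpy())


def marginal_effects(
    fit: LogitFit,
    trials,
    detfun=None,
    focal: str = "distance",
    grid=None,
) -> pd.DataFrame:
    """Average-of-predictions marginal effect of one focal covariate.

    For each grid value the focal covariate is set to that value in every
    trial row, predictions are averaged, and the SE of the mean prediction
    comes from the delta method on the coefficient covariance. Setting the
    trial distance recomputes the stage-1 ``distance_model`` covariate.
    """
    frame = as_frame(trials).copy()
    col = _TERM_COLUMNS.get(focal, focal)
    if col is None:
        raise ValueError("the distance-model covariate is derived; use focal='distance'")
    if col not in frame.columns:
        raise ValueError(f"focal covariate {focal!r} not found in trials")
    if grid is None:
        raise ValueError("marginal_effects needs an explicit grid of focal values")
    if focal in _CATEGORICAL_LEVELS:
        bad = [g for g in grid if g not in _CATEGORICAL_LEVELS[focal]]
        if bad:
            raise ValueError(f"grid value(s) outside declared {focal} levels: {bad}")

    beta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    rows = []
    for value in grid:
        counterfactual = frame.copy()
        counterfactual[col] = value
        X, _ = build_design_matrix(counterfactual, list(fit.term_map), detfun, fit.reference_levels)
        X = X[fit.params.index].to_numpy(dtype=float)
        p = expit(X @ beta)
        grad = (p * (1.0 - p)) @ X / len(p)  # d mean(p) / d beta
        se = float(np.sqrt(grad @ V @ grad))
        rows.append({"value": value, "probability": float(p.mean()), "se": se})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classification performance and diagnostics


@dataclass
class ROCResult:
    """Receiver-operating characteristic with trapezoidal AUC."""

    auc: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivities,
            "specificity": self.specificities,
        })


def roc_auc(outcomes, predicted) -> ROCResult:
    """ROC curve and AUC of predicted trigger probabilities.

    The AUC is the trapezoidal area over all distinct thresholds, which
    equals the Mann-Whitney probability of ranking a random detection above
    a random miss, ties counted one half.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(outcomes, dtype=float).reshape(-1)
    scores = np.asarray(predicted, dtype=float).reshape(-1)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined with a single outcome class")
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    return ROCResult(
        auc=float(np.trapezoid(tpr, fpr)),
        thresholds=thresholds,
        sensitivities=tpr,
        specificities=1.0 - fpr,
    )


def collinearity_check(trials, covariate_pair: tuple[str, str]) -> float:
    """Spearman rank correlation (midrank ties) between two covariates.

    Used to decide the two-suite strategy: the vertical angle is modelled
    separately from lens height and aiming distance when strongly
    rank-correlated with them.
    """
    frame = as_frame(trials)
    cols = [_TERM_COLUMNS.get(c, c) for c in covariate_pair]
    a = frame[cols[0]].to_numpy(dtype=float)
    b = frame[cols[1]].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("collinearity_check needs at least 3 rows")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("rank correlation is undefined for a constant covariate")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def combined_detection_probability(r_e: float, r_t: float, r_p: float, n_visits: int) -> float:
    """Overall probability of recording an animal across repeated visits.

    ``p = 1 - [1 - (r_e * r_t * r_p)]^N`` combines the probabilities of the
    animal encountering the camera's sample unit (r_e), triggering the
    camera (r_t), and yielding a usable image (r_p) over N visits.
    """
    for name, r in (("r_e", r_e), ("r_t", r_t), ("r_p", r_p)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r!r}")
    if n_visits < 0 or int(n_visits) != n_visits:
        raise ValueError(f"n_visits must be a nonnegative integer, got {n_visits!r}")
    return float(1.0 - (1.0 - r_e * r_t * r_p) ** int(n_visits))


# ---------------------------------------------------------------------------
# Estimator facade


class TriggerGLM(BaseEstimator):
    """Two-stage trigger-probability regression (scikit-learn style).

    Wraps the stage-2 logit-link binomial regression conditioned on a
    fitted stage-1 detection function, with optional backwards stepwise
    selection under the marginality rule.

    Parameters
    ----------
    terms : sequence of str
        Model terms; interactions as ``"A:B"``. Defaults to the
        vertical-angle suite.
    detection_function : DetectionFunction or DetectionFunctionSpec
        Stage-1 model supplying the ``distance_model`` covariate.
    stepwise : bool
        Apply backwards stepwise selection after the global fit.
    alpha : float
        Wald significance threshold for stepwise pruning.
    reference_levels : dict, optional
        Treatment-contrast baselines per categorical covariate.
    """

    def __init__(
        self,
        terms=ANGLE_SUITE_TERMS,
        detection_function=None,
        stepwise: bool = False,
        alpha: float = 0.05,
        reference_levels: dict[str, str] | None = None,
    ):
        self.terms = terms
        self.detection_function = detection_function
        self.stepwise = stepwise
        self.alpha = alpha
        self.reference_levels = reference_levels

    def fit(self, X, y=None):
        frame = as_frame(X)
        if y is None:
            if "outcome" not in frame.columns:
                raise ValueError("no outcomes: pass y or include an 'outcome' column")
            y = frame["outcome"].to_numpy(dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        refs = dict(DEFAULT_REFERENCE_LEVELS, **(self.reference_levels or {}))
        if self.stepwise:
            fit, final_terms = backward_stepwise(
                frame, y, list(self.terms), self.detection_function,
                alpha=self.alpha, reference_levels=self.reference_levels,
            )
        else:
            design, term_map = build_design_matrix(
                frame, list(self.terms), self.detection_function, self.reference_levels
            )
            fit = fit_logit(design, y, term_map=term_map, reference_levels=refs)
            final_terms = list(self.terms)
        self.result_ = fit
        self.terms_ = final_terms
        self.params_ = fit.params
        self.bse_ = fit.bse
        self.zvalues_ = fit.zvalues
        self.pvalues_ = fit.pvalues
        self.cov_params_ = fit.cov_params
        self.log_likelihood_ = fit.log_likelihood
        self.converged_ = fit.converged
        self.reference_levels_ = fit.reference_levels
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        p = predict_probability(self.result_, as_frame(X), self.detection_function)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def coefficient_table(self) -> pd.DataFrame:
        self._check_fitted()
        return self.result_.coefficient_table()

    def marginal_effects(self, X, focal: str, grid) -> pd.DataFrame:
        self._check_fitted()
        return marginal_effects(self.result_, as_frame(X), self.detection_function, focal, grid)

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise RuntimeError("TriggerGLM is not fitted yet; call fit first")

    def to_dict(self) -> dict:
        self._check_fitted()
        spec = _resolve_spec(self.detection_function)
        return {
            "terms": list(self.terms_),
            "coefficients": self.params_.to_dict(),
            "cov_params": {
                "labels": list(self.cov_params_.columns),
                "matrix": self.cov_params_.to_numpy().tolist(),
            },
            "reference_levels": dict(self.reference_levels_),
            "detection_function": spec.to_dict() if spec is not None else None,
            "log_likelihood": self.log_likelihood_,
            "converged": self.converged_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TriggerGLM":
        spec = (DetectionFunctionSpec.from_dict(d["detection_function"])
                if d.get("detection_function") else None)
        est = cls(terms=tuple(d["terms"]), detection_function=spec,
                  reference_levels=d.get("reference_levels"))
        labels = d["cov_params"]["labels"]
        params = pd.Series({k: d["coefficients"][k] for k in labels})
        cov = pd.DataFrame(np.asarray(d["cov_params"]["matrix"]), index=labels, columns=labels)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=labels)
        z = params / bse
        term_map: dict[str, list[str]] = {}
        for term in d["terms"]:
            term_map[term] = [c for c in labels if _belongs_to_term(c, term)]
        fit = LogitFit(
            params=params, bse=bse, zvalues=z,
            pvalues=pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=labels),
            cov_params=cov, log_likelihood=float(d.get("log_likelihood", np.nan)),
            converged=bool(d.get("converged", True)), n=0,
            reference_levels=dict(d.get("reference_levels", {})), term_map=term_map,
        )
        est.result_ = fit
        est.terms_ = list(d["terms"])
        est.params_ = params
        est.bse_ = bse
        est.zvalues_ = z
        est.pvalues_ = fit.pvalues
        est.cov_params_ = cov
        est.log_likelihood_ = fit.log_likelihood
        est.converged_ = fit.converged
        est.reference_levels_ = fit.reference_levels
        return est


def _belongs_to_term(column: str, term: str) -> bool:
    strip = lambda label: label.split("[")[0]
    col_parts = [strip(p) for p in column.split(":")]
    term_parts = term.split(":")
    return col_parts == term_parts
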