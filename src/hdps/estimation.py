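"""Propensity-score estimation, IPTW and the weighted outcome model.

The propensity score is fitted by maximum-likelihood logistic regression on
the pre-defined covariates, optionally augmented with the selected HDPS
covariates. Inverse probability of treatment weights target the average
treatment effect: ``1/ps`` for the exposed and ``1/(1-ps)`` for the
unexposed, optionally stabilised by the marginal exposure probabilities
(stabilisation rescales weights within each group and leaves the point
estimate unchanged). Optional percentile trimming of the PS distribution
handles positivity violations; the default is no trimming.

The treatment effect is a hazard ratio from a Cox model with exposure as the
sole term, fitted by weighted partial likelihood (Efron tie handling) with a
robust sandwich variance treating the weights as fixed — weight-estimation
uncertainty is not propagated, matching standard IPTW practice. The
confidence limit ratio (upper over lower 95% bound) summarises precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from hdps.io import CohortTable, ValidationError

logger = logging.getLogger(__name__)

# A logistic fit that classifies exposure essentially perfectly (residual
# deviance ~ 0) is completely separated; quasi-separated rare binary cells
# (common in HDPS fits) leave most of the deviance intact and are tolerated.
_SEPARATION_DEVIANCE = 1e-4


class SeparationError(RuntimeError):
    """The logistic fit produced fitted probabilities at machine 0/1."""


@dataclass
class PSResult:
    """A fitted propensity-score model."""

    label: str
    covariates: list[str]
    scores: pd.Series  # indexed by patient_id, strictly inside (0, 1)
    converged: bool
    dropped: list[str] = field(default_factory=list)
    coefficients: pd.Series | None = None


@dataclass
class WeightedAnalysis:
    """IPTW weights for a (possibly trimmed) analysis population."""

    ps: PSResult
    weights: pd.Series  # positive, indexed by patient_id, analysed patients only
    stabilized: bool
    trim_rule: tuple[float, float] | None
    n_trimmed: int

    @property
    def analysed_ids(self) -> pd.Index:
        return self.weights.index


@dataclass
class EffectEstimate:
    """Hazard ratio with robust 95% CI and confidence limit ratio."""

    label: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    clr: float
    n_events: int
    log_hr: float
    se_log_hr: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.hazard_ratio <= self.ci_upper):
            raise ValidationError("CI must bracket the hazard ratio")


def _independent_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedy removal of perfectly collinear columns via pivoted QR."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return X, []
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[i] for i in keep]


def fit_ps(
    cohort: CohortTable,
    predefined: list[str],
    hdps_covariates: pd.DataFrame | None = None,
    label: str = "ps",
) -> PSResult:
    """Fit the PS by logistic regression on predefined (+ HDPS) covariates.

    ``hdps_covariates`` is a patient-indexed 0/1 frame (e.g. a subset of a
    :class:`~hdps.features.CovariateMatrix`). Perfectly collinear columns
    are dropped with a logged list; non-convergence is reported on the
    result, and complete separation raises :class:`SeparationError`.
    """
    missing = [c for c in predefined if c not in cohort.data.columns]
    if missing:
        raise ValidationError(f"pre-defined covariate(s) not in cohort: {missing}")
    parts = [cohort.data[predefined].to_numpy(dtype=float)] if predefined else []
    names = list(predefined)
    if hdps_covariates is not None and hdps_covariates.shape[1]:
        aligned = hdps_covariates.reindex(cohort.patient_ids.values)
        if aligned.isna().any().any():
            raise ValidationError("HDPS covariates do not cover all cohort patients")
        parts.append(aligned.to_numpy(dtype=float))
        names += list(hdps_covariates.columns)
    X = np.column_stack(parts) if parts else np.empty((cohort.n, 0))
    X, kept = _independent_columns(X, names)
    dropped = [n for n in names if n not in kept]
    # The intercept itself can render a constant covariate redundant.
    const = X.std(axis=0) == 0
    if const.any():
        dropped += [n for n, c in zip(kept, const) if c]
        kept = [n for n, c in zip(kept, const) if not c]
        X = X[:, ~const]
    if dropped:
        logger.info("fit_ps[%s]: dropped collinear column(s): %s", label, dropped)

    design = sm.add_constant(X, has_constant="add")
    y = cohort.exposure.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    fitted = np.asarray(res.fittedvalues)
    if res.deviance < _SEPARATION_DEVIANCE or (fitted <= 0).any() or (fitted >= 1).any():
        raise SeparationError(
            "fitted propensity scores at machine 0/1 indicate separation; "
            "consider trimming the cohort or using fewer covariates"
        )
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("fit_ps[%s]: IRLS did not converge", label)
    scores = pd.Series(
        fitted, index=pd.Index(cohort.patient_ids.values, name="patient_id")
    )
    coefs = pd.Series(res.params, index=["const"] + kept)
    return PSResult(label, kept, scores, converged, dropped, coefs)


def c_statistic(ps: PSResult, cohort: CohortTable) -> float:
    """Concordance of the PS with exposure (area under the ROC curve)."""
    s = ps.scores.reindex(cohort.patient_ids.values).to_numpy()
    y = cohort.exposure.to_numpy()
    ranks = pd.Series(s).rank().to_numpy()
    n1, n0 = y.sum(), (1 - y).sum()
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def iptw_weights(
    ps: PSResult, exposure: pd.Series | np.ndarray, stabilized: bool = False
) -> pd.Series:
    """ATE inverse probability of treatment weights.

    Unstabilised: ``1/ps`` (exposed), ``1/(1-ps)`` (unexposed). Stabilised
    weights multiply by the marginal exposure probability of the patient's
    own group, giving mean weight ~1 per group.
    """
    s = ps.scores.to_numpy()
    x = np.asarray(exposure)
    w = np.where(x == 1, 1.0 / s, 1.0 / (1.0 - s))
    if stabilized:
        p = x.mean()
        w = np.where(x == 1, p, 1.0 - p) * w
    return pd.Series(w, index=ps.scores.index, name="iptw")


def make_weighted_analysis(
    ps: PSResult,
    cohort: CohortTable,
    stabilized: bool = False,
    trim: tuple[float, float] | None = None,
) -> WeightedAnalysis:
    """Weights (optionally after PS-percentile trimming) for a cohort."""
    wa = WeightedAnalysis(
        ps=ps,
        weights=iptw_weights(ps, cohort.exposure.to_numpy(), stabilized),
        stabilized=stabilized,
        trim_rule=None,
        n_trimmed=0,
    )
    if trim is not None:
        wa = trim_ps(wa, cohort, *trim)
    return wa


def trim_ps(
    analysis: WeightedAnalysis,
    cohort: CohortTable,
    lower_pct: float,
    upper_pct: float,
) -> WeightedAnalysis:
    """Remove patients outside the [lower, upper] PS percentiles.

    Percentiles are taken over the whole analysed PS distribution; (0, 100)
    is the identity. Trimming that empties an exposure group raises.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValidationError("require 0 <= lower_pct < upper_pct <= 100")
    scores = analysis.ps.scores.loc[analysis.analysed_ids]
    lo, hi = np.percentile(scores.to_numpy(), [lower_pct, upper_pct])
    keep = scores.index[(scores >= lo) & (scores <= hi)]
    n_trimmed = analysis.n_trimmed + (len(scores) - len(keep))
    exposure = cohort.data.set_index("patient_id")["exposure"].loc[keep]
    for grp, cnt in ((1, (exposure == 1).sum()), (0, (exposure == 0).sum())):
        if cnt == 0:
            raise ValidationError(f"trimming emptied exposure group {grp}")
    logger.info(
        "trim_ps[%s]: removed %d patient(s) (exposed kept %d, unexposed kept %d)",
        analysis.ps.label,
        n_trimmed,
        int((exposure == 1).sum()),
        int((exposure == 0).sum()),
    )
    return WeightedAnalysis(
        ps=analysis.ps,
        weights=analysis.weights.loc[keep],
        stabilized=analysis.stabilized,
        trim_rule=(lower_pct, upper_pct),
        n_trimmed=int(n_trimmed),
    )


def fit_weighted_cox(
    cohort: CohortTable,
    weights: pd.Series | np.ndarray | None = None,
    label: str = "cox",
) -> EffectEstimate:
    """Weighted Cox model with exposure as the sole term, robust 95% CI.

    ``weights=None`` fits the unweighted (crude) model. When ``weights`` is
    a patient-indexed Series covering only part of the cohort (after
    trimming), the fit is restricted to those patients.
    """
    df = cohort.data[["patient_id", "followup_time", "event", "exposure"]].copy()
    if weights is None:
        df["_w"] = 1.0
    elif isinstance(weights, pd.Series):
        df = df[df["patient_id"].isin(weights.index)]
        df["_w"] = weights.loc[df["patient_id"]].to_numpy()
    else:
        df["_w"] = np.asarray(weights, dtype=float)
    if (df["_w"] <= 0).any():
        raise ValidationError("weights must be positive")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValidationError("no outcome events in the analysis population")

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df.drop(columns="patient_id"),
            duration_col="followup_time",
            event_col="event",
            weights_col="_w",
            robust=True,
        )
    coef = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    lo, hi = np.exp(coef - 1.959963984540054 * se), np.exp(coef + 1.959963984540054 * se)
    return EffectEstimate(
        label=label,
        hazard_ratio=float(np.exp(coef)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        clr=compute_clr(lo, hi),
        n_events=n_events,
        log_hr=coef,
        se_log_hr=se,
    )


def compute_clr(ci_lower: float, ci_upper: float) -> float:
    """Confidence limit ratio: upper over lower confidence bound."""
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValidationError("confidence bounds must be positive")
    if ci_upper < ci_lower:
        raise ValidationError("ci_upper must be >= ci_lower")
    return ci_upper / ci_lower


def estimates_table(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Delimited-friendly summary table of effect estimates."""
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "hazard_ratio": e.hazard_ratio,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
                "clr": e.clr,
                "n_events": e.n_events,
            }
            for e in estimates
        ]
    )
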