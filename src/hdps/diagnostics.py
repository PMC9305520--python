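"""Diagnostics for HDPS models: balance, overlap, influential covariates.

Covers the diagnostic toolkit recommended for HDPS analyses:

* chapter-level concept summaries of the selected covariates per data
  dimension;
* propensity-score overlap between exposure groups, before and after adding
  the HDPS covariates to the model;
* covariate prevalence by treatment group with prevalence-ratio reference
  bands at 0.5 and 2.0;
* absolute standardised differences (ASD, percent scale; 10% is the
  conventional concern threshold), unweighted and under any number of
  candidate weight sets, plus mean ASDs optionally weighted by rank-based
  importance weights ``((N+1) - rank)/N`` (pre-defined covariates weight 1);
* the rank-ordered distribution of absolute log Bross bias values;
* the covariate-exposure vs covariate-outcome association scatter and the
  empirical near-instrument rule: flag a covariate when
  ``|log rr_ce| > tau_exposure`` and ``|log rr_cd| < tau_outcome`` (natural
  log; presets ``tau_exposure`` in {1.5, 1.1}, ``tau_outcome`` = 0.5 — the
  lower exposure threshold is the more inclusive rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hdps.estimation import PSResult
from hdps.features import CovariateMatrix
from hdps.io import CodeHierarchy, CohortTable, ValidationError
from hdps.prioritise import CONTINUITY

#: Conventional balance concern threshold, percent scale.
ASD_REFERENCE = 10.0

#: Prevalence-ratio reference band for the prevalence scatter.
PR_BAND = (0.5, 2.0)


@dataclass(frozen=True)
class NearIVRule:
    """Empirical near-instrument rule on |log risk ratios| (natural log)."""

    tau_exposure: float = 1.1
    tau_outcome: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_exposure <= 0 or self.tau_outcome <= 0:
            raise ValidationError("near-IV thresholds must be > 0")


#: The stricter preset flags fewer covariates; the 1.1 preset is a superset.
NEAR_IV_STRICT = NearIVRule(tau_exposure=1.5)
NEAR_IV_RELAXED = NearIVRule(tau_exposure=1.1)


def asd_binary(p1: float, p0: float) -> float:
    """Absolute standardised difference (percent) of a binary covariate.

    ``100 |p1 - p0| / sqrt((p1(1-p1) + p0(1-p0))/2)``; 0 when both group
    variances vanish (both prevalences 0 or both 1).
    """
    if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
        raise ValidationError("prevalences must lie in [0, 1]")
    var = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    if var == 0:
        return 0.0
    return 100.0 * abs(p1 - p0) / math.sqrt(var)


def asd_continuous(m1, m0, v1, v0) -> float:
    """Two-sample standardised difference (percent) with pooled variance."""
    var = (v1 + v0) / 2.0
    if var == 0:
        return 0.0
    return 100.0 * abs(m1 - m0) / math.sqrt(var)


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    total = w.sum()
    if total <= 0:
        raise ValidationError("weight set with non-positive total in a group")
    return float((w * x).sum() / total)


def balance_table(
    covariates: pd.DataFrame,
    cohort: CohortTable,
    weight_sets: dict[str, pd.Series] | None = None,
    binary: list[str] | None = None,
    weighted_denominator: bool = False,
) -> pd.DataFrame:
    """Per-covariate ASDs, unweighted and under each candidate weight set.

    ``covariates`` is a patient-indexed frame mixing binary HDPS columns and
    (binary or continuous) pre-defined columns; columns named in ``binary``
    (default: all 0/1-valued columns) use the binary-prevalence ASD, others
    the pooled-variance continuous ASD. Weighted ASDs compare weighted group
    prevalences/means; by default the denominator keeps the *unweighted*
    variances so the weighted and unweighted columns share one scale (set
    ``weighted_denominator=True`` for fully weighted variances). A weight
    set covering only part of the cohort (after trimming) is evaluated on
    its own patients.
    """
    weight_sets = weight_sets or {}
    aligned = covariates.reindex(cohort.patient_ids.values)
    if aligned.isna().any().any():
        raise ValidationError("covariate frame does not cover all cohort patients")
    X = cohort.exposure.to_numpy()
    if binary is None:
        binary = [
            c for c in aligned.columns if set(np.unique(aligned[c])) <= {0, 1, 0.0, 1.0}
        ]
    rows = []
    for col in aligned.columns:
        x = aligned[col].to_numpy(dtype=float)
        is_bin = col in binary
        p1, p0 = x[X == 1].mean(), x[X == 0].mean()
        v1, v0 = x[X == 1].var(ddof=1), x[X == 0].var(ddof=1)
        row = {
            "name": col,
            "type": "binary" if is_bin else "continuous",
            "mean_exposed": p1,
            "mean_unexposed": p0,
            "asd_unweighted": asd_binary(p1, p0) if is_bin else asd_continuous(p1, p0, v1, v0),
        }
        for wl, wseries in weight_sets.items():
            mask = cohort.patient_ids.isin(wseries.index).to_numpy()
            w = wseries.loc[cohort.patient_ids[mask]].to_numpy()
            xw, Xw = x[mask], X[mask]
            w1, w0 = w[Xw == 1], w[Xw == 0]
            m1 = _weighted_mean(xw[Xw == 1], w1)
            m0 = _weighted_mean(xw[Xw == 0], w0)
            row[f"mean_exposed_{wl}"] = m1
            row[f"mean_unexposed_{wl}"] = m0
            if is_bin:
                if weighted_denominator:
                    row[f"asd_{wl}"] = asd_binary(m1, m0)
                else:
                    var = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
                    row[f"asd_{wl}"] = (
                        0.0 if var == 0 else 100.0 * abs(m1 - m0) / math.sqrt(var)
                    )
            else:
                if weighted_denominator:
                    vv1 = _weighted_mean((xw[Xw == 1] - m1) ** 2, w1)
                    vv0 = _weighted_mean((xw[Xw == 0] - m0) ** 2, w0)
                else:
                    vv1, vv0 = v1, v0
                row[f"asd_{wl}"] = asd_continuous(m1, m0, vv1, vv0)
        rows.append(row)
    return pd.DataFrame(rows)


def importance_weight(rank: int, N: int) -> float:
    """Rank-based importance weight ``((N+1) - rank)/N`` in (0, 1].

    Rank 1 (highest priority) gets weight 1; rank N gets ``1/N``.
    Pre-defined covariates, which have no rank, conventionally get weight 1.
    """
    if not 1 <= rank <= N:
        raise ValidationError(f"rank must lie in 1..{N}, got {rank}")
    return ((N + 1) - rank) / N


def mean_asd(
    asds,
    importance: bool = False,
    ranks=None,
    N: int | None = None,
    weights=None,
) -> float:
    """Mean ASD, optionally importance-weighted.

    With ``importance=True`` either pass per-covariate ``weights`` directly
    or ``ranks`` (NaN/None entries mean pre-defined, weight 1) together with
    the ranked-set size ``N``.
    """
    asds = np.asarray(asds, dtype=float)
    if asds.size == 0:
        raise ValidationError("mean_asd of an empty set")
    if not importance:
        return float(asds.mean())
    if weights is None:
        if ranks is None:
            raise ValidationError("importance weighting needs ranks or weights")
        if N is None:
            N = int(np.nanmax(np.asarray(ranks, dtype=float)))
        weights = np.array(
            [
                1.0 if r is None or (isinstance(r, float) and math.isnan(r))
                else importance_weight(int(r), N)
                for r in ranks
            ]
        )
    weights = np.asarray(weights, dtype=float)
    return float((weights * asds).sum() / weights.sum())


def ps_overlap_summary(
    ps_predefined: PSResult,
    ps_hdps: PSResult,
    cohort: CohortTable,
    n_bins: int = 100,
) -> dict:
    """Binned PS densities per exposure group and overlap coefficients.

    Returns ``{"grid": bin edges, "densities": {model: {0: .., 1: ..}},
    "overlap": {model: coefficient}}`` where the overlap coefficient is the
    area under the pointwise minimum of the two group densities on
    ``n_bins`` equal-width bins over [0, 1] (1 = identical, 0 = disjoint).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    width = 1.0 / n_bins
    X = cohort.exposure.to_numpy()
    out = {"grid": edges, "densities": {}, "overlap": {}}
    for ps in (ps_predefined, ps_hdps):
        s = ps.scores.reindex(cohort.patient_ids.values).to_numpy()
        d1, _ = np.histogram(s[X == 1], bins=edges, density=True)
        d0, _ = np.histogram(s[X == 0], bins=edges, density=True)
        out["densities"][ps.label] = {1: d1, 0: d0}
        out["overlap"][ps.label] = float(np.minimum(d1, d0).sum() * width)
    return out


def prevalence_scatter(prioritised: pd.DataFrame) -> pd.DataFrame:
    """Group prevalences per covariate with prevalence-ratio band flags.

    Adds ``pr`` (continuity-corrected where a prevalence is 0) and
    ``outside_band`` for covariates with PR outside [0.5, 2.0].
    """
    df = prioritised[["name", "dimension", "pc1", "pc0"]].copy()
    pc1 = df["pc1"].to_numpy(dtype=float)
    pc0 = df["pc0"].to_numpy(dtype=float)
    zero = (pc1 == 0) | (pc0 == 0)
    # 0.1-per-cell correction on the prevalence scale: treat prevalences as
    # proportions of a unit table.
    pr = np.where(
        zero,
        (pc1 + CONTINUITY) / (pc0 + CONTINUITY),
        np.divide(pc1, pc0, out=np.ones_like(pc1), where=pc0 > 0),
    )
    df["pr"] = pr
    df["pr_corrected"] = zero
    df["outside_band"] = (pr < PR_BAND[0]) | (pr > PR_BAND[1]) | zero
    return df


def bias_distribution(ranked: pd.DataFrame) -> pd.DataFrame:
    """Rank-ordered |log Bross bias| values with per-dimension counts.

    Returns the ranked table sorted by rank (so ``abs_log_bias`` is
    monotone non-increasing) with an attached ``.attrs['dimension_counts']``
    mapping each dimension to its covariate count.
    """
    if "rank" not in ranked.columns:
        raise ValidationError("bias_distribution expects a ranked table")
    df = (
        ranked[["rank", "name", "dimension", "abs_log_bias"]]
        .sort_values("rank", kind="stable")
        .reset_index(drop=True)
    )
    df.attrs["dimension_counts"] = df["dimension"].value_counts().to_dict()
    return df


def association_scatter(prioritised: pd.DataFrame) -> pd.DataFrame:
    """Exposure vs outcome association strengths ``|rr - 1|`` per covariate.

    Covariates in the top-left region (high exposure strength, low outcome
    strength) behave empirically like instruments; ``near_iv_strict`` /
    ``near_iv_relaxed`` give the rule-based flags on the log-RR scale,
    reported alongside because |rr - 1| and |log rr| are different scales.
    """
    df = prioritised[["name", "dimension", "rr_ce", "rr_cd"]].copy()
    df["strength_exposure"] = np.abs(df["rr_ce"].astype(float) - 1.0)
    df["strength_outcome"] = np.abs(df["rr_cd"].astype(float) - 1.0)
    df["near_iv_strict"] = df["name"].isin(flag_near_ivs(prioritised, NEAR_IV_STRICT))
    df["near_iv_relaxed"] = df["name"].isin(flag_near_ivs(prioritised, NEAR_IV_RELAXED))
    return df


def flag_near_ivs(prioritised: pd.DataFrame, rule: NearIVRule) -> list[str]:
    """Names of covariates behaving empirically like instruments.

    Flags ``|log rr_ce| > tau_exposure`` and ``|log rr_cd| < tau_outcome``.
    Lowering ``tau_exposure`` can only add flags (monotone rule).
    """
    lce = np.abs(np.log(prioritised["rr_ce"].astype(float)))
    lcd = np.abs(np.log(prioritised["rr_cd"].astype(float)))
    mask = (lce > rule.tau_exposure) & (lcd < rule.tau_outcome)
    return prioritised.loc[mask, "name"].tolist()


def concept_summary(
    selected: pd.DataFrame, hierarchy: CodeHierarchy
) -> pd.DataFrame:
    """Counts of selected covariates by (dimension, chapter).

    ``selected`` needs ``dimension`` and ``code`` columns (e.g. the top-k
    slice of a ranked prioritisation table). Every covariate is counted
    once; unmapped codes fall under the hierarchy's unmapped label. Counts
    sum to the number of selected covariates.
    """
    if len(selected) == 0:
        return pd.DataFrame(columns=["dimension", "chapter", "n"])
    df = selected[["dimension", "code"]].copy()
    df["chapter"] = [hierarchy.lookup(c) for c in df["code"]]
    return (
        df.groupby(["dimension", "chapter"])
        .size()
        .reset_index(name="n")
        .sort_values(["dimension", "chapter"], kind="stable")
        .reset_index(drop=True)
    )
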