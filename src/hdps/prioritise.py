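"""Covariate prioritisation by confounding potential (HDPS steps four/five).

For every binary proxy covariate C the procedure tabulates two 2x2 tables
against exposure X and outcome D and computes

* ``pc1 = P(C=1 | X=1)``, ``pc0 = P(C=1 | X=0)`` and their ratio
  ``rr_ce`` (covariate-exposure risk ratio);
* ``rr_cd = P(D=1 | C=1) / P(D=1 | C=0)`` (covariate-outcome risk ratio,
  by default from the binary any-event indicator ignoring follow-up time; a
  person-time rate-ratio variant is available via ``outcome_measure="rate"``);
* the Bross bias multiplier

  .. math::

     \\mathrm{bias} = \\frac{p_{c1}(rr - 1) + 1}{p_{c0}(rr - 1) + 1},
     \\qquad rr = \\max(rr_{cd},\\ 1/rr_{cd}),

  an upper bound on the multiplicative confounding bias a binary covariate
  with these margins could induce. The inversion of protective outcome
  associations (``rr -> max(rr, 1/rr)``) keeps protective confounders from
  ranking spuriously low.

Covariates are ranked by descending ``|log bias|`` (or ``|log rr_ce|`` under
exposure-only ranking, used when outcome events are few), ties broken by
name, and the top *k* are selected to augment the pre-defined covariates.

Zero cells are handled by adding 0.1 to every cell of the affected 2x2 table
before computing that ratio (the convention of the original HDPS macro).
Covariates constant across all patients carry no information and are
excluded, with the reason logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hdps.features import CovariateMatrix
from hdps.io import CohortTable, ValidationError

logger = logging.getLogger(__name__)

#: Continuity correction added to each cell of a 2x2 table with a zero cell.
CONTINUITY = 0.1

RANKING_METHODS = ("bross", "exposure_only")


def bross_bias(pc1: float, pc0: float, rr_cd: float) -> float:
    """Bross bias multiplier for a binary covariate.

    Parameters are the covariate prevalence in the exposed (``pc1``) and
    unexposed (``pc0``) and the covariate-outcome risk ratio. The outcome
    association enters as ``max(rr_cd, 1/rr_cd)`` so protective and harmful
    associations of equal strength score equally.
    """
    if not (0 <= pc1 <= 1 and 0 <= pc0 <= 1):
        raise ValidationError("prevalences must lie in [0, 1]")
    if rr_cd <= 0:
        raise ValidationError("rr_cd must be positive")
    rr = max(rr_cd, 1.0 / rr_cd)
    return (pc1 * (rr - 1.0) + 1.0) / (pc0 * (rr - 1.0) + 1.0)


def _ratio_with_continuity(num_events, num_total, den_events, den_total):
    """Vectorised a/n1 over b/n0 ratio; +0.1 per cell where the table has a zero.

    Cells are (events, non-events) in each arm.
    """
    num_events = np.asarray(num_events, dtype=float)
    num_total = np.asarray(num_total, dtype=float)
    den_events = np.asarray(den_events, dtype=float)
    den_total = np.asarray(den_total, dtype=float)
    zero_cell = (
        (num_events == 0)
        | (den_events == 0)
        | (num_total - num_events == 0)
        | (den_total - den_events == 0)
    )
    ne = np.where(zero_cell, num_events + CONTINUITY, num_events)
    nt = np.where(zero_cell, num_total + 2 * CONTINUITY, num_total)
    de = np.where(zero_cell, den_events + CONTINUITY, den_events)
    dt = np.where(zero_cell, den_total + 2 * CONTINUITY, den_total)
    return (ne / nt) / (de / dt)


def univariate_associations(
    cov: CovariateMatrix | pd.DataFrame,
    cohort: CohortTable,
    outcome_measure: str = "risk",
) -> pd.DataFrame:
    """Tabulate covariate-exposure and covariate-outcome associations.

    Returns an unranked table with one row per covariate: ``name``,
    ``dimension``, ``code``, ``cutoff`` (where a dictionary is available),
    ``pc1``, ``pc0``, ``rr_ce``, ``rr_cd``, ``bias_m``, ``abs_log_bias``.

    ``outcome_measure="risk"`` uses the binary any-event indicator;
    ``"rate"`` uses person-time incidence-rate ratios instead.
    """
    if outcome_measure not in ("risk", "rate"):
        raise ValidationError(f"unknown outcome_measure {outcome_measure!r}")
    if isinstance(cov, CovariateMatrix):
        values = cov.aligned(cohort)
        dictionary = cov.dictionary.set_index("name") if len(cov.dictionary) else None
    else:
        values = cov.reindex(cohort.patient_ids.values)
        dictionary = None
    if values.isna().any().any():
        raise ValidationError("covariate matrix does not cover all cohort patients")

    X = cohort.exposure.to_numpy()
    D = cohort.event.to_numpy()
    T = cohort.data["followup_time"].to_numpy()
    C = values.to_numpy(dtype=float)
    names = np.asarray(values.columns)

    constant = (C.min(axis=0) == C.max(axis=0))
    if constant.any():
        for nm in names[constant]:
            logger.info("excluding covariate %r: constant across all patients", nm)
    C = C[:, ~constant]
    names = names[~constant]
    if C.shape[1] == 0:
        return pd.DataFrame(
            columns=[
                "name", "dimension", "code", "cutoff",
                "pc1", "pc0", "rr_ce", "rr_cd", "bias_m", "abs_log_bias",
            ]
        )

    n1, n0 = X.sum(), (1 - X).sum()
    c_in_exposed = C[X == 1].sum(axis=0)
    c_in_unexposed = C[X == 0].sum(axis=0)
    pc1 = c_in_exposed / n1
    pc0 = c_in_unexposed / n0
    rr_ce = _ratio_with_continuity(c_in_exposed, n1, c_in_unexposed, n0)

    m1 = C.sum(axis=0)  # patients with C=1
    m0 = C.shape[0] - m1
    e1 = (C * D[:, None]).sum(axis=0)
    e0 = D.sum() - e1
    if outcome_measure == "risk":
        rr_cd = _ratio_with_continuity(e1, m1, e0, m0)
    else:
        t1 = (C * T[:, None]).sum(axis=0)
        t0 = T.sum() - t1
        zero = (e1 == 0) | (e0 == 0)
        e1c = np.where(zero, e1 + CONTINUITY, e1)
        e0c = np.where(zero, e0 + CONTINUITY, e0)
        rr_cd = (e1c / t1) / (e0c / t0)

    rr = np.maximum(rr_cd, 1.0 / rr_cd)
    bias = (pc1 * (rr - 1.0) + 1.0) / (pc0 * (rr - 1.0) + 1.0)

    out = pd.DataFrame(
        {
            "name": names,
            "pc1": pc1,
            "pc0": pc0,
            "rr_ce": rr_ce,
            "rr_cd": rr_cd,
            "bias_m": bias,
            "abs_log_bias": np.abs(np.log(bias)),
        }
    )
    if dictionary is not None:
        meta = dictionary.reindex(out["name"])[["dimension", "code", "cutoff"]]
        out.insert(1, "dimension", meta["dimension"].to_numpy())
        out.insert(2, "code", meta["code"].to_numpy())
        out.insert(3, "cutoff", meta["cutoff"].to_numpy())
    else:
        out.insert(1, "dimension", pd.NA)
        out.insert(2, "code", pd.NA)
        out.insert(3, "cutoff", pd.NA)
    return out


def rank_covariates(table: pd.DataFrame, method: str = "bross") -> pd.DataFrame:
    """Assign ranks 1..N by descending priority score.

    ``bross`` ranks on ``|log bias_m|``; ``exposure_only`` on
    ``|log rr_ce|``. Ties broken by covariate name so ranks are always a
    permutation of 1..N.
    """
    if method not in RANKING_METHODS:
        raise ValidationError(
            f"unknown ranking method {method!r}; expected one of {RANKING_METHODS}"
        )
    if len(table) == 0:
        raise ValidationError("cannot rank an empty covariate table")
    df = table.copy()
    score = (
        df["abs_log_bias"]
        if method == "bross"
        else np.abs(np.log(df["rr_ce"].astype(float)))
    )
    df["_score"] = np.asarray(score, dtype=float)
    df = df.sort_values(["_score", "name"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_score").reset_index(drop=True)


def select_top_k(ranked: pd.DataFrame, k: int) -> list[str]:
    """Names of the top-``k`` ranked covariates (all of them when k > N)."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    if "rank" not in ranked.columns:
        raise ValidationError("table is not ranked; call rank_covariates first")
    if k > len(ranked):
        logger.info("k=%d exceeds the %d available covariates; selecting all", k, len(ranked))
    ordered = ranked.sort_values("rank", kind="stable")
    return ordered["name"].head(min(k, len(ranked))).tolist()


def write_prioritisation(ranked: pd.DataFrame, path) -> None:
    """Write the full prioritisation table (the data behind the bias-
    distribution and association-scatter diagnostics)."""
    ranked.to_csv(path, index=False)
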