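"""Sensitivity analyses over the fitted HDPS pipeline.

Three families of scenario, all reusing the single prioritisation computed
by the primary run (estimates depend only on k and removals, never on
re-ranking):

* :func:`vary_k` — refit the whole PS -> IPTW -> Cox chain for a discrete
  set of k values, always alongside the crude and predefined-only models;
* :func:`incremental_curve` — estimates along a k grid (0, stride,
  2*stride, ..., N) with a numerical stabilisation summary (the maximum
  pairwise |Δ log HR| over the top half of the grid);
* :func:`remove_and_refit` — keep only the top-m ranked covariates, drop
  covariates flagged by a near-instrument rule, or drop an explicit name
  list, reporting covariates removed/retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hdps.diagnostics import NearIVRule, flag_near_ivs
from hdps.estimation import EffectEstimate
from hdps.io import ValidationError
from hdps.pipeline import HDPSRun

logger = logging.getLogger(__name__)


@dataclass
class SensitivityResult:
    """One sensitivity scenario's covariate accounting and estimate."""

    label: str
    k: int
    removed: list[str]
    n_removed: int
    estimate: EffectEstimate | None
    error: str | None = None


def _safe(run: HDPSRun, names: list[str], label: str, removed: list[str], k: int):
    try:
        est = run.refit(names, label)
        return SensitivityResult(label, k, removed, len(removed), est)
    except Exception as exc:  # record per-scenario failure, keep going
        logger.warning("scenario %r failed: %s", label, exc)
        return SensitivityResult(label, k, removed, len(removed), None, str(exc))


def vary_k(run: HDPSRun, k_values: list[int]) -> list[SensitivityResult]:
    """Full re-fits for each k, plus the crude and predefined-only scenarios.

    Duplicate k values (including a duplicate of the primary k) are
    de-duplicated with a logged notice.
    """
    if not k_values:
        raise ValidationError("k_values must be non-empty")
    if any(k < 0 for k in k_values):
        raise ValidationError("k values must be >= 0")
    seen, unique_k = set(), []
    for k in k_values:
        if k in seen:
            logger.info("duplicate k=%d ignored", k)
            continue
        seen.add(k)
        unique_k.append(k)

    results = [
        SensitivityResult("crude", 0, [], 0, run.estimates["crude"]),
        SensitivityResult("predefined_only", 0, [], 0, run.estimates["predefined"]),
    ]
    ordered = run.priority.sort_values("rank", kind="stable")["name"].tolist()
    for k in unique_k:
        names = ordered[: min(k, len(ordered))]
        results.append(_safe(run, names, f"hdps_k{k}", [], len(names)))
    return results


def incremental_curve(run: HDPSRun, stride: int) -> pd.DataFrame:
    """Estimates for k = 0, stride, 2*stride, ..., N along the fixed ranking.

    The returned frame has one row per k (log HR, HR, CI) and carries a
    stabilisation summary in ``.attrs['max_delta_log_hr_top_half']``: the
    maximum pairwise |Δ log HR| among the grid points in the upper half of
    the k range, a numerical stand-in for judging by eye whether the trace
    has flattened.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    N = len(run.priority)
    ks = list(range(0, N + 1, stride))
    if ks[-1] != N:
        ks.append(N)
    ordered = run.priority.sort_values("rank", kind="stable")["name"].tolist()
    rows = []
    for k in ks:
        res = _safe(run, ordered[:k], f"hdps_k{k}", [], k)
        if res.estimate is None:
            rows.append({"k": k, "log_hr": np.nan, "hazard_ratio": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan, "error": res.error})
        else:
            e = res.estimate
            rows.append({"k": k, "log_hr": e.log_hr, "hazard_ratio": e.hazard_ratio,
                         "ci_lower": e.ci_lower, "ci_upper": e.ci_upper, "error": None})
    curve = pd.DataFrame(rows)
    top = curve[curve["k"] >= N / 2]["log_hr"].dropna().to_numpy()
    curve.attrs["max_delta_log_hr_top_half"] = (
        float(np.max(top) - np.min(top)) if top.size >= 2 else 0.0
    )
    return curve


def remove_and_refit(
    run: HDPSRun,
    top_m_only: int | None = None,
    near_iv_rule: NearIVRule | None = None,
    remove_names: list[str] | None = None,
    label: str | None = None,
) -> SensitivityResult:
    """Refit after restricting or pruning the selected HDPS covariates.

    Exactly one of ``top_m_only`` (keep only the m best-ranked selected
    covariates), ``near_iv_rule`` (drop selected covariates the rule flags)
    or ``remove_names`` (drop an explicit list) must be given. The result
    reports covariates removed and total retained.
    """
    given = [x is not None for x in (top_m_only, near_iv_rule, remove_names)]
    if sum(given) != 1:
        raise ValidationError(
            "specify exactly one of top_m_only, near_iv_rule, remove_names"
        )
    selected = list(run.selected)
    if top_m_only is not None:
        if top_m_only < 0:
            raise ValidationError("top_m_only must be >= 0")
        keep = selected[:top_m_only]
        removed = selected[top_m_only:]
        label = label or f"top_{top_m_only}_only"
    elif near_iv_rule is not None:
        flagged = set(flag_near_ivs(run.priority, near_iv_rule))
        keep = [n for n in selected if n not in flagged]
        removed = [n for n in selected if n in flagged]
        label = label or (
            f"near_iv_removed_tau{near_iv_rule.tau_exposure:g}"
        )
    else:
        drop = set(remove_names)
        unknown = drop - set(selected)
        if unknown:
            logger.info("remove_and_refit: %d name(s) not in selection", len(unknown))
        keep = [n for n in selected if n not in drop]
        removed = [n for n in selected if n in drop]
        label = label or "explicit_removal"
    return _safe(run, keep, label, removed, len(keep))


def sensitivity_table(results: list[SensitivityResult]) -> pd.DataFrame:
    """Delimited-friendly summary mirroring the standard sensitivity layout:
    scenario, covariates removed, total HDPS covariates, HR (95% CI), CLR."""
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValidationError("scenario labels must be unique within a run")
    rows = []
    for r in results:
        row = {
            "label": r.label,
            "n_removed": r.n_removed,
            "n_hdps_covariates": r.k,
        }
        if r.estimate is not None:
            row.update(
                hazard_ratio=r.estimate.hazard_ratio,
                ci_lower=r.estimate.ci_lower,
                ci_upper=r.estimate.ci_upper,
                clr=r.estimate.clr,
            )
        else:
            row.update(hazard_ratio=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                       clr=np.nan)
        row["error"] = r.error
        rows.append(row)
    return pd.DataFrame(rows)
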