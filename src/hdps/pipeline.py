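"""End-to-end HDPS pipeline orchestration.

One :func:`run_hdps` call executes the full procedure on a cohort plus its
data dimensions: pre-exposure restriction, per-dimension prevalence filter,
recurrence expansion, univariate associations, Bross (or exposure-only)
ranking, top-k selection, PS fits for the predefined-only and
predefined+HDPS models, IPTW, and crude / predefined-only / HDPS-weighted
Cox estimates. The prioritisation is computed exactly once per run; every
sensitivity scenario reuses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from hdps.estimation import (
    EffectEstimate,
    PSResult,
    WeightedAnalysis,
    fit_ps,
    fit_weighted_cox,
    make_weighted_analysis,
)
from hdps.features import CovariateMatrix, build_covariate_matrix
from hdps.io import CohortTable, DimensionTable, ValidationError
from hdps.prioritise import rank_covariates, select_top_k, univariate_associations


@dataclass(frozen=True)
class HDPSConfig:
    """Tuning parameters of one HDPS run.

    ``n_top`` codes per dimension pass the prevalence filter; ``k`` HDPS
    covariates augment the pre-defined set; ``ranking`` is ``"bross"`` or
    ``"exposure_only"``; ``trim`` is an optional (lower, upper) PS
    percentile pair (default: no trimming); ``stabilized`` switches IPTW
    stabilisation; ``outcome_measure`` is ``"risk"`` or ``"rate"`` for the
    prioritisation's covariate-outcome association.
    """

    lookback_days: int = 365
    n_top: int = 200
    ranking: str = "bross"
    k: int = 100
    stabilized: bool = False
    trim: tuple[float, float] | None = None
    outcome_measure: str = "risk"


@dataclass
class HDPSRun:
    """Artefacts of one full HDPS pipeline run."""

    cohort: CohortTable
    dimensions: list[DimensionTable]
    config: HDPSConfig
    covariates: CovariateMatrix
    priority: pd.DataFrame  # ranked prioritisation table
    selected: list[str]
    ps_predefined: PSResult
    ps_hdps: PSResult
    analysis: WeightedAnalysis
    estimates: dict[str, EffectEstimate] = field(default_factory=dict)

    def refit(self, hdps_names: list[str], label: str) -> EffectEstimate:
        """PS -> weights -> weighted Cox for an alternative HDPS subset.

        Removing or changing covariates triggers full PS re-estimation and
        re-weighting; weights are never reused across covariate sets.
        """
        if hdps_names:
            ps = fit_ps(
                self.cohort,
                self.cohort.predefined,
                self.covariates.values[hdps_names],
                label=label,
            )
        else:
            ps = fit_ps(self.cohort, self.cohort.predefined, None, label=label)
        wa = make_weighted_analysis(
            ps, self.cohort, stabilized=self.config.stabilized, trim=self.config.trim
        )
        return fit_weighted_cox(self.cohort, wa.weights, label=label)


def run_hdps(
    cohort: CohortTable,
    dimensions: list[DimensionTable],
    config: HDPSConfig = HDPSConfig(),
) -> HDPSRun:
    """Execute the five HDPS steps plus estimation on a loaded study."""
    covariates = build_covariate_matrix(
        dimensions, cohort, lookback_days=config.lookback_days, n_top=config.n_top
    )
    if len(covariates) == 0:
        raise ValidationError("no covariates generated; check dimensions and window")
    assoc = univariate_associations(
        covariates, cohort, outcome_measure=config.outcome_measure
    )
    priority = rank_covariates(assoc, method=config.ranking)
    selected = select_top_k(priority, config.k)

    ps_predefined = fit_ps(cohort, cohort.predefined, None, label="predefined")
    if selected:
        ps_hdps = fit_ps(
            cohort, cohort.predefined, covariates.values[selected], label="hdps"
        )
    else:
        ps_hdps = ps_predefined
    analysis = make_weighted_analysis(
        ps_hdps, cohort, stabilized=config.stabilized, trim=config.trim
    )
    wa_predefined = make_weighted_analysis(
        ps_predefined, cohort, stabilized=config.stabilized, trim=config.trim
    )

    estimates = {
        "crude": fit_weighted_cox(cohort, None, label="crude"),
        "predefined": fit_weighted_cox(cohort, wa_predefined.weights, label="predefined"),
        "hdps": fit_weighted_cox(cohort, analysis.weights, label="hdps"),
    }
    return HDPSRun(
        cohort=cohort,
        dimensions=dimensions,
        config=config,
        covariates=covariates,
        priority=priority,
        selected=selected,
        ps_predefined=ps_predefined,
        ps_hdps=ps_hdps,
        analysis=analysis,
        estimates=estimates,
    )
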