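"""Pre-exposure feature generation and recurrence-based covariate expansion.

Steps one to three of the HDPS procedure: restrict each data dimension to the
pre-exposure lookback window, keep the most common codes per dimension
(prevalence filter), and expand each retained feature into up to three binary
recurrence covariates per patient —

``once``
    the code appears at least once in the window;
``sporadic``
    at least as often as the median count among patients with >= 1 record;
``frequent``
    at least as often as the 75th-percentile count among those patients.

Thresholds use the nearest-rank percentile (no interpolation), computed among
patients with at least one occurrence — computed over the whole cohort the
median would be 0 for any code under 50% prevalence and every cut-off would
collapse to ``once``. When two cut-offs give element-wise identical indicator
columns for the same code (e.g. median = 1) the columns are collapsed keeping
the least stringent name, and the merge is recorded.

The pre-exposure window is half-open, ``[index_date - lookback, index_date)``:
records on the index date itself are ambiguous pre/post exposure and are
always excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hdps.io import CohortTable, DimensionTable, ValidationError

CUTOFFS = ("once", "sporadic", "frequent")


@dataclass(frozen=True)
class Feature:
    """A code that passed the prevalence filter in one dimension."""

    dimension_name: str
    code: str
    n_patients_with_code: int
    prevalence: float


@dataclass
class CovariateMatrix:
    """Patient x binary-covariate matrix with its covariate dictionary.

    ``values`` is indexed by patient_id with int8 0/1 columns named
    ``<dimension>__<code>__<cutoff>``. ``dictionary`` holds one row per
    column (name, dimension, code, cutoff, threshold, prevalence) and
    ``merge_map`` records collapsed duplicate columns (dropped -> kept).
    """

    values: pd.DataFrame
    dictionary: pd.DataFrame
    merge_map: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return self.values.shape[1]

    def aligned(self, cohort: CohortTable) -> pd.DataFrame:
        """Values reindexed to the cohort's patient order."""
        return self.values.reindex(cohort.patient_ids.values)


def covariate_name(dimension: str, code: str, cutoff: str) -> str:
    return f"{dimension}__{code}__{cutoff}"


def nearest_rank(values, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValidationError("nearest_rank of an empty set")
    idx = max(int(math.ceil(pct / 100.0 * arr.size)), 1)
    return arr[idx - 1]


def restrict_pre_exposure(
    dim: DimensionTable, cohort: CohortTable, lookback_days: int
) -> DimensionTable:
    """Keep records with ``index_date - lookback <= date < index_date``."""
    if lookback_days < 1:
        raise ValidationError("lookback_days must be >= 1")
    idx = cohort.data.set_index("patient_id")["index_date"]
    rec = dim.records
    index_date = rec["patient_id"].map(idx)
    delta = (index_date - rec["date"]).dt.days
    keep = (delta >= 1) & (delta <= lookback_days)
    return DimensionTable(dim.name, rec.loc[keep])


def prevalence_filter(
    dim: DimensionTable, cohort: CohortTable, n_top: int
) -> list[Feature]:
    """Retain the ``n_top`` codes recorded for the most patients.

    A patient with several records of one code counts once. Ties are broken
    by lexicographic code order for determinism.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if len(dim.records) == 0:
        return []
    counts = (
        dim.records.drop_duplicates(["patient_id", "code"])
        .groupby("code")
        .size()
        .reset_index(name="n")
        .sort_values(["n", "code"], ascending=[False, True], kind="stable")
        .head(n_top)
    )
    return [
        Feature(dim.name, row.code, int(row.n), row.n / cohort.n)
        for row in counts.itertuples()
    ]


def assess_recurrence(
    dim: DimensionTable, features: list[Feature], cohort: CohortTable
) -> CovariateMatrix:
    """Expand features into once/sporadic/frequent indicator covariates.

    ``dim`` must already be restricted to the pre-exposure window; every
    feature must be present in it (a missing feature signals a pipeline
    inconsistency and raises).
    """
    pids = cohort.patient_ids.values
    count_table = (
        dim.records.groupby(["code", "patient_id"]).size()
        if len(dim.records)
        else pd.Series(dtype=int)
    )
    columns: dict[str, np.ndarray] = {}
    dict_rows: list[dict] = []
    merge_map: dict[str, str] = {}

    for feat in features:
        if len(dim.records) == 0 or feat.code not in dim.records["code"].values:
            raise ValidationError(
                f"feature {feat.code!r} has no records in dimension {dim.name!r}"
            )
        per_patient = count_table.loc[feat.code]
        n_i = per_patient.reindex(pids).fillna(0).to_numpy()
        positives = per_patient.to_numpy()
        thresholds = {
            "once": 1,
            "sporadic": nearest_rank(positives, 50),
            "frequent": nearest_rank(positives, 75),
        }
        kept: dict[bytes, str] = {}
        for cutoff in CUTOFFS:
            thr = thresholds[cutoff]
            vec = (n_i >= thr).astype(np.int8)
            name = covariate_name(feat.dimension_name, feat.code, cutoff)
            key = vec.tobytes()
            if key in kept:  # identical column within this feature: collapse
                merge_map[name] = kept[key]
                continue
            kept[key] = name
            columns[name] = vec
            dict_rows.append(
                {
                    "name": name,
                    "dimension": feat.dimension_name,
                    "code": feat.code,
                    "cutoff": cutoff,
                    "threshold": thr,
                    "prevalence": float(vec.mean()),
                }
            )

    values = pd.DataFrame(columns, index=pd.Index(pids, name="patient_id"))
    return CovariateMatrix(values, pd.DataFrame(dict_rows), merge_map)


def build_covariate_matrix(
    dimensions: list[DimensionTable],
    cohort: CohortTable,
    lookback_days: int = 365,
    n_top: int = 200,
) -> CovariateMatrix:
    """Run steps one to three over several dimensions and concatenate."""
    parts: list[CovariateMatrix] = []
    for dim in dimensions:
        pre = restrict_pre_exposure(dim, cohort, lookback_days)
        feats = prevalence_filter(pre, cohort, n_top)
        if feats:
            parts.append(assess_recurrence(pre, feats, cohort))
    if not parts:
        empty = pd.DataFrame(index=pd.Index(cohort.patient_ids.values, name="patient_id"))
        return CovariateMatrix(empty, pd.DataFrame(
            columns=["name", "dimension", "code", "cutoff", "threshold", "prevalence"]
        ))
    values = pd.concat([p.values for p in parts], axis=1)
    dictionary = pd.concat([p.dictionary for p in parts], ignore_index=True)
    merge_map: dict[str, str] = {}
    for p in parts:
        merge_map.update(p.merge_map)
    return CovariateMatrix(values, dictionary, merge_map)


def write_covariate_matrix(cov: CovariateMatrix, values_path, dictionary_path) -> None:
    cov.values.to_csv(values_path)
    cov.dictionary.to_csv(dictionary_path, index=False)
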