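"""Cohort, data-dimension and code-hierarchy tables and their CSV readers.

The data model shared by every downstream stage:

* a *cohort table* — one row per patient with index date, binary exposure,
  binary event indicator, positive follow-up time and any investigator
  pre-defined covariates;
* one or more *data dimensions* — long-format streams of coded events
  (patient id, code, date), each capturing one aspect of care such as
  clinical diagnoses, referrals or prescriptions;
* an optional *code hierarchy* mapping codes to chapter-level labels
  (e.g. ICD-10 chapters, BNF chapters) for concept summaries.

All files are delimited text with a header row; dates are ISO-8601 calendar
dates (time of day is ignored — the pre-exposure windows are day-granular).
Follow-up time units are the caller's responsibility and are never converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Default label returned by :meth:`CodeHierarchy.lookup` for unknown codes.
UNMAPPED = "unmapped"

_COHORT_REQUIRED = ["patient_id", "index_date", "exposure", "event", "followup_time"]


class ValidationError(ValueError):
    """A table violates the HDPS data model."""


@dataclass
class CohortTable:
    """Patient-level study cohort.

    Parameters
    ----------
    data
        One row per patient with at least the columns ``patient_id``
        (unique), ``index_date`` (datetime), ``exposure`` (0/1), ``event``
        (0/1) and ``followup_time`` (> 0). Any further columns are treated
        as pre-defined covariates unless ``predefined`` narrows them down.
    predefined
        Names of the investigator pre-defined covariate columns.
    """

    data: pd.DataFrame
    predefined: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing required column(s): {missing}")
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate patient_id: {sorted(set(dup))[:5]}")
        for col in ("exposure", "event"):
            bad = df.loc[~df[col].isin([0, 1]), col]
            if len(bad):
                raise ValidationError(
                    f"column {col!r} must be binary 0/1; offending value(s) "
                    f"{sorted(set(bad))[:5]} at row(s) {list(bad.index[:5])}"
                )
        if (df["followup_time"] <= 0).any():
            rows = df.index[df["followup_time"] <= 0][:5]
            raise ValidationError(f"followup_time must be > 0 (row(s) {list(rows)})")
        if df["exposure"].nunique() < 2:
            raise ValidationError("both exposure groups must be non-empty")
        unknown = [c for c in self.predefined if c not in df.columns]
        if unknown:
            raise ValidationError(f"pre-defined covariate(s) not in table: {unknown}")
        self.data = df.reset_index(drop=True)
        self.data["index_date"] = pd.to_datetime(self.data["index_date"]).astype(
            "datetime64[ns]"
        )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> pd.Series:
        return self.data["patient_id"]

    @property
    def exposure(self) -> pd.Series:
        return self.data["exposure"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]


@dataclass
class DimensionTable:
    """Long-format coded events for one declared data dimension."""

    name: str
    records: pd.DataFrame  # columns: patient_id, code, date

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("patient_id", "code", "date") if c not in df.columns]
        if missing:
            raise ValidationError(
                f"dimension {self.name!r} missing column(s): {missing}"
            )
        if len(df) and (df["code"].astype(str).str.len() == 0).any():
            raise ValidationError(f"dimension {self.name!r} contains empty codes")
        df = df.reset_index(drop=True)
        df["date"] = pd.to_datetime(df["date"]).astype("datetime64[ns]")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CodeHierarchy:
    """Total code → chapter-label map; unknown codes map to ``unmapped``."""

    mapping: dict[str, str]
    unmapped_label: str = UNMAPPED

    def lookup(self, code: str) -> str:
        return self.mapping.get(code, self.unmapped_label)


def read_cohort(
    path, predefined: list[str] | None = None, sep: str = ","
) -> CohortTable:
    """Read a cohort table from delimited text.

    Columns beyond the required five are taken as pre-defined covariates
    when ``predefined`` is not given.
    """
    df = pd.read_csv(path, sep=sep)
    if predefined is None:
        predefined = [c for c in df.columns if c not in _COHORT_REQUIRED]
    return CohortTable(df, predefined=list(predefined))


def read_dimension(path, name: str, cohort: CohortTable, sep: str = ",") -> DimensionTable:
    """Read one data dimension, restricted to patients present in ``cohort``.

    Records for unknown patients (orphans) are dropped and their count
    logged; an unparseable date raises with the offending line number.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("patient_id", "code", "date") if c not in df.columns]
    if missing:
        raise ValidationError(f"dimension file {path} missing column(s): {missing}")
    parsed = pd.to_datetime(df["date"], errors="coerce")
    if parsed.isna().any() and len(df):
        bad = parsed.index[parsed.isna()][0]
        # +2: header line plus 1-based numbering
        raise ValidationError(
            f"unparseable date {df['date'].iloc[bad]!r} at line {bad + 2} of {path}"
        )
    df["date"] = parsed
    known = df["patient_id"].isin(set(cohort.patient_ids))
    n_orphans = int((~known).sum())
    if n_orphans:
        logger.info(
            "dimension %r: dropped %d orphan record(s) for patients outside the cohort",
            name,
            n_orphans,
        )
    return DimensionTable(name, df.loc[known])


def read_code_hierarchy(path, sep: str = ",") -> CodeHierarchy:
    """Read a two-column code → chapter file; conflicting duplicates error."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"hierarchy file {path} needs two columns (code, chapter)")
    code_col, chap_col = df.columns[:2]
    conflicts = (
        df.groupby(code_col)[chap_col].nunique().loc[lambda s: s > 1].index.tolist()
    )
    if conflicts:
        raise ValidationError(
            f"conflicting chapter assignments for code(s): {conflicts[:5]}"
        )
    return CodeHierarchy(dict(zip(df[code_col], df[chap_col])))


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    df = cohort.data.copy()
    df["index_date"] = df["index_date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep=sep, index=False)


def write_dimension(dim: DimensionTable, path, sep: str = ",") -> None:
    df = dim.records.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep=sep, index=False)


def write_code_hierarchy(hierarchy: CodeHierarchy, path, sep: str = ",") -> None:
    pd.DataFrame(
        {"code": list(hierarchy.mapping), "chapter": list(hierarchy.mapping.values())}
    ).to_csv(path, sep=sep, index=False)
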