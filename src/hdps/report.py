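"""Seven-item structured report of an HDPS analysis.

The report covers, in order: (1) the data dimensions declared and the
aspects of care they characterise; (2) the feature-generation parameters
(code granularity, prevalence-filter size per dimension); (3) the recurrence
assessment (cut-offs used, whether proximity to exposure start was
considered); (4) the covariate prioritisation method; (5) the number of
covariates selected and its justification; (6) the software used; (7) the
diagnostics and sensitivity analyses run and their key outputs. Every item
is always rendered; anything the run did not supply appears as
"not reported" rather than being silently omitted.

The document is a pure function of its inputs: regenerating it from the
same artefacts yields an identical document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

import hdps
from hdps.pipeline import HDPSRun
from hdps.sensitivity import SensitivityResult, sensitivity_table

NOT_REPORTED = "not reported"

ITEM_TITLES = {
    1: "Data dimensions",
    2: "Feature-generation parameters",
    3: "Feature recurrence assessment",
    4: "Covariate prioritisation method",
    5: "Number of covariates selected",
    6: "Software",
    7: "Diagnostics and sensitivity analyses",
}


@dataclass
class ReportDocument:
    """Structured seven-item report, renderable as markdown or key-values."""

    items: dict[int, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i in ITEM_TITLES:
            self.items.setdefault(i, {})

    def to_markdown(self) -> str:
        lines = ["# HDPS analysis report", ""]
        for i, title in ITEM_TITLES.items():
            lines.append(f"## Item {i}: {title}")
            entries = self.items.get(i) or {}
            if not entries:
                lines.append(NOT_REPORTED)
            for key, value in entries.items():
                lines.append(f"- **{key}**: {value if value else NOT_REPORTED}")
            lines.append("")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            f"item{i}_{key.replace(' ', '_')}": value
            for i, entries in self.items.items()
            for key, value in entries.items()
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def build_report(
    run: HDPSRun,
    sensitivity: list[SensitivityResult] | None = None,
    diagnostics_files: dict[str, str] | None = None,
    dimension_descriptions: dict[str, str] | None = None,
    k_justification: str | None = None,
    software: str | None = None,
) -> ReportDocument:
    """Populate the seven report items from a completed pipeline run."""
    cfg = run.config
    doc = ReportDocument()

    dims = {}
    for dim in run.dimensions:
        desc = (dimension_descriptions or {}).get(dim.name, NOT_REPORTED)
        dims[dim.name] = f"{desc} ({len(dim)} records)"
    doc.items[1] = dims or {"dimensions": NOT_REPORTED}

    n_features = (
        run.covariates.dictionary["code"].nunique() if len(run.covariates.dictionary) else 0
    )
    doc.items[2] = {
        "feature type": "coded events, one feature per distinct code",
        "prevalence filter": f"top {cfg.n_top} most common codes per dimension",
        "pre-exposure window": f"{cfg.lookback_days} days before index (index date excluded)",
        "features passing filter": str(n_features),
    }

    doc.items[3] = {
        "recurrence cut-offs": (
            ">= once, >= median count, >= 75th-percentile count "
            "(nearest-rank, among patients with >= 1 record)"
        ),
        "collapsed duplicate columns": str(len(run.covariates.merge_map)),
        "proximity to exposure start": "not considered",
    }

    doc.items[4] = {
        "ranking method": (
            "Bross bias multiplier (|log bias|)"
            if cfg.ranking == "bross"
            else "exposure-association only (|log RR_CE|)"
        ),
        "outcome association measure": cfg.outcome_measure,
    }

    doc.items[5] = {
        "HDPS covariates selected": str(len(run.selected)),
        "pre-defined covariates": ", ".join(run.cohort.predefined) or NOT_REPORTED,
        "justification": k_justification or NOT_REPORTED,
    }

    doc.items[6] = {"software": software or f"hdps {hdps.__version__} (Python)"}

    item7 = {}
    if diagnostics_files:
        item7["diagnostics"] = "; ".join(
            f"{name}: {path}" for name, path in diagnostics_files.items()
        )
    else:
        item7["diagnostics"] = NOT_REPORTED
    if sensitivity:
        table = sensitivity_table(sensitivity)
        parts = []
        for row in table.itertuples():
            if pd.notna(row.hazard_ratio):
                parts.append(
                    f"{row.label}: HR {row.hazard_ratio:.2f} "
                    f"({row.ci_lower:.2f}-{row.ci_upper:.2f}), CLR {row.clr:.2f}"
                )
            else:
                parts.append(f"{row.label}: failed ({row.error})")
        item7["sensitivity analyses"] = "; ".join(parts)
    else:
        item7["sensitivity analyses"] = NOT_REPORTED
    est = run.estimates.get("hdps")
    if est is not None:
        item7["primary estimate"] = (
            f"HR {est.hazard_ratio:.2f} ({est.ci_lower:.2f}-{est.ci_upper:.2f}), "
            f"CLR {est.clr:.2f}, {est.n_events} events"
        )
    doc.items[7] = item7
    return doc
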