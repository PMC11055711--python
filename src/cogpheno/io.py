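"""CSV/JSON/YAML data contracts.

Canonical interchange is long-format scores (subject_id, timepoint,
subscore, value) plus per-subject demographics and MRI tables; see
:mod:`cogpheno.cohort` for the column contracts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import DEMO_COLUMNS, SCORE_COLUMNS, Cohort, ParticipantRecord
from .config import CohortConfig, ConfigError, PipelineConfig, validate_registry_names
from .normative import NormativeModel, norms_from_json, norms_to_json


class CohortValidationError(ConfigError):
    """One or more rows failed validation; message lists every failure."""


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "demographics": out / "demographics.csv",
        "scores": out / "scores.csv",
        "mri": out / "mri.csv",
    }
    cohort.demographics.to_csv(paths["demographics"], index=False)
    cohort.scores.to_csv(paths["scores"], index=False)
    cohort.mri.to_csv(paths["mri"], index=False)
    return paths


def read_cohort(
    demographics: str | Path,
    scores: str | Path,
    mri: str | Path | None = None,
) -> Cohort:
    """Read and validate the three cohort CSVs.

    Row-level failures (education outside 1-7, malformed EDSS, unknown
    sub-score names, duplicate rows) are collected and reported together.
    """
    demo = pd.read_csv(demographics)
    sc = pd.read_csv(scores)
    mri_df = pd.read_csv(mri) if mri is not None else pd.DataFrame(columns=["subject_id"])

    missing = [c for c in DEMO_COLUMNS if c not in demo.columns]
    if missing:
        raise CohortValidationError(f"demographics CSV lacks column(s) {missing}")
    missing = [c for c in SCORE_COLUMNS if c not in sc.columns]
    if missing:
        raise CohortValidationError(f"scores CSV lacks column(s) {missing}")
    validate_registry_names(sc["subscore"].unique())

    errors: list[str] = []
    for i, row in demo.iterrows():
        try:
            ParticipantRecord(
                subject_id=str(row["subject_id"]),
                group_truth=row["group_truth"] if pd.notna(row["group_truth"]) else None,
                age=float(row["age"]),
                sex=row["sex"],
                education=int(row["education"]),
                edss=float(row["edss"]) if pd.notna(row["edss"]) else None,
                disease_duration=(
                    float(row["disease_duration"]) if pd.notna(row["disease_duration"]) else None
                ),
                ms_type=row["ms_type"],
                retained=bool(row["retained"]),
                followup_years=(
                    float(row["followup_years"]) if pd.notna(row["followup_years"]) else None
                ),
            )
        except Exception as exc:  # pydantic ValidationError or coercion failure
            errors.append(f"demographics row {i} (subject {row.get('subject_id')}): {exc}")
    if errors:
        raise CohortValidationError(
            f"{len(errors)} invalid row(s):\n" + "\n".join(errors[:20])
        )
    return Cohort(demographics=demo, scores=sc, mri=mri_df)


def write_norms(norms: dict[str, NormativeModel], path: str | Path) -> None:
    Path(path).write_text(norms_to_json(norms))


def read_norms(path: str | Path) -> dict[str, NormativeModel]:
    return norms_from_json(Path(path).read_text())


def read_cohort_config(path: str | Path) -> CohortConfig:
    return CohortConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def read_pipeline_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
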