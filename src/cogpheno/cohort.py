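"""In-memory cohort container and per-participant record validation.

A :class:`Cohort` bundles three pandas DataFrames:

* ``demographics`` — one row per subject: age, sex, education (1-7),
  EDSS, disease type and duration, group label, follow-up metadata;
* ``scores`` — long format, one row per (subject, timepoint, sub-score);
* ``mri`` — one row per subject of precomputed MRI scalars (volumes in L
  or mL, lesion volume in mL, cortical lesion count, skeleton FA).

Missing values are absent rows (scores) or NaN (MRI); a missing value
never silently becomes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .config import ConfigError, validate_registry_names

SCORE_COLUMNS = ["subject_id", "timepoint", "subscore", "value"]
DEMO_COLUMNS = [
    "subject_id", "group_truth", "age", "sex", "education", "edss",
    "disease_duration", "ms_type", "retained", "followup_years",
]


class ParticipantRecord(BaseModel):
    """Validated single-subject record (the row-level data contract)."""

    model_config = ConfigDict(extra="forbid")

    subject_id: str
    group_truth: str | None = None
    age: float
    sex: Literal["male", "female"]
    education: int
    edss: float | None = None
    disease_duration: float | None = None
    ms_type: Literal["RR", "SP", "PP", "none"] = "none"
    retained: bool = True
    followup_years: float | None = None
    #: (subscore, timepoint) -> raw value
    raw_scores: dict[tuple[str, int], float] = {}
    mri: dict[str, float] = {}

    @field_validator("education")
    @classmethod
    def _education(cls, v: int) -> int:
        if not 1 <= v <= 7:
            raise ValueError(f"education must be on the 1-7 scale, got {v}")
        return v

    @field_validator("edss")
    @classmethod
    def _edss(cls, v: float | None) -> float | None:
        if v is None:
            return v
        if not (0.0 <= v <= 10.0) or round(v * 2) != v * 2:
            raise ValueError(f"EDSS must be 0-10 in 0.5 steps, got {v}")
        return v

    @field_validator("age")
    @classmethod
    def _age(cls, v: float) -> float:
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"age must be a positive finite number, got {v}")
        return v

    @field_validator("raw_scores")
    @classmethod
    def _raw(cls, v: dict) -> dict:
        bad = [k for k, x in v.items() if not np.isfinite(x)]
        if bad:
            raise ValueError(f"non-finite raw score(s) at {bad}")
        validate_registry_names({name for name, _tp in v})
        return v


@dataclass
class Cohort:
    """Demographics + long-format scores + MRI scalars for many subjects."""

    demographics: pd.DataFrame
    scores: pd.DataFrame
    mri: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in DEMO_COLUMNS if c not in self.demographics.columns]
        if missing:
            raise ConfigError(f"demographics table lacks column(s) {missing}")
        missing = [c for c in SCORE_COLUMNS if c not in self.scores.columns]
        if missing:
            raise ConfigError(f"scores table lacks column(s) {missing}")
        dup = self.scores.duplicated(subset=["subject_id", "timepoint", "subscore"])
        if dup.any():
            rows = self.scores.loc[dup, ["subject_id", "timepoint", "subscore"]]
            raise ConfigError(
                f"duplicate subject/timepoint/subscore rows: {rows.head().to_dict('records')}"
            )
        if self.demographics["subject_id"].duplicated().any():
            raise ConfigError("duplicate subject_id in demographics")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.demographics["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.demographics)

    def subset(self, subject_ids) -> "Cohort":
        ids = set(subject_ids)
        mri = self.mri
        if len(mri):
            mri = mri[mri["subject_id"].isin(ids)].reset_index(drop=True)
        return Cohort(
            demographics=self.demographics[
                self.demographics["subject_id"].isin(ids)
            ].reset_index(drop=True),
            scores=self.scores[self.scores["subject_id"].isin(ids)].reset_index(drop=True),
            mri=mri,
        )

    @property
    def controls(self) -> "Cohort":
        ids = self.demographics.loc[self.demographics["ms_type"] == "none", "subject_id"]
        return self.subset(ids)

    @property
    def patients(self) -> "Cohort":
        ids = self.demographics.loc[self.demographics["ms_type"] != "none", "subject_id"]
        return self.subset(ids)

    def scores_wide(self, timepoint: int | None = None) -> pd.DataFrame:
        """Pivot the long score table to subjects x sub-scores."""
        t = self.scores
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
            return t.pivot(index="subject_id", columns="subscore", values="value")
        return t.pivot(index=["subject_id", "timepoint"], columns="subscore", values="value")

    def to_records(self) -> list[ParticipantRecord]:
        mri_by_id: dict[str, dict[str, float]] = {}
        if len(self.mri):
            for _, row in self.mri.iterrows():
                vals = {
                    k: float(v)
                    for k, v in row.items()
                    if k != "subject_id" and pd.notna(v)
                }
                mri_by_id[row["subject_id"]] = vals
        scores_by_id: dict[str, dict[tuple[str, int], float]] = {}
        for _, row in self.scores.iterrows():
            scores_by_id.setdefault(row["subject_id"], {})[
                (row["subscore"], int(row["timepoint"]))
            ] = float(row["value"])
        out = []
        for _, row in self.demographics.iterrows():
            out.append(
                ParticipantRecord(
                    subject_id=row["subject_id"],
                    group_truth=row["group_truth"] if pd.notna(row["group_truth"]) else None,
                    age=float(row["age"]),
                    sex=row["sex"],
                    education=int(row["education"]),
                    edss=float(row["edss"]) if pd.notna(row["edss"]) else None,
                    disease_duration=(
                        float(row["disease_duration"])
                        if pd.notna(row["disease_duration"])
                        else None
                    ),
                    ms_type=row["ms_type"],
                    retained=bool(row["retained"]),
                    followup_years=(
                        float(row["followup_years"])
                        if pd.notna(row["followup_years"])
                        else None
                    ),
                    raw_scores=scores_by_id.get(row["subject_id"], {}),
                    mri=mri_by_id.get(row["subject_id"], {}),
                )
            )
        return out
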