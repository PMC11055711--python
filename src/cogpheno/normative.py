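"""Regression-based normative scoring of raw neuropsychological scores.

Norms are ordinary least-squares models of each raw sub-score on age, sex
(male = 1) and education (numeric 1-7), fitted on healthy controls.  A
subject's normative Z is the standardised residual, oriented so that
higher always means better:

    z_raw = (observed - predicted) / residual_sd
    z     = z_raw                      (count scores, more correct = better)
    z     = -z_raw                     (timed scores, slower = worse)

Derived composites follow the battery's standard definitions: Stroop
interference is card 3 minus the mean of cards 1 and 2; the MCT slope is
the 4-letter minus the 1-letter trial time; WLG total sums the three
fluency trials; the SRT average pools its four sub-scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .registry import load_registry

logger = logging.getLogger(__name__)

MIN_CONTROLS = 20


class FittingError(RuntimeError):
    """Normative model could not be fitted for a sub-score."""


class ScoringError(RuntimeError):
    """Z-scoring failed (uncovered sub-score or unusable demographics)."""


@dataclass(frozen=True)
class NormativeModel:
    """Per-sub-score control regression with residual spread and direction."""

    test_subscore: str
    intercept: float
    b_age: float
    b_sex: float
    b_edu: float
    residual_sd: float
    direction: str
    n_fit: int
    timepoint: int = 1

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise FittingError(
                f"{self.test_subscore}: residual_sd must be > 0, got {self.residual_sd}"
            )
        if self.n_fit < MIN_CONTROLS:
            raise FittingError(
                f"{self.test_subscore}: n_fit = {self.n_fit} < {MIN_CONTROLS}"
            )

    @property
    def sign(self) -> int:
        return 1 if self.direction == "higher_is_better" else -1

    def predict(self, age, sex_male, education):
        return (
            self.intercept
            + self.b_age * np.asarray(age, dtype=float)
            + self.b_sex * np.asarray(sex_male, dtype=float)
            + self.b_edu * np.asarray(education, dtype=float)
        )


def _design(demo: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(index=demo["subject_id"])
    x["age"] = demo["age"].to_numpy(dtype=float)
    x["sex_male"] = (demo["sex"] == "male").to_numpy(dtype=float)
    x["education"] = demo["education"].to_numpy(dtype=float)
    return x


def fit_norms(
    controls: Cohort,
    timepoint: int = 1,
    subscores: list[str] | None = None,
) -> dict[str, NormativeModel]:
    """Fit OLS norms on controls for every scored sub-score.

    Raises :class:`FittingError` (naming the sub-score) when fewer than 20
    controls carry the score, when it is absent altogether, or when the
    residual variance is zero.
    """
    reg = load_registry()
    wanted = subscores if subscores is not None else reg.scored
    demo = controls.demographics
    design = _design(demo)
    wide = controls.scores_wide(timepoint=timepoint)
    norms: dict[str, NormativeModel] = {}
    for name in wanted:
        if name not in wide.columns:
            raise FittingError(
                f"sub-score {name!r} absent from all controls at timepoint {timepoint}"
            )
        y = wide[name].reindex(design.index)
        mask = y.notna() & design.notna().all(axis=1)
        n = int(mask.sum())
        if n < MIN_CONTROLS:
            raise FittingError(
                f"sub-score {name!r}: only {n} usable controls (< {MIN_CONTROLS})"
            )
        X = sm.add_constant(design.loc[mask], has_constant="add")
        fit = sm.OLS(y.loc[mask], X).fit()
        resid_sd = float(np.sqrt(fit.scale))  # ssr / (n - 4)
        tiny = 1e-10 * max(1.0, float(np.abs(y.loc[mask]).mean()))
        if not resid_sd > tiny or not np.isfinite(resid_sd):
            raise FittingError(f"sub-score {name!r}: zero residual variance")
        norms[name] = NormativeModel(
            test_subscore=name,
            intercept=float(fit.params["const"]),
            b_age=float(fit.params["age"]),
            b_sex=float(fit.params["sex_male"]),
            b_edu=float(fit.params["education"]),
            residual_sd=resid_sd,
            direction=reg.subscores[name].direction,
            n_fit=n,
            timepoint=timepoint,
        )
    return norms


def score(
    records: Cohort,
    norms: dict[str, NormativeModel],
    timepoints: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Convert raw scores to oriented normative Z-scores.

    Returns a long table (subject_id, timepoint, subscore, z).  Sub-scores
    present in the data but not covered by ``norms`` raise; subjects with
    unusable demographics are excluded with a logged warning.
    """
    reg = load_registry()
    scored = set(reg.scored) & set(records.scores["subscore"].unique())
    uncovered = sorted(scored - set(norms))
    if uncovered:
        raise ScoringError(f"no normative model for sub-score(s) {uncovered}")

    demo = records.demographics
    usable = demo[["age", "sex", "education"]].notna().all(axis=1)
    if not usable.all():
        bad = list(demo.loc[~usable, "subject_id"])
        logger.warning("excluding %d subject(s) with missing demographics: %s", len(bad), bad)
    demo = demo.loc[usable]
    design = _design(demo)

    t = records.scores
    t = t[t["subscore"].isin(scored) & t["subject_id"].isin(design.index)]
    if timepoints is not None:
        t = t[t["timepoint"].isin(timepoints)]
    out = t[["subject_id", "timepoint", "subscore"]].copy()
    z = np.empty(len(t))
    obs = t["value"].to_numpy(dtype=float)
    d = design.loc[t["subject_id"]]
    for name, model in norms.items():
        m = (t["subscore"] == name).to_numpy()
        if not m.any():
            continue
        pred = model.predict(
            d["age"].to_numpy()[m], d["sex_male"].to_numpy()[m], d["education"].to_numpy()[m]
        )
        z[m] = model.sign * (obs[m] - pred) / model.residual_sd
    out["z"] = z
    return out.reset_index(drop=True)


def _derive_wide(wide: pd.DataFrame) -> pd.DataFrame:
    """Compute derived composites on a wide raw-score table (NaN-propagating)."""
    reg = load_registry()
    out = wide.copy()
    for name, spec in reg.derived.items():
        args = spec["args"]
        cols = [out[a] if a in out.columns else pd.Series(np.nan, index=out.index) for a in args]
        block = pd.concat(cols, axis=1)
        ok = block.notna().all(axis=1)
        if spec["op"] == "interference":
            val = block.iloc[:, 0] - block.iloc[:, 1:].mean(axis=1)
        elif spec["op"] == "difference":
            val = block.iloc[:, 0] - block.iloc[:, 1]
        elif spec["op"] == "sum":
            val = block.sum(axis=1)
        elif spec["op"] == "mean":
            val = block.mean(axis=1)
        else:  # pragma: no cover - registry is package data
            raise ValueError(f"unknown derived op {spec['op']!r}")
        out[name] = val.where(ok)  # any missing constituent -> missing
    return out


def derive_composites(records: Cohort) -> Cohort:
    """Return a cohort whose score table includes the derived composites.

    A derived score with any missing constituent stays missing; existing
    derived rows are recomputed.
    """
    reg = load_registry()
    scores = records.scores
    base = scores[~scores["subscore"].isin(reg.derived)]
    wide = base.pivot(index=["subject_id", "timepoint"], columns="subscore", values="value")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        derived = _derive_wide(wide)[list(reg.derived)]
    long = (
        derived.reset_index()
        .melt(id_vars=["subject_id", "timepoint"], var_name="subscore", value_name="value")
        .dropna(subset=["value"])
    )
    merged = pd.concat([base, long], ignore_index=True)
    merged = merged.sort_values(["subject_id", "timepoint", "subscore"]).reset_index(drop=True)
    return Cohort(demographics=records.demographics, scores=merged, mri=records.mri)


def norms_to_json(norms: dict[str, NormativeModel]) -> str:
    return json.dumps({k: asdict(v) for k, v in norms.items()}, indent=2, sort_keys=True)


def norms_from_json(text: str) -> dict[str, NormativeModel]:
    raw = json.loads(text)
    return {k: NormativeModel(**v) for k, v in raw.items()}
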