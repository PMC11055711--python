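"""End-to-end pipeline: simulate/ingest -> norms -> Z-scores -> phenotypes
-> reliable change -> transitions -> MRI models.

Cross-sectional classification at both timepoints uses the timepoint-1
norms (practice is handled by the RCI numerator); the RCI stage scores
follow-up data against norms fitted on healthy-control timepoint-2 data.
MRI univariate screens run across all patients; forward models are fitted
within the isolated group of each domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import Cohort
from .config import PipelineConfig
from .io import write_cohort, write_json, write_norms
from .longitudinal import TransitionTable, build_transition_table, classify_trajectories, compute_rci
from .mri import (
    LogisticReport,
    ModelError,
    RegressionReport,
    collinearity_screen,
    decline_logistic,
    forward_regression,
    normality_gate,
    screen_candidates,
)
from .normative import score
from .phenotyping import classify_profiles, compose_domains, phenotype_frequencies
from .registry import DOMAINS
from .synthetic import SimulationResult, simulate_cohort

logger = logging.getLogger(__name__)

MRI_CANDIDATES = [
    "cortical_gmv",
    "wm_volume",
    "lesion_volume",
    "thalamus_volume",
    "hippocampus_volume",
    "cortical_lesion_count",
    "fa",
]

LOGISTIC_FEATURES = [
    "age",
    "sex_male",
    "edss",
    "cortical_gmv",
    "thalamus_volume",
    "hippocampus_volume",
    "lesion_volume",
    "fa",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage
        self.__cause__ = exc


@dataclass
class PipelineResult:
    config: PipelineConfig
    simulation: SimulationResult
    baseline_labels: pd.DataFrame
    followup_labels: pd.DataFrame
    frequencies: dict
    rci: pd.DataFrame
    trajectories: pd.DataFrame
    transition: TransitionTable
    transforms: list
    predictor_set: object
    mri_reports: dict[str, RegressionReport]
    decline_report: LogisticReport | None
    warnings: list[str] = field(default_factory=list)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def _domain_wide(z_long: pd.DataFrame, threshold: float, timepoint: int) -> pd.DataFrame:
    prof = compose_domains(z_long, threshold=threshold)
    prof = prof[prof["timepoint"] == timepoint]
    return prof.set_index("subject_id")[list(DOMAINS)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    notes: list[str] = []

    sim = _stage("simulate")(simulate_cohort)(config.cohort)
    patients, controls = sim.patients, sim.controls

    z_pat = _stage("score")(score)(patients, sim.norms_t1)
    profiles = _stage("phenotype")(compose_domains)(
        z_pat, threshold=config.impairment_threshold
    )
    bl = classify_profiles(profiles[profiles["timepoint"] == 1])
    fu = classify_profiles(profiles[profiles["timepoint"] == 2])
    freqs = _stage("phenotype")(phenotype_frequencies)(bl)

    # RCI on domain scores: baseline vs follow-up against control change norms
    z_pat_fu = _stage("rci")(score)(patients, sim.norms_t2, timepoints=(2,))
    z_hc_bl = _stage("rci")(score)(controls, sim.norms_t1, timepoints=(1,))
    z_hc_fu = _stage("rci")(score)(controls, sim.norms_t2, timepoints=(2,))
    thr = config.impairment_threshold
    rci = _stage("rci")(compute_rci)(
        _domain_wide(z_pat, thr, 1),
        _domain_wide(z_pat_fu, thr, 2),
        _domain_wide(z_hc_bl, thr, 1),
        _domain_wide(z_hc_fu, thr, 2),
        level="domain",
        threshold=config.rci_threshold,
        sed_estimator=config.sed_estimator,
    )

    cols = ["subject_id", "phenotype", "n_impaired"]
    traj = _stage("transitions")(classify_trajectories)(
        bl[cols],
        fu[cols],
        rci=rci,
        rci_gated=config.rci_gated,
        rci_threshold=config.rci_threshold,
        multidomain_declines=config.multidomain_declines,
    )
    transition = _stage("transitions")(build_transition_table)(traj)

    # --- MRI models ------------------------------------------------------
    mri = patients.mri.set_index("subject_id")
    demo = patients.demographics.set_index("subject_id")
    covars = pd.DataFrame(
        {
            "age": demo["age"],
            "sex_male": (demo["sex"] == "male").astype(float),
            "education": demo["education"].astype(float),
        }
    )
    transforms = []
    predictors = pd.DataFrame(index=mri.index)
    for meas in MRI_CANDIDATES:
        try:
            decision, vals = normality_gate(mri[meas], name=meas)
        except ModelError as exc:
            notes.append(str(exc))
            continue
        transforms.append(decision)
        predictors[meas] = vals
    pset = _stage("mri-model")(collinearity_screen)(
        predictors, transform_log=tuple(t.measure for t in transforms if t.transform)
    )

    bl_idx = bl.set_index("subject_id")
    mri_reports: dict[str, RegressionReport] = {}
    for dom in DOMAINS:
        outcome_all = bl_idx[dom]
        cand = predictors.loc[predictors.index.intersection(outcome_all.index),
                              list(pset.survivors)]
        try:
            screen = screen_candidates(
                outcome_all.loc[cand.index],
                cand,
                covars.loc[cand.index],
                alpha=config.screen_alpha,
                multiplicity=config.multiplicity,
            )
            kept = [s.name for s in screen if s.kept]
            subset = bl_idx.index[bl_idx["phenotype"] == f"isolated_{dom}"]
            subset = subset.intersection(predictors.index)
            if not kept:
                report = RegressionReport(
                    outcome=dom, selected=[], std_betas={}, pvalues={}, f_stat=None,
                    df_model=0, df_resid=max(len(subset) - 1, 0), r2=0.0, adj_r2=0.0,
                    n=len(subset), model_pvalue=None, significant=False,
                )
            else:
                report = forward_regression(
                    bl_idx.loc[subset, dom],
                    predictors.loc[subset, kept],
                    entry_alpha=config.entry_alpha,
                    outcome_name=dom,
                )
            report.screen = screen
            mri_reports[dom] = report
        except ModelError as exc:
            notes.append(f"mri-model[{dom}]: {exc}")

    # --- decline vs stable logistic --------------------------------------
    decline_report: LogisticReport | None = None
    iso_traj = traj[
        traj["baseline_phenotype"].str.startswith("isolated")
        & traj["change"].isin(["declining", "stable"])
    ].set_index("subject_id")
    if len(iso_traj):
        feats = pd.concat([covars[["age", "sex_male"]], demo[["edss"]], predictors], axis=1)
        feats = feats.loc[feats.index.intersection(iso_traj.index),
                          [f for f in LOGISTIC_FEATURES if f in feats.columns]]
        labels = (iso_traj.loc[feats.index, "change"] == "declining").astype(float)
        try:
            decline_report = decline_logistic(feats, labels)
        except ModelError as exc:
            notes.append(f"decline-logistic: {exc}")

    result = PipelineResult(
        config=config,
        simulation=sim,
        baseline_labels=bl,
        followup_labels=fu,
        frequencies=freqs,
        rci=rci,
        trajectories=traj,
        transition=transition,
        transforms=transforms,
        predictor_set=pset,
        mri_reports=mri_reports,
        decline_report=decline_report,
        warnings=notes,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    h = cfg.config_hash()
    (out / "resolved_config.yaml").write_text(cfg.resolved_yaml())
    write_cohort(result.simulation.cohort, out / "cohort")
    write_norms(result.simulation.norms_t1, out / "norms_t1.json")
    write_norms(result.simulation.norms_t2, out / "norms_t2.json")
    result.baseline_labels.to_csv(out / "phenotypes_baseline.csv", index=False)
    result.followup_labels.to_csv(out / "phenotypes_followup.csv", index=False)
    write_json({"config_hash": h, **result.frequencies}, out / "frequency_report.json")
    result.rci.to_csv(out / "rci.csv", index=False)
    result.trajectories.to_csv(out / "trajectories.csv", index=False)
    result.transition.to_frame().to_csv(out / "transition_table.csv")
    write_json({"config_hash": h, **result.transition.to_dict()}, out / "transition_table.json")
    write_json(
        {
            "config_hash": h,
            "transforms": [vars(t) for t in result.transforms],
            "collinearity": {
                "survivors": list(result.predictor_set.survivors),
                "dropped": [vars(d) for d in result.predictor_set.dropped],
            },
            "models": {d: r.to_dict() for d, r in result.mri_reports.items()},
            "decline_logistic": (
                result.decline_report.to_dict() if result.decline_report else None
            ),
        },
        out / "mri_models.json",
    )
    manifest = {
        "config_hash": h,
        "seed": cfg.seed,
        "warnings": result.warnings,
        "files": sorted(p.name for p in out.iterdir()),
    }
    write_json(manifest, out / "run_manifest.json")
    logger.info("pipeline outputs written to %s (config %s)", out, h)
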