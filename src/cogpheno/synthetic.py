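"""Synthetic MS cohort generator.

Emulates the statistical structure the phenotyping analysis assumes: a
healthy-control normative sample whose raw scores are linear in age, sex
and education; an MS cohort whose members belong to latent phenotype
groups (preserved, four isolated-impairment groups, multi-domain) with
prescribed mean domain deficits in normative-SD units; two timepoints
with practice effects and configurable test-retest correlation; and
correlated per-subject MRI scalars whose group means follow published
MS-cohort summaries.

Patient deficits are expressed directly in the normative metric: a target
Z vector is drawn per subject and converted to raw scores through the
*fitted* control norms, so a group's mean pipeline-computed domain Z
equals its configured ``domain_effects`` entry by construction.  The
within-domain sub-score deviations are mean-centred per domain, hence the
domain average equals the unit-variance latent domain score exactly and
the null impairment rate at the -1.5 cut is the normal tail
``Phi(-1.5) = 6.68%``.

All randomness flows from ``config.seed`` through per-stage
``numpy.random.Generator`` instances; identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults
from .cohort import DEMO_COLUMNS, Cohort
from .config import CohortConfig, ConfigError
from .normative import NormativeModel, derive_composites, fit_norms
from .registry import load_registry

# latent correlation shares for control raw-score noise:
# general ability / domain-specific / test-unique
_CONTROL_SHARES = (0.30, 0.30, 0.40)

# cluster assignment of trial-level raw inputs for the control
# correlation structure (scored sub-scores use their registry domain)
_RAW_CLUSTER = {
    "stroop_card3": "efwm",
    "wlg_animals": "efwm",
    "wlg_professions": "efwm",
    "wlg_m_words": "efwm",
    "mct_1letter": "efwm",
    "mct_4letter": "efwm",
}

_WLG_TRIALS = ("wlg_animals", "wlg_professions", "wlg_m_words")


def _control_cluster(name: str) -> str:
    reg = load_registry()
    if name in reg.subscores and reg.subscores[name].domain is not None:
        return reg.subscores[name].domain
    return _RAW_CLUSTER.get(name, "efwm")


def _truth_predict(model, age, male, edu):
    base, _sd, b_age, b_sex, b_edu = model
    return base + b_age * (age - 46.0) + b_sex * male + b_edu * (edu - 5.0)


def _education(rng, centre, n):
    return np.clip(np.rint(rng.normal(centre - 0.3, 1.2, n)), 1, 7).astype(int)


def _mri_correlation(config: CohortConfig) -> np.ndarray:
    measures = list(defaults.MRI_MEASURES)
    k = len(measures)
    R = np.eye(k)
    for key, r in config.mri_corr.items():
        a, b = key.split("|")
        if a not in measures or b not in measures:
            raise ConfigError(f"mri_corr key {key!r} names an unknown measure")
        i, j = measures.index(a), measures.index(b)
        R[i, j] = R[j, i] = r
    return R


def _mri_noise(rng, R: np.ndarray, n: int) -> np.ndarray:
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        L = V @ np.diag(np.sqrt(np.clip(w, 1e-10, None)))
    return rng.standard_normal((n, R.shape[0])) @ L.T


def _mri_frame(
    rng,
    config: CohortConfig,
    subject_ids,
    params_by_subject: list[dict],
    domain_dev: dict[str, np.ndarray],
    lesion_measures: bool,
) -> pd.DataFrame:
    n = len(subject_ids)
    measures = list(defaults.MRI_MEASURES)
    noise = _mri_noise(rng, _mri_correlation(config), n)
    m = pd.DataFrame(noise, columns=measures)
    for meas, slopes in config.mri_cog_slopes.items():
        for dom, s in slopes.items():
            if dom in domain_dev:
                m[meas] = m[meas] + s * domain_dev[dom]
    out = pd.DataFrame({"subject_id": subject_ids})
    for meas in measures:
        vals = np.full(n, np.nan)
        for i, p in enumerate(params_by_subject):
            if meas == "lesion_volume":
                if lesion_measures and p.get("log_lesion") is not None:
                    mu, sd = p["log_lesion"]
                    vals[i] = np.exp(mu + sd * m[meas].iloc[i])
            elif meas == "cortical_lesion_count":
                if lesion_measures and p.get("cl_median") is not None:
                    med = p["cl_median"]
                    vals[i] = max(
                        round(float(np.exp(np.log(med + 1) + 0.9 * m[meas].iloc[i]))) - 1, 0
                    )
            else:
                mu, sd = p[meas]
                vals[i] = mu + sd * m[meas].iloc[i]
        out[meas] = vals
    if lesion_measures and config.cortical_lesion_available < 1.0:
        miss = rng.random(n) >= config.cortical_lesion_available
        out.loc[miss, "cortical_lesion_count"] = np.nan
    return out


def generate_controls(config: CohortConfig) -> Cohort:
    """Healthy-control sample with both timepoints and correlated raw scores."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_controls
    hc = defaults.DEMOGRAPHICS["hc"]
    ids = [f"HC{i:04d}" for i in range(n)]
    age = np.clip(rng.normal(*hc["age"], n), 20, 80)
    male = (rng.random(n) < hc["male"]).astype(float)
    edu = _education(rng, hc["edu"], n)
    sex = np.where(male > 0, "male", "female")

    retest = config.retest_by_test()
    tests = list(config.test_models)
    clusters = sorted({_control_cluster(t) for t in tests})
    a, b, c = _CONTROL_SHARES

    def latent(n_sub):
        g = rng.standard_normal(n_sub)
        h = {cl: rng.standard_normal(n_sub) for cl in clusters}
        return {
            t: np.sqrt(a) * g
            + np.sqrt(b) * h[_control_cluster(t)]
            + np.sqrt(c) * rng.standard_normal(n_sub)
            for t in tests
        }

    eps1, fresh = latent(n), latent(n)
    rows = []
    for t in tests:
        model = config.test_models[t]
        sd = model[1]
        pred = _truth_predict(model, age, male, edu)
        r = retest[t]
        eps2 = r * eps1[t] + np.sqrt(1 - r * r) * fresh[t]
        raw1 = pred + sd * eps1[t]
        raw2 = pred + config.practice_effect.get(t, 0.0) + sd * eps2
        rows.append(pd.DataFrame({"subject_id": ids, "timepoint": 1, "subscore": t, "value": raw1}))
        rows.append(pd.DataFrame({"subject_id": ids, "timepoint": 2, "subscore": t, "value": raw2}))
    scores = pd.concat(rows, ignore_index=True)

    demo = pd.DataFrame(
        {
            "subject_id": ids,
            "group_truth": "hc",
            "age": age,
            "sex": sex,
            "education": edu,
            "edss": np.nan,
            "disease_duration": np.nan,
            "ms_type": "none",
            "retained": True,
            "followup_years": np.clip(rng.normal(*config.followup_years, n), 1.0, None),
        }
    )[DEMO_COLUMNS]

    # controls couple MRI to the general-ability component only
    dev = {d: np.zeros(n) for d in load_registry().domains}
    params = [defaults.MRI_PARAMS["hc"]] * n
    mri = _mri_frame(rng, config, ids, params, dev, lesion_measures=False)
    scores = scores.sort_values(["subject_id", "timepoint", "subscore"]).reset_index(drop=True)
    return Cohort(demographics=demo, scores=scores, mri=mri)


def generate_patients(config: CohortConfig, norms: dict[str, NormativeModel]) -> Cohort:
    """MS patients with group-structured deficits injected via fitted norms.

    ``norms`` must be timepoint-1 norms fitted on a compatible control
    sample (normally the one from :func:`generate_controls`); the injected
    ``domain_effects`` are expressed in those normative-SD units.
    """
    reg = load_registry()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_patients
    groups = list(config.group_mix)
    probs = np.array([config.group_mix[g] for g in groups])
    group = rng.choice(groups, size=n, p=probs / probs.sum())
    ids = [f"MS{i:04d}" for i in range(n)]

    age = np.empty(n)
    male = np.empty(n)
    edu = np.empty(n, dtype=int)
    edss = np.empty(n)
    dd = np.empty(n)
    ms_type = np.empty(n, dtype=object)
    for g in groups:
        m = group == g
        k = int(m.sum())
        if k == 0:
            continue
        d = defaults.DEMOGRAPHICS[g]
        age[m] = np.clip(rng.normal(*d["age"], k), 18, 85)
        male[m] = (rng.random(k) < d["male"]).astype(float)
        edu[m] = _education(rng, d["edu"], k)
        edss[m] = np.clip(np.rint(rng.normal(d["edss"], 1.5, k) * 2) / 2, 0.0, 10.0)
        dd[m] = np.clip(rng.normal(*d["dd"], k), 1.0, None)
        tp = np.array(d["ms_type"], dtype=float)
        ms_type[m] = rng.choice(["RR", "SP", "PP"], size=k, p=tp / tp.sum())
    sex = np.where(male > 0, "male", "female")

    eff1 = config.domain_effects
    eff2 = config.followup_effects()
    delta1 = {d: np.array([eff1[g].get(d, 0.0) for g in group]) for d in reg.domains}
    delta2 = {d: np.array([eff2[g].get(d, 0.0) for g in group]) for d in reg.domains}

    c = config.cross_domain_r
    sw = config.within_domain_sd
    retest = config.retest_by_test()

    def domain_latent():
        """Unit-variance latent domain scores with cross-domain correlation c."""
        g0 = rng.standard_normal(n)
        return {
            d: np.sqrt(c) * g0 + np.sqrt(1 - c) * rng.standard_normal(n)
            for d in reg.domains
        }

    def within_noise(members):
        """Per-sub-score deviations, mean-centred within domain."""
        e = sw * rng.standard_normal((n, len(members)))
        e -= e.mean(axis=1, keepdims=True)
        return {s: e[:, j] for j, s in enumerate(members)}

    dom_members = {d: reg.domain_members(d) for d in reg.domains}
    D1 = domain_latent()
    Df = domain_latent()
    z1: dict[str, np.ndarray] = {}
    z2: dict[str, np.ndarray] = {}
    for d in reg.domains:
        members = dom_members[d]
        w1 = within_noise(members)
        wf = within_noise(members)
        for s in members:
            z1[s] = delta1[d] + D1[d] + w1[s]
            r = retest[s] if s in retest else defaults.TEST_RETEST_R
            nu = Df[d] + wf[s]
            z2[s] = delta2[d] + r * (z1[s] - delta1[d]) + np.sqrt(1 - r * r) * nu

    # practice effects on derived scores follow from their constituents
    p = config.practice_effect
    derived_practice = {
        "stroop_interference": p.get("stroop_card3", 0.0)
        - 0.5 * (p.get("stroop_card1", 0.0) + p.get("stroop_card2", 0.0)),
        "mct_slope": p.get("mct_4letter", 0.0) - p.get("mct_1letter", 0.0),
        "wlg_total": sum(p.get(t, 0.0) for t in _WLG_TRIALS),
    }

    def raw_from_z(name: str, z: dict[str, np.ndarray], practice: bool) -> np.ndarray:
        nm = norms[name]
        pred = nm.predict(age, male, edu)
        shift = derived_practice.get(name, p.get(name, 0.0)) if practice else 0.0
        return pred + shift + nm.sign * z[name] * nm.residual_sd

    scored_direct = [
        s
        for d in reg.domains
        for s in dom_members[d]
        if s not in reg.derived
    ]
    missing = sorted(set(scored_direct + list(reg.derived)) - set(norms) - {"srt_average"})
    if missing:
        raise ConfigError(f"norms lack required sub-score model(s): {missing}")

    raw1: dict[str, np.ndarray] = {}
    raw2: dict[str, np.ndarray] = {}
    for s in scored_direct:
        raw1[s] = raw_from_z(s, z1, practice=False)
        raw2[s] = raw_from_z(s, z2, practice=True)

    # back out trial-level constituents of the derived scores
    int1 = raw_from_z("stroop_interference", z1, practice=False)
    int2 = raw_from_z("stroop_interference", z2, practice=True)
    raw1["stroop_card3"] = int1 + 0.5 * (raw1["stroop_card1"] + raw1["stroop_card2"])
    raw2["stroop_card3"] = int2 + 0.5 * (raw2["stroop_card1"] + raw2["stroop_card2"])

    mct_model = config.test_models["mct_1letter"]
    r_mct = retest["mct_1letter"]
    e1 = rng.standard_normal(n)
    e2 = r_mct * e1 + np.sqrt(1 - r_mct**2) * rng.standard_normal(n)
    base1 = _truth_predict(mct_model, age, male, edu)
    raw1["mct_1letter"] = base1 + mct_model[1] * e1
    raw2["mct_1letter"] = base1 + p.get("mct_1letter", 0.0) + mct_model[1] * e2
    slope1 = raw_from_z("mct_slope", z1, practice=False)
    slope2 = raw_from_z("mct_slope", z2, practice=True)
    raw1["mct_4letter"] = slope1 + raw1["mct_1letter"]
    raw2["mct_4letter"] = slope2 + raw2["mct_1letter"]

    tot1 = raw_from_z("wlg_total", z1, practice=False)
    tot2 = raw_from_z("wlg_total", z2, practice=True)
    for tot, raw in ((tot1, raw1), (tot2, raw2)):
        e = 2.0 * rng.standard_normal((n, 3))
        e -= e.mean(axis=1, keepdims=True)
        for j, t in enumerate(_WLG_TRIALS):
            raw[t] = tot / 3.0 + e[:, j]

    retained = rng.random(n) < config.retention
    rows = []
    for name, vals in raw1.items():
        rows.append(
            pd.DataFrame({"subject_id": ids, "timepoint": 1, "subscore": name, "value": vals})
        )
    kept = [i for i in range(n) if retained[i]]
    kept_ids = [ids[i] for i in kept]
    for name, vals in raw2.items():
        rows.append(
            pd.DataFrame(
                {"subject_id": kept_ids, "timepoint": 2, "subscore": name, "value": vals[kept]}
            )
        )
    scores = pd.concat(rows, ignore_index=True)
    scores = scores.sort_values(["subject_id", "timepoint", "subscore"]).reset_index(drop=True)

    demo = pd.DataFrame(
        {
            "subject_id": ids,
            "group_truth": group,
            "age": age,
            "sex": sex,
            "education": edu,
            "edss": edss,
            "disease_duration": dd,
            "ms_type": ms_type,
            "retained": retained,
            "followup_years": np.where(
                retained, np.clip(rng.normal(*config.followup_years, n), 1.0, None), np.nan
            ),
        }
    )[DEMO_COLUMNS]

    dev = {d: D1[d] for d in reg.domains}
    params = [defaults.MRI_PARAMS[g] for g in group]
    mri = _mri_frame(rng, config, ids, params, dev, lesion_measures=True)
    return Cohort(demographics=demo, scores=scores, mri=mri)


@dataclass
class SimulationResult:
    cohort: Cohort
    controls: Cohort
    patients: Cohort
    norms_t1: dict[str, NormativeModel]
    norms_t2: dict[str, NormativeModel]


def simulate_cohort(config: CohortConfig) -> SimulationResult:
    """Controls -> composites -> norms -> patients, merged into one cohort."""
    controls = derive_composites(generate_controls(config))
    norms_t1 = fit_norms(controls, timepoint=1)
    norms_t2 = fit_norms(controls, timepoint=2)
    patients = derive_composites(generate_patients(config, norms_t1))
    merged = Cohort(
        demographics=pd.concat(
            [controls.demographics, patients.demographics], ignore_index=True
        ),
        scores=pd.concat([controls.scores, patients.scores], ignore_index=True),
        mri=pd.concat([controls.mri, patients.mri], ignore_index=True),
    )
    return SimulationResult(
        cohort=merged,
        controls=controls,
        patients=patients,
        norms_t1=norms_t1,
        norms_t2=norms_t2,
    )
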