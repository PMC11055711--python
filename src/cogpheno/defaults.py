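"""Default generating parameters for the synthetic MS cohort.

Group-level demographic and MRI summaries follow published values for a
long-standing MS cohort (348 patients, 96 healthy controls) phenotyped
into isolated-IPS / isolated-memory / isolated-EF-WM / isolated-attention /
multi-domain / preserved groups.  Raw neuropsychological score scales are
chosen to match typical extended-BRB-N control performance; only the
Z-level behaviour is contractual, and every scale is config-overridable.
"""

from __future__ import annotations

GROUPS = (
    "isolated_ips",
    "isolated_memory",
    "isolated_efwm",
    "isolated_attention",
    "multidomain",
    "preserved",
)

#: Baseline phenotype mix among patients (cohort of 348:
#: 25 / 23 / 37 / 23 isolated, 148 multidomain, 92 preserved).
GROUP_MIX = {
    "isolated_ips": 25 / 348,
    "isolated_memory": 23 / 348,
    "isolated_efwm": 37 / 348,
    "isolated_attention": 23 / 348,
    "multidomain": 148 / 348,
    "preserved": 92 / 348,
}

# age mean/sd, disease-duration mean/sd, male fraction, education centre
# (1-7 scale), EDSS centre, MS-type proportions RR/SP/PP.
DEMOGRAPHICS = {
    "isolated_ips": dict(age=(46.63, 9.95), dd=(11.40, 6.35), male=0.160,
                         edu=5, edss=3.0, ms_type=(16, 5, 2)),
    "isolated_memory": dict(age=(49.74, 9.46), dd=(11.72, 8.02), male=0.565,
                            edu=6, edss=3.0, ms_type=(11, 4, 4)),
    "isolated_efwm": dict(age=(45.96, 12.79), dd=(10.32, 6.70), male=0.351,
                          edu=4, edss=3.0, ms_type=(27, 6, 3)),
    "isolated_attention": dict(age=(48.78, 8.33), dd=(13.30, 6.66), male=0.130,
                               edu=4, edss=3.5, ms_type=(16, 4, 3)),
    "multidomain": dict(age=(47.23, 10.33), dd=(10.43, 7.30), male=0.365,
                        edu=5, edss=3.5, ms_type=(102, 27, 15)),
    "preserved": dict(age=(47.23, 10.34), dd=(10.43, 5.92), male=0.293,
                      edu=6, edss=3.0, ms_type=(72, 6, 9)),
    "hc": dict(age=(45.87, 10.45), dd=None, male=0.417,
               edu=6, edss=None, ms_type=None),
}

MRI_MEASURES = (
    "cortical_gmv",
    "wm_volume",
    "lesion_volume",
    "thalamus_volume",
    "hippocampus_volume",
    "cortical_lesion_count",
    "fa",
)

# mean/sd per group: cortical GMV (L), WM volume (L), lesion volume
# (log-mL scale: the generator exponentiates, so the stored raw measure is
# right-skewed and the normality gate re-discovers the log transform),
# thalamus (mL), hippocampus (mL), cortical lesion count (median of a
# rounded log-normal), whole-skeleton FA.
MRI_PARAMS = {
    "isolated_ips": dict(cortical_gmv=(0.75, 0.06), wm_volume=(0.67, 0.03),
                         log_lesion=(4.06, 0.40), thalamus_volume=(17.89, 2.02),
                         hippocampus_volume=(8.86, 1.53), cl_median=16,
                         fa=(0.39, 0.03)),
    "isolated_memory": dict(cortical_gmv=(0.74, 0.04), wm_volume=(0.68, 0.04),
                            log_lesion=(4.00, 0.48), thalamus_volume=(18.61, 2.18),
                            hippocampus_volume=(9.22, 1.31), cl_median=10,
                            fa=(0.39, 0.03)),
    "isolated_efwm": dict(cortical_gmv=(0.76, 0.04), wm_volume=(0.67, 0.03),
                          log_lesion=(3.79, 0.39), thalamus_volume=(19.05, 1.69),
                          hippocampus_volume=(9.60, 1.21), cl_median=7,
                          fa=(0.40, 0.02)),
    "isolated_attention": dict(cortical_gmv=(0.77, 0.05), wm_volume=(0.67, 0.04),
                               log_lesion=(3.96, 0.36), thalamus_volume=(18.30, 1.96),
                               hippocampus_volume=(9.45, 1.36), cl_median=11,
                               fa=(0.39, 0.02)),
    "multidomain": dict(cortical_gmv=(0.73, 0.06), wm_volume=(0.66, 0.04),
                        log_lesion=(4.08, 0.41), thalamus_volume=(17.41, 2.75),
                        hippocampus_volume=(8.76, 1.46), cl_median=14,
                        fa=(0.39, 0.03)),
    "preserved": dict(cortical_gmv=(0.76, 0.05), wm_volume=(0.68, 0.03),
                      log_lesion=(3.90, 0.34), thalamus_volume=(19.19, 1.68),
                      hippocampus_volume=(9.69, 1.15), cl_median=6,
                      fa=(0.40, 0.02)),
    "hc": dict(cortical_gmv=(0.78, 0.05), wm_volume=(0.70, 0.03),
               log_lesion=None, thalamus_volume=(20.64, 1.33),
               hippocampus_volume=(10.28, 0.97), cl_median=None,
               fa=(0.42, 0.02)),
}

# Control-sample linear models generating raw scores:
# value = base + b_age*(age-46) + b_sex*male + b_edu*(edu-5) + sd*noise.
# Counts (correct responses) fall with age and rise with education; timed
# scores (seconds) do the opposite.
TEST_MODELS = {
    # name: (base, residual sd, b_age, b_sex(male), b_edu)
    "sdmt": (55.0, 9.0, -0.30, -1.0, 1.5),
    "srt_lts": (50.0, 9.0, -0.25, -2.0, 1.2),
    "srt_ltr": (45.0, 10.0, -0.30, -2.0, 1.2),
    "srt_cltr": (40.0, 11.0, -0.35, -2.5, 1.3),
    "srt_delayed": (9.0, 2.0, -0.05, -0.4, 0.25),
    "spart_direct": (7.0, 1.5, -0.04, 0.2, 0.15),
    "spart_delayed": (7.5, 1.8, -0.05, 0.2, 0.15),
    "wlg_animals": (22.0, 4.0, -0.08, -0.5, 0.8),
    "wlg_professions": (18.0, 4.0, -0.08, -0.5, 0.8),
    "wlg_m_words": (16.0, 4.0, -0.08, -0.5, 0.8),
    "stroop_card1": (45.0, 7.0, 0.15, 0.5, -0.8),
    "stroop_card2": (58.0, 9.0, 0.20, 0.5, -1.0),
    "stroop_card3": (95.0, 16.0, 0.45, 1.5, -2.0),
    "cst_numbers": (30.0, 6.0, 0.15, 0.3, -0.6),
    "cst_letters": (32.0, 7.0, 0.15, 0.3, -0.6),
    "cst_shifting": (45.0, 12.0, 0.30, 0.8, -1.2),
    "mct_1letter": (9.0, 1.5, 0.03, 0.1, -0.10),
    "mct_4letter": (16.0, 3.5, 0.08, 0.3, -0.30),
}

# Mean healthy-control raw-score change timepoint 1 -> 2 (practice):
# counts improve slightly, times shorten slightly.
PRACTICE_EFFECT = {
    "sdmt": 2.0, "srt_lts": 1.0, "srt_ltr": 1.0, "srt_cltr": 1.0,
    "srt_delayed": 0.3, "spart_direct": 0.3, "spart_delayed": 0.3,
    "wlg_animals": 0.5, "wlg_professions": 0.5, "wlg_m_words": 0.5,
    "stroop_card1": -1.5, "stroop_card2": -1.5, "stroop_card3": -3.0,
    "cst_numbers": -1.0, "cst_letters": -1.0, "cst_shifting": -3.0,
    "mct_1letter": -0.2, "mct_4letter": -0.5,
}

#: Five-year test-retest correlation, uniform across tests by default.
TEST_RETEST_R = 0.80

# Per-group mean domain shift in normative SD units.  The affected domain
# of each isolated group sits well below the -1.5 cut; unaffected domains
# carry the mild subclinical deficit seen across MS cohorts.
DOMAIN_EFFECTS = {
    "preserved": dict(ips=-0.3, memory=-0.3, efwm=-0.3, attention=-0.3),
    "isolated_ips": dict(ips=-2.3, memory=-0.5, efwm=-0.5, attention=-0.5),
    "isolated_memory": dict(ips=-0.5, memory=-2.3, efwm=-0.5, attention=-0.5),
    "isolated_efwm": dict(ips=-0.5, memory=-0.5, efwm=-2.3, attention=-0.5),
    "isolated_attention": dict(ips=-0.5, memory=-0.5, efwm=-0.5, attention=-2.3),
    "multidomain": dict(ips=-2.0, memory=-1.8, efwm=-1.8, attention=-1.3),
}

#: Additional mean worsening (SD units, applied to every domain) between
#: baseline and five-year follow-up; emulates gradual progression.
FOLLOWUP_DRIFT = -0.2

#: Fraction of patients retained at cognitive follow-up (240/348).
RETENTION = 0.71

#: Follow-up interval, years: mean and SD.
FOLLOWUP_YEARS = (4.9, 0.9)

#: Fraction of patients with cortical lesion counts available (208/348).
CORTICAL_LESION_AVAILABLE = 0.60

# Standardised coupling of MRI measures to a subject's latent domain
# deviation (measure -> domain -> slope); grey-matter structures and FA
# track processing speed and memory, lesion measures run opposite.
MRI_COG_SLOPES = {
    "cortical_gmv": dict(ips=0.30, memory=0.25),
    "wm_volume": dict(ips=0.25),
    "thalamus_volume": dict(ips=0.35, memory=0.25),
    "hippocampus_volume": dict(memory=0.35),
    "fa": dict(ips=0.30, efwm=0.15),
    "lesion_volume": dict(ips=-0.25, memory=-0.20),
    "cortical_lesion_count": dict(ips=-0.20),
}

# Cross-measure correlation of the MRI noise (before cognitive coupling):
# volumes and FA positively related, lesion burden negatively.
MRI_CORR = {
    ("cortical_gmv", "wm_volume"): 0.45,
    ("cortical_gmv", "thalamus_volume"): 0.45,
    ("cortical_gmv", "hippocampus_volume"): 0.40,
    ("cortical_gmv", "fa"): 0.35,
    ("wm_volume", "thalamus_volume"): 0.40,
    ("wm_volume", "hippocampus_volume"): 0.35,
    ("wm_volume", "fa"): 0.40,
    ("thalamus_volume", "hippocampus_volume"): 0.45,
    ("thalamus_volume", "fa"): 0.35,
    ("hippocampus_volume", "fa"): 0.30,
    ("lesion_volume", "cortical_lesion_count"): 0.45,
    ("lesion_volume", "cortical_gmv"): -0.30,
    ("lesion_volume", "wm_volume"): -0.30,
    ("lesion_volume", "thalamus_volume"): -0.35,
    ("lesion_volume", "fa"): -0.35,
    ("cortical_lesion_count", "cortical_gmv"): -0.25,
    ("cortical_lesion_count", "fa"): -0.25,
}
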