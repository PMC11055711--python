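# Methods

## Scientific problem

Roughly half of people with multiple sclerosis (PwMS) develop cognitive
impairment, but an averaged "cognition score" hides which functions are
affected and disguises single-domain deficits behind preserved ones.
`cogpheno` implements a domain-resolved phenotyping pipeline for an
extended Brief Repeatable Battery of Neuropsychological tests (BRB-N):
demographically corrected Z-scores, four a-priori cognitive domains,
classification into *preserved* / *isolated* / *multi-domain* impairment
phenotypes, reliable-change-based five-year trajectories, and regression
models relating domain scores to structural-MRI scalars.

## Normative model

For every sub-score the normative model is an ordinary least-squares
regression of the raw control score on age (years), sex (male = 1) and
education (numeric, Dutch 1–7 scale):

    raw ~ b0 + b_age·age + b_sex·male + b_edu·education

with residual SD computed with denominator n − 4.  A subject's Z is the
standardised residual, orientation-corrected so that higher always means
better (timed scores — Stroop cards and interference, CST conditions,
MCT slope — are sign-flipped).  Main effects only, no interactions or
polynomial terms: published norms for this battery are not available, so
the package uses the simplest defensible regression-based form, and the
sub-score registry (`data/subscores.yaml`) keeps direction and domain
membership editable without code changes.  Education enters as a numeric
covariate rather than a 7-level factor because the upper levels dominate
and small cells would make factor estimates unstable.

## Domains and phenotypes

| domain | constituents |
|---|---|
| IPS | SDMT (alone) |
| memory | SRT LTS, SRT LTR, SRT CLTR, SRT delayed; SPART direct, SPART delayed |
| EF/WM | Stroop interference, CST shifting, WLG total, MCT slope |
| attention | Stroop cards 1–2, CST numbers, CST letters |

A domain score is the unweighted mean of its constituents' Z-scores.  A
domain with Z **strictly below −1.5** is impaired; Z = −1.5 exactly is
preserved (the two inequalities are applied literally).  Phenotypes:
0 impaired domains → preserved; exactly 1 → isolated (labelled by the
domain); ≥ 2 → multi-domain.  When some constituents are missing the
domain is averaged over the present ones provided at least half are
present, otherwise the domain — and the subject-timepoint — is flagged
unclassifiable; this avoids discarding a subject for one missing trial
while refusing to score a domain from a minority of its tests.  The
EF/WM facets (inhibition = Stroop interference, flexibility = CST
shifting, fluency = WLG, working memory = MCT slope) are reported as an
informational sub-profile.

## Reliable change and trajectories

    RCI = [(x2 − x1) − (mean(HC2) − mean(HC1))] / SEd

with |RCI| ≥ 1.64 (inclusive) flagging reliable change.  "Standard error
of the difference score" is ambiguous between two common estimators, so
both are implemented: the default Jacobson–Truax practice-corrected form
`SEd = sqrt(SEM1² + SEM2²)`, `SEM_i = SD_i·sqrt(1 − r12)`, and
`sd_of_differences` (the SD of the control change scores).  For
`SD1 = SD2 = σ` the default reduces to `σ·sqrt(2(1 − r))`.

Trajectory labels are count-based: *declining* when more domains are
impaired at follow-up than at baseline, *stable* when the count is equal
(including a switch of the single impaired domain), *improving* when the
subject moves multi-domain → isolated or isolated → preserved.  Because
the study design computes RCIs yet defines decline by impaired-domain
counts, the count rule is the default and a `rci_gated` flag additionally
requires a reliable domain-level RCI in the matching direction before a
decline/improve label is granted.  A multi-domain subject impaired in
fewer (but still ≥ 2) domains at follow-up stays *stable* under the count
rule (logged); `multidomain_declines=True` instead reproduces the
published cross-tabulation accounting in which every multi-domain →
multi-domain subject counts as declining.  Displayed row percentages use
half-up rounding to whole percent; exact values are retained.

Cross-sectional classification at both timepoints uses timepoint-1 norms
— practice effects are removed by the RCI numerator, not by re-norming
follow-up scores — while the RCI stage scores follow-up data against
norms fitted on control timepoint-2 data.

## MRI models

1. **Normality gate** — Lilliefors-corrected Kolmogorov–Smirnov per
   measure; p < 0.05 triggers a natural-log transform (values ≤ 0 are
   shifted to just above zero with a logged warning; the trigger
   statistic is recorded).
2. **Collinearity screen** — while any pair of candidates has |r| ≥ 0.7,
   drop the candidate with the most such partners; ties break on larger
   mean |r|, then name.  The drop order and evidence are recorded.
3. **Univariate preselection** — OLS of the domain Z on each candidate
   plus age, sex and education, across all patients; Bonferroni
   correction within the domain's candidate family by default
   (`multiplicity="none"` available since the analysis family of the
   blanket correction is ambiguous).
4. **Forward regression** — within the isolated group of the domain,
   standard forward selection on the F-change p-value with entry
   threshold 0.05 (configurable).  Reported: standardised β
   (coefficient·SD(x)/SD(y)), per-term p, model F with df, R² and
   adjusted R²; an empty model is reported as non-significant.
   Complete-case (listwise) deletion throughout; cortical lesion counts
   are retained as a candidate and fitted on the subjects that have them,
   with the case count reported.
5. **Decline logistic** — declining vs stable among isolated-baseline
   subjects, maximum-likelihood logistic regression on age, sex, EDSS and
   the MRI scalars, reported with the likelihood-ratio Χ², df, p and
   odds ratios; complete separation is reported as such rather than as a
   convergence failure.
6. **Group comparisons** — per measure, a general linear model when the
   pooled within-group residuals pass the normality gate, otherwise
   Kruskal–Wallis with pairwise Mann–Whitney follow-ups; Bonferroni
   across measures.

Standardised βs are invariant to affine rescaling of any predictor or the
outcome; adjusted R² always equals `1 − (1 − R²)(n − 1)/(n − k − 1)`.

## Synthetic cohort

No per-subject data from the motivating cohort are distributable, so the
generator emulates its statistical structure and is itself a first-class,
tested module.

* **Controls** (default n = 96): raw scores linear in age/sex/education
  with the slopes and residual SDs in `defaults.TEST_MODELS` (scales
  follow typical control BRB-N performance, e.g. SDMT 55 ± 9); latent
  noise shares 0.3 general / 0.3 domain-cluster / 0.4 unique give
  realistic between-test correlation.  Two timepoints with per-test
  practice effects and test–retest correlation (default 0.80).
* **Patients** (default n = 348, group mix 25/23/37/23 isolated,
  148 multi-domain, 92 preserved out of 348): each subject draws latent
  unit-variance domain scores `D_d = δ_gd + sqrt(c)·g + sqrt(1−c)·h_d`
  (cross-domain correlation c = 0.45) and sub-score targets
  `z_s = D_d + w_s` with within-domain deviations `w_s` (SD 0.6)
  **mean-centred per domain**, so the pipeline's domain average equals
  `D_d` exactly.  Targets are converted to raw scores through the fitted
  control norms, which makes the configured `domain_effects` hold exactly
  in normative-SD units: a group's mean pipeline domain Z equals its
  configured shift, and with zero effects the per-domain impairment rate
  is the normal tail Φ(−1.5) = 6.68%.  Default shifts put each isolated
  group's own domain at −2.3 SD, other domains at the mild subclinical
  −0.5, multi-domain at −2.0/−1.8/−1.8/−1.3, preserved at −0.3.
* **Follow-up**: 71% retained; follow-up interval 4.9 ± 0.9 years; a
  uniform −0.2 SD drift across domains emulates gradual progression
  (overridable per group via `domain_effects_followup`).
* **MRI**: per-group means/SDs follow published group summaries for this
  battery's cohort (e.g. cortical GMV 0.73–0.78 L, FA 0.39–0.42); lesion
  volume is generated log-normally so the normality gate re-discovers the
  log transform; cortical lesion counts are rounded log-normals missing
  for 40% of patients and absent in controls; a configurable correlation
  matrix (volumes and FA positive, lesion burden negative) plus
  standardised couplings to the subject's latent domain deviation give
  the collinearity screen and the regressions realistic structure.

What the generator does **not** emulate: floor/ceiling effects and
discreteness of real test scales, non-linear age effects, differential
(informative) attrition, scanner or site effects, and measurement error
in the MRI scalars.  Passing tests therefore validate the *procedures*
(scoring, classification, accounting, selection) and their calibration
under a faithful statistical model — not the clinical parameter values a
real cohort would produce.  Because injected deficits are expressed
through the fitted norms, the patient path does not test norm estimation
itself; the control self-scoring tests (mean ≈ 0, SD ≈ 1) and the slope
recovery tests cover that.

## Numerical choices and problem sizes

* Impairment boundary strict (<), reliable-change boundary inclusive (≥).
* Forward-selection ties on F-change p resolve to the first-evaluated
  candidate (column order); at entry threshold 1.0 selection returns the
  full model, at 0 the empty model.
* Constant score vectors, fewer than 20 usable controls, zero SEd, rank
  deficiency and single-class logistic outcomes raise typed errors; a
  missing constituent propagates as missing, never as zero.
* Calibration tests and the acceptance script use 2000-patient null
  cohorts, 1000 simulees for the reliable-change rate, n = 500 for
  standardised-effect recovery, and 200 replicate seeds for the
  empty-model and type-I-error rates — sizes at which binomial Monte
  Carlo error is a few tenths of a percentage point, small against the
  asserted tolerances.
* All randomness flows from one integer seed through
  `numpy.random.Generator` instances keyed per stage; identical configs
  give byte-identical cohorts.

## Known limitations

* The normative regressions are a reconstruction; no claim is made that
  they match the unpublished norms of any specific centre.
* Published group-level tables are reproduced only where their printed
  numbers are arithmetically consistent; the per-domain involvement
  counts among multi-domain patients (369 affected-domain slots) conflict
  with the printed 2/3/4-domain distribution (362 slots), so only the
  processing-speed involvement is pinned in the packaged count tables.
* Regression coefficients estimated on ~25-subject isolated groups are
  reported with their case counts and should be read as the procedure's
  output, not as stable population estimates.
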