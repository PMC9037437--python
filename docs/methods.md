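# Methods

This note documents the models, parameter defaults, numerical choices
and known limits of `baripath`. Nothing here states an empirical result
the test suite or `scripts/acceptance.py` does not itself compute.

## Severity stratification

**Model.** All patient-by-timepoint rows (baseline, 1 y, 5 y) enter one
feature matrix of seven variables: HbA1C (%), fasting blood glucose
(mmol/L), T2D duration (years), age (years), sex (F=0/M=1), number of
glucose-lowering drugs (ordinal count), insulin use (0/1). Age and T2D
duration carry the patient's **baseline** value in every row; otherwise
the mere passage of time would push every patient toward "Severe".
Columns are standardized over the stacked rows (sample sd), the
correlation matrix is eigen-decomposed, and components with eigenvalue
≥ 1 are retained (Kaiser–Guttman). Ward linkage (Ward.D2 criterion) on
the retained scores is cut at k = 2, followed by a deterministic
centroid-consolidation pass (k-means initialized from the Ward cut,
lowest-index tie-break). The consolidation guarantees the documented
invariant that projecting a training row reproduces its assignment
exactly; because its initialization is deterministic, so is the result.
The cluster with the higher mean standardized HbA1C is named *Severe*.

**Choices.**
* Standardization over stacked rows rather than per time point keeps one
  common severity space across the follow-up; a per-timepoint variant
  would erase the shared post-surgery improvement signal and is easy to
  add by standardizing before calling `fit_severity_model`.
* Drug count enters as a numeric ordinal (0, 1, 2, …), not one-hot: PCA
  needs a scalar and the clinical presentation bins at "≥ 2".
* Sex stays in the model by default (dropping it is a one-line change:
  pass a feature matrix without the column).
* Zero-variance columns are dropped from the PCA with a warning — a
  constant column cannot inform the clustering; if HbA1C itself is
  constant the fit refuses ("unlabelable") since the Severe label is
  anchored on it.
* Projection standardizes new rows with the stored means/sds, multiplies
  by the stored loadings and assigns the nearer centroid (Euclidean in
  retained-component space). Fit and projection must therefore see the
  same scale; the pipeline fits on unstandardized features so stored
  constants are raw-scale.
* Median imputation uses `np.median` (midpoint for even counts), mode
  for categoricals.
* Standardized odds ratios: univariate logistic models of cluster
  membership on z-scored continuous variables; binary 0/1 variables
  enter unstandardized so the OR is the familiar cross-product ratio.
  Perfect separation (|coefficient| > 10 on the standardized scale or
  non-convergence within 100 iterations) is reported as a sentinel with
  a flag rather than a number.
* Covariate-adjusted comparisons: OLS with an F-test of the group term
  for continuous variables, logistic likelihood-ratio tests for binary
  ones, both adjusted for age and sex; Dunn's rank test (tie-corrected
  pooled variance) for pairwise contrasts; BH adjustment within each
  variable family.

## Microbiome statistics

* **Rarefaction** draws one multivariate-hypergeometric sample per
  column (subsampling without replacement to exactly the target depth),
  from a single generator seeded with the run seed — default 711, the
  convention used throughout. Defaults: 48,000 reads for human samples,
  65,000 for donor-vs-recipient comparisons, 113,000 within animals.
* **Filters**: taxa detected in < 20 % of samples are dropped
  (boundary inclusive); relative abundances are renormalized over the
  retained taxa; a second filter keeps taxa with mean relative
  abundance ≥ 0.1 %.
* **Cliff's delta** is computed from the full sign matrix; the 95 % CI
  uses Cliff's consistent variance estimate with the asymmetric
  transform, so bounds cannot leave [−1, 1]. Positive delta = enriched
  in the first group (Severe, by convention). A Welch t-test p-value is
  computed alongside and BH-adjusted across taxa. The "controlled for
  metformin / cluster transition" robustness pass recomputes the effect
  within strata and keeps the flag when per-stratum signs agree and a
  van Elteren-style stratified rank test has p < 0.05.
* **PCoA** Gower-centers −½D², eigen-decomposes, returns coordinates for
  positive eigenvalues scaled by √λ; negative eigenvalues are reported
  but excluded from the proportion-explained denominator (no Lingoes
  correction by default). Axis signs are fixed deterministically.
* **dbRDA** regresses the positive-eigenvalue PCoA axes on one centered
  predictor: R² = constrained inertia / total positive inertia,
  adjusted with Ezekiel's formula (reported in percent), p from 999
  seeded free permutations of the predictor.
* **Rosner (generalized ESD)** screening uses k = 5 candidates at
  α = 0.001, matching the outlier-exclusion convention for cohorts of
  about a hundred samples.
* Permutation counts default to 999 and every permutation stream is
  seeded, so permutation p-values are reproducible.

## Functional inference

KO abundance = binary membership matrix × species abundance vector, per
sample (incidence weighting — the summation rule implies presence, not
copy number). Input abundances are post-rarefaction relative abundances
by default; because the rule is linear, raw counts give proportional
results. Pathway abundance sums member KOs with no splitting: a KO in
several pathways contributes fully to each, so pathway totals may
exceed the KO total by design. A per-sample-normalized KO matrix is
available (`normalize=True`) since whether to renormalize before
pathway tests is a genuinely open choice; both outputs are exposed.

## FMT analytics

* **Engraftment**: donor and recipient are rarefied at the same depth
  and seed; a species counts as detected at ≥ 1 rarefied read (an
  optional minimum-read threshold guards against index bleed);
  fraction = |donor ∩ recipient| / |donor|.
* **Pseudoreplication**: the four animals of a donor share its inoculum
  and cage and are not independent; all inference runs on the 13
  donor-level geometric means. Zeros require an explicit offset
  (added before, subtracted after), keeping the transform reversible
  and visible. Animal-level effect sizes are reported as descriptive
  only.
* **OGTT AUC** integrates glucose by trapezoids from t = 0 (gavage) to
  90 min — the −30 min sample is fasting context only — and subtracts
  the rectangle under the curve minimum, so a flat curve scores zero
  and the statistic is invariant to adding a constant.
* **QUICKI** uses base-10 logarithms (the index's original definition;
  the base is switchable). HOMA-IR uses the mg/dl × 0.0555 / 22.5 form;
  fasting values are taken at t = 0.
* **Energy absorption** = (ingested − fecal kcal) / ingested × 100, with
  daily intake and fecal output averaged arithmetically over the
  collection days; excretion above intake warns (measurement artefact)
  but still returns.
* Two-group phenotype tests screen with Shapiro (normality, both
  groups) and Levene (variance homogeneity) at 0.05 and use Welch when
  both pass, Mann-Whitney otherwise; BH across the variable family.

## Synthetic-data generator

The generator's defaults are the study conditions the analytics are
validated under.

**Cohort** (`CohortSpec`): 100 patients, 55 % Severe at baseline, and
exactly round(45.5 % × n_Severe) responders transitioning to Mild within
the first year (prevalence 55 % → 30 %). Effect sizes are standardized
Severe−Mild gaps in *Mild-group* sd units — HbA1C 2.8, glucose 1.8,
duration 2.8, age 0.9 — because the Mild group is the natural reference
and Severe-group dispersion in such cohorts is inflated by
responder/non-responder substructure the two-group generator does not
model. Medication variables mirror the published composition of such
cohorts directly: post-surgery drug counts separate strongly (Mild
mostly 0, Severe mostly ≥ 2) and insulin use is essentially confined to
the Severe group. HbA1C/glucose/drug latents carry a within-patient
random effect (75 % of the unit noise) since longitudinal clinical
variables are strongly autocorrelated; the cross-sectional sd stays 1,
so the planted gaps are unchanged. About 80 % of patients are women.
Age and duration advance by exactly 1 and 5 years. All draws flow
through a named substream of the spec seed; identical specs are
bit-identical.

**Counts** (`CommunitySpec`): per-taxon baseline log-abundances are
normal (sd 1.5); each sample adds a log-normal perturbation
(sd 0.8, the overdispersion default), Severe samples multiply planted
taxa by 2^LFC, and one multinomial draw at a Poisson(depth) total makes
the column sums equal the drawn depths exactly. Planted taxa sit near
0.2 % relative abundance in Mild samples so the 0.1 % filter keeps
them; the default planted set is 12 taxa at LFC 2, assigned to the
Bacteroidia class to mirror the severity signature being emulated.

**FMT** (`FmtSpec`): each recipient keeps a Bernoulli(p_engraft = 0.6)
subset of its donor's species, renormalized to 40 % of reads, with the
remaining 60 % on a single diet-contaminant taxon (a *Lactococcus
lactis*-like dairy contaminant dominating high-fat-diet mice).
Phenotype defaults plant the Severe-worse regime: +4 mmol/L at the OGTT
peak (decaying over the curve), +6 mU/L fasting insulin, −0.4 g/day
food intake, on top of donor-level random effects and animal noise;
body composition carries no group effect.

**What the generator does not emulate**: within-patient microbiome
dynamics, read-level error, compositional interactions beyond closure,
realistic phylogenetic correlation among taxa, cage-to-cage microbial
drift. Passing tests therefore demonstrate that the statistics recover
the structure they assume, not that the assumptions hold in any real
cohort.

## Known limitations

* Cliff's-delta CIs are asymptotic; at group sizes below ~5 they are
  wide and the bounds are clipped.
* dbRDA drops negative eigenvalues rather than correcting them; for
  strongly non-Euclidean dissimilarities the explained fractions are
  relative to the positive part only.
* The per-timepoint standardization variant of the severity model is
  not built in (see above).
* Differential abundance works on relative abundances; no
  compositional (CLR-type) alternative is provided.
* BH control at q < 0.1 *expects* about a tenth of the rejections to be
  false; with a dozen true signals that is roughly one expected false
  positive per analysis — a property of the error criterion, not of the
  implementation.
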