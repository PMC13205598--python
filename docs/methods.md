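# Methods

This note documents the models, the statistical definitions, the defaults
and the open design choices behind `synthehr`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Record model

A record is `(sex, [(age, {codes}), ...])` with visits in canonical temporal
order; a cohort adds an ordered code vocabulary, the diabetes anchor code and
the CKD endpoint code.  Ages are stored as real years rounded to one decimal.
Raw generated visits may carry zero or several age labels; well-formed visits
carry exactly one, and downstream code reads a visit's *effective age* as the
maximum of its labels (the same resolution the refinement pipeline applies).

The flat feature table has columns `sex` (categorical), `age_at_diabetes`
(continuous), a boolean presence flag and a continuous first-diagnosis age
per comorbidity code, and `visit_count` (continuous).  These are the only
attributes the sequence encoding carries, which is why they define the
metric substrate; the age columns can be dropped (`flatten(...,
include_ages=False)`) for flag-only analyses.  Presence flag false implies a
missing age for that row.  The endpoint code is an ordinary column for
fidelity/privacy metrics and becomes the label (never a feature) in the
prediction task.

## 2. Cohort simulator

The simulator emulates a diabetes-anchored population cohort with known
generative parameters:

- sex ~ Bernoulli(female_fraction), default 0.5;
- age at diabetes ~ Normal(60.56, 13.83) truncated at 18 years — the
  demographic anchor of the cohort being emulated;
- a catalog of 80 comorbidities with prevalences log-spaced from 0.35 down
  to 5·10⁻⁴, mild cyclic female/male odds multipliers plus two strongly
  sex-specific analogs (odds multipliers 25 and 0.04), and onset-age normals
  with means 35–75 and SDs 8–14 years;
- disease assignment: logit⁻¹(logit(p₀) + log FM·[female] + log AM(band,
  sex)), where the age-profile multiplier AM depends on the band of the
  drawn onset age (young < 45, mid 45–65, old > 65).  The default profile
  (women 1.30/0.85/1.25 vs men 0.85/1.30/0.90) makes diagnosis rates higher
  in women in early adulthood and late life and higher in men in middle age
  — the clinically documented lifespan pattern the trajectory audit must
  recover;
- endpoint: P(CKD) = logit⁻¹(−2.6 + 0.015·dm_age + Σ wⱼ·flagⱼ) over
  pre-diabetes flags (the eight most prevalent diseases carry weights 0.9
  down to 0.2); onset is dm_age + Uniform(0.5, 15) years, so the endpoint is
  always strictly after the anchor.  These defaults give an endpoint rate
  near 0.35 and a Bayes-optimal AUROC near 0.72, a realistic operating point
  for CKD-after-diabetes risk models;
- visits group onsets sharing the same rounded age; diagnosis year ~
  Uniform over 2003–2022.  An optional year-dependent label-flip rate
  emulates improving data quality over calendar time.

Disease assignments are conditionally independent given sex and onset-age
band; real multimorbidity correlation structure is *not* emulated beyond the
shared age/sex drivers, because the audits need a known truth, not realism.
Explicit pairwise dependence can be exercised through the bias injector
instead.  `ground_truth` recomputes prevalences, sex gaps, the endpoint rate
and the Bayes AUROC (AUROC of the true endpoint probability) by vectorized
Monte Carlo from the same generative core the simulator uses.

**What passing tests do and do not show.**  Parameter-recovery tests prove
the audits measure what they claim on data whose truth is known.  They do
not certify behavior on real EHR data, whose missingness, coding drift and
dependency structure the simulator deliberately simplifies.

### Bias injector

Each injected pathology has a known magnitude so audits are testable:
female over-representation (flip an exact count of male records), rare-code
dropout below an empirical prevalence threshold (mode-collapse analog),
pairwise decorrelation (strip one code and re-assign it to random patients,
preserving the marginal), sex-specific trajectory delay (shift all
non-anchor onset ages of one sex), and random blanking of sex or anchor (to
exercise the refinement accounting).

## 3. Generator

The dual adversarial autoencoder is implemented on a small reverse-mode
autodiff core (`_autodiff.py`) written for this package; it is pure numpy,
float64, and bit-for-bit deterministic given (seed, config, input order) on
a fixed platform.

Token space: diagnosis codes ∪ age-band tokens (band = ⌊age/width⌋, width
default 5 years desk-scale, 1 year at full scale) ∪ {SEX_F, SEX_M} ∪ {EOS}.
The sex token is prepended into the first visit; every record ends with an
EOS step; sequences are truncated to the earliest max_len − 1 visits
(dropping the oldest-age tail) and padded with an explicit mask.

Architecture (smallest faithful instantiation of the dual-adversarial
idea):

- visit-set embedder: one hidden layer, multi-hot → ReLU(64);
- sequence encoder: GRU(64) over embedded visits, final state → linear →
  latent z (default dim 8);
- decoder: autoregressive GRU(64) whose step input is the embedded previous
  visit concatenated with z; per-step linear → sigmoid token probabilities.
  Teacher forcing during reconstruction, soft (probability) feedback in the
  adversarial generation pass, hard (thresholded) feedback at sampling;
- critics: two-hidden-layer (32) ReLU discriminators with the
  non-saturating adversarial loss, one on z vs N(0, I) draws, one on the
  sequence-mean token profile of real vs generated records.

Reconstruction is masked binary cross-entropy per token with an active-token
weight of 8 (visit vectors activate a handful of hundreds of tokens;
unweighted BCE keeps every probability below the 0.5 activation threshold).
Two latent-space stabilizers keep prior samples on-manifold at desk scale:
a batch moment-matching penalty (mean → 0, variance → 1, weight 1) added to
the reconstruction objective, and Gaussian latent noise (SD 0.3) during
reconstruction, which widens each record's latent basin.  Setting the
adversarial weights and both stabilizers to zero reduces the model to a
plain sequence autoencoder (tested by a memorization check).

Optimization: one Adam optimizer (lr 10⁻², desk-scale) per component;
L2 weight decay applied analytically to the autoencoder gradients; fixed
epoch count (default 50 desk-scale, 500 at full scale), no early stopping.
With DP enabled the reconstruction step becomes per-sample: gradients are
clipped to the clip norm, summed, Gaussian noise with SD
noise_multiplier·clip_norm is added, and the average is fed to Adam
(DP-Adam style).  No formal (ε, δ) accountant is implemented; the summary
reports clip norm, noise multiplier and step count for informal accounting
only.  Sampling decodes z ~ N(0, I), activates tokens at probability ≥ 0.5,
stops at EOS or max_len, and maps age bands back to band midpoints; all
defects (no anchor, no sex, empty or multi-age visits) are retained raw for
the refinement stage to handle and count.

## 4. Refinement

Rules applied per record, in order: (1) drop without anchor or sex;
(2) drop empty/age-only visits; (3) first occurrence per chronic code
(every vocabulary code is chronic by default; configurable); (4) keep the
maximum of multiple age labels; (5) impute a missing visit age as the
arithmetic mean of the adjacent visits' ages.  Boundary visits copy their
single neighbor's age, and a record with no aged visit at all is dropped
and counted — the minimal extension of the neighbor-mean rule that
preserves monotonicity.  Imputation runs after rule (2) so age-only visits
never donate ages.  The prediction stage additionally drops records with
non-ascending visit ages or an endpoint before the anchor.  The discard
report carries exact counts; `fraction_total_discarded` is computed as
(n_in − n_out)/n_in so the arithmetic is exact in floating point.

## 5. Metric definitions and numerical choices

- **KS complement**: 1 − max ECDF gap per continuous column, missing values
  excluded per column; mean over columns.
- **TV complement**: 1 − ½Σ|freq difference| over the union of categories.
- **Correlation similarity**: per continuous pair 1 − |r_real − r_synth|/2
  on pairwise-complete observations.  The division by 2 bounds the score in
  [0, 1] (a full sign flip scores 0); zero-variance pairs are skipped and
  noted.
- **Contingency similarity**: per column pair 1 − |V_real − V_synth|
  (Cramér's V over the union of observed levels, missing as an explicit
  level); continuous members are discretized into 10 equal-width bins with
  edges from the real data, widened so out-of-range synthetic values still
  land in a bin; a single-level table has V ≡ 0.
- **Sliced Wasserstein**: features numerically encoded (flags 0/1,
  categories one-hot over real levels, continuous median-imputed with the
  real median), min-max normalized by real bounds, zero-range features
  excluded; mean 1D Wasserstein-1 over seeded uniform random unit
  directions (default 1000).
- **Co-occurrence correlation**: f(a→b) = fraction of patients in whom a's
  first occurrence has a strictly smaller visit *index* than b's, over all
  ordered non-anchor pairs; Pearson correlation between the real and
  synthetic f-vectors.  Visit-index order (not age) is used and same-visit
  pairs count for neither direction; undefined when either vector has fewer
  than two distinct values.
- **New row synthesis**: a synthetic row matches a real row iff categorical
  values are identical, continuous values lie within 0.01 × the real column
  range, and missing positions coincide; the score is 1 − match fraction.
  The mean diagnosis count among matched rows is reported as the
  structural-simplicity diagnostic.
- **Disclosure protection**: correct-attribution attack — match on the key
  columns (default sex + age at diabetes, continuous keys within 0.01 of
  range), predict the sensitive column (default endpoint status) by
  majority vote among matches, baseline guess otherwise.  Full mode uses
  the modal-category baseline; estimate mode averages the attack over
  random subsamples against a uniform-random baseline.  Score =
  clamp(1 − max(0, acc_attack − acc_base)/(1 − acc_base)); a single-category
  sensitive column scores 1 by definition.
- **Membership inference**: zero-knowledge distance-to-closest-record —
  the canonical attacker requiring no model access.  Mixed-type distance:
  range-normalized absolute difference for continuous columns (ranges from
  the synthetic table, making the score invariant to common rescaling),
  0/1 mismatch for discrete; missing-vs-missing 0, missing-vs-present 1;
  averaged over columns.  Groups are downsampled to equal size with the
  given seed.  Reported as AUROC, AUROC* = max(a, 1−a), Δ = |a − 0.5|.
  A `cdist` fast path covers complete two-level/continuous columns; it is
  numerically identical to the reference column loop (tested).
- **Trajectories**: events are every code in every aged visit; rates divide
  bin event counts by the total individuals of the sex.  Because per-person
  rates may exceed 1, the 95% band uses the Poisson-rate Wald form
  diff ± 1.96·√(c_f/n_f² + c_m/n_m²).  Default bins: 5 years over
  [18, 100), top bin open.  DTW is exact O(nm) dynamic programming with
  |aᵢ − bⱼ| local cost and symmetric steps — at ≤ ~17 bins the
  approximation used by fast-DTW libraries is pointless and exactness
  enables oracle tests; distances are therefore comparable to, not
  identical with, approximate implementations.  Bins unpopulated in either
  cohort are dropped pairwise before DTW.
- **HWT**: additive hyperbolic weights w(r) = 1/(1+r) over zero-based
  ranks; a discordant pair at reference ranks (i, j) contributes
  w(i) + w(j); normalized by the total pair weight and symmetrized over the
  two reference choices.  Equal weights recover the unweighted Kendall tau.
- **Effect sizes**: Cohen's d (pooled SD) for continuous features, Cohen's
  h (arcsine-difference) for prevalences — the conventional standardized
  pair for means and proportions.

## 6. Prediction task and classifiers

Features: sex, age at diabetes, and per-comorbidity flag + first age
restricted to diagnoses at or before the anchor age (missing ages coded as a
−1 sentinel next to their flag column; tree-based additive models split
cleanly on the sentinel).  The leakage guard is tested by a perturbation
oracle: deleting all post-anchor visits must leave the feature matrix
unchanged.  The default classifier is boosted depth-1 stumps (LightGBM,
300 rounds, learning rate 0.1, deterministic single-thread mode): each tree
splits on one feature, so the ensemble is an additive model with per-feature
gain importances, ranked descending with a name-lexicographic tie-break.
Any object with `fit` / `predict_proba` / `feature_importances()` can be
substituted, including sequence models.  CV uses repeated stratified K-fold
(default 10 × 10; the desk-scale experiment plan uses 2 × 5) over the
scenario's training pool, each fit scored on the fixed real test set;
degenerate single-class folds are skipped and counted.  Hybrid pools are
plain concatenations — no reweighting, no deduplication.

## 7. Experiment designs and problem sizes

SSMR fixes one stratified 80/20 patient-level split and varies generator
seeds; MSSR varies the split and trains one generator per split.  Splits
are stratified by endpoint status to stabilize CV folds.  The desk-scale
defaults (2 000 simulated patients, 3 runs, 50 epochs, 200 SWD directions,
pairwise column metrics opt-in because they are O(p²) in the ~165-column
table) keep a full experiment in CPU-minutes; all full-scale values remain
configurable.  The validation battery itself runs at the sizes each check
needs: n = 20 000 for parameter-recovery bands and the Bayes-AUROC oracle
(±0.03), n = 2 000–4 000 for membership-inference calibration, 200 training
patients for the generator smoke run.

## 8. Known limitations

- The generator is a desk-scale instantiation: with tens of epochs and
  hundreds of records it reproduces structure (anchor, sex, visit grammar,
  coarse age progression) but not fine distributional detail, as the
  README's worked example shows honestly.
- DP accounting is informal; no (ε, δ) guarantee is claimed.
- The simulator's conditional-independence assumption understates real
  comorbidity correlation; co-occurrence and contingency metrics on
  simulated data therefore probe mechanics, not clinical structure.
- Privacy audits cover novelty, attribute disclosure and zero-knowledge
  membership inference only — no record-linkage with auxiliary data, model
  inversion, or subpopulation-targeted attacks.
- Which sensitive attribute the disclosure attack targets is a
  configuration choice (endpoint status by default); whether the metric
  substrate should carry per-comorbidity ages as well as flags is likewise
  configurable (both on by default).
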