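# Methods

## Overview

`painprofiles` implements a population-level pain-profiling pipeline: a
two-view partial least squares (PLS) canonical decomposition links a
participant × pain-experience matrix **Y** (n × q) to a participant ×
regional-brain-volume matrix **X** (n × p), permutation inference selects the
latent modes and loadings that exceed chance, individual "pain scores" are
derived by projecting centered pain data onto the retained pain-side vectors,
and each score is screened against medication, diagnosis, and phenotype
histories (MedWAS / DiWAS / PheWAS). A body-part labeling and a
dominant-profile labeling of the same cohort are compared by how well a
linear discriminant classifier predicts each from behavioural features.
Because the motivating cohort data are access-restricted, the package ships a
synthetic-cohort generator with planted ground truth; every stage is tested
against that ground truth or against independent brute-force oracles.

## Decomposition

The model seeks unit-norm weight vectors `v_l` (brain) and `u_l` (pain) whose
latent scores `X v_l` and `Y u_l` are maximally correlated. Both views are
centered (never scaled) before fitting. Per mode, the dominant singular pair
of the residual cross-covariance `X'Y` is found by NIPALS-style power
iteration (tolerance 1e-6, at most 500 alternations), after which both views
are symmetrically deflated by regressing each on its own latent score
("canonical" / mode-A deflation). After `min(p, q)` modes the residual
cross-covariance is numerically zero.

Two conventions worth stating:

- `R[l]` is the correlation of the paired *deflated* latent scores of mode l
  (the quantity the per-mode extraction maximizes). R is not assumed to be
  non-increasing across modes.
- The PLS Pain Score projects the *original* centered pain matrix onto `u_l`
  (`L_Y = Y U`), so a participant sitting exactly at the feature means scores
  zero on every mode.
- Signs are fixed by making each pain-side vector's largest-magnitude entry
  positive; flipping `u_l` and `v_l` jointly changes neither R nor any
  magnitude downstream.

The default number of fitted modes is K = 10; significance then retains a
subset.

## Permutation inference

Mode significance uses a non-parametric null: the brain matrix stays fixed,
the rows of the pain matrix are shuffled uniformly, and the full model is
refit (default 1000 permutations; the scaled-down study runs in this
repository use 100–200 and say so where they do). For every permutation all K
R-values and both weight matrices are recorded **per mode index**, with no
re-alignment of permuted modes to observed modes — aligning the null to the
observed solution would make the null depend on the alternative. P-values use
the add-one estimator `p = (1 + #{null R >= observed R}) / (1 + n_perms)`, so
the smallest attainable p at 1000 permutations is 1/1001 (< 0.001).

Per-feature loading significance compares each observed weight magnitude
against the (1 − tail) quantile of **that feature's own** permuted-magnitude
null for the same mode (default tail 5%). Per-domain summaries count flagged
features and sum their signed weights; the dominant domain is the one with
the largest absolute summed weight.

The null's 95% interval is reported as the 2.5th/97.5th percentiles of the
per-mode null R draws.

A caveat the synthetic experiments make visible: the per-index null is only
well calibrated for post-signal modes when the two views carry substantial
*within-view* correlation structure beyond the shared modes (as real
questionnaire and volumetric data do). On views that are pure shared-signal
plus white noise, the observed residual modes compete as "best remaining
direction" while the same index in the null sits deeper in the spectrum, and
the test becomes anticonservative for those indices. The generator therefore
plants private within-view structure by default (below).

## Split-half stability

Participants are split into random disjoint halves; each half is fit
independently; half-B modes are matched to half-A modes by greedy
maximal-|correlation| assignment with sign fixing; the per-mode |correlation|
between the halves' pain-side vectors is the stability statistic. For random
unit vectors in q dimensions the expected |correlation| is ≈ sqrt(2/(πq)),
which anchors the "unstable" end of the scale.

## Preprocessing

Fixed pipeline order, each step idempotent where that is meaningful:

1. **Participant filter** — drop participants with ≥ 90% missing across all
   pain fields (inclusive threshold).
2. **Field filter** — drop pain fields with ≥ 75% missing across the
   retained participants.
3. **Recoding** — every pain item is mapped onto a common 0–10 scale with 0
   "best" (health) and 10 "worst" (disease). Shipped rules: continuous
   identity, continuous reversed (10 − x), a 1–4 ordinal mapped to
   {0, 10/3, 20/3, 10}, and binary {0 → 0, 1 → 10}. A raw value outside its
   rule's domain is reported per cell, set missing, and warned about.
4. **Imputation** — each missing cell is replaced by a uniform draw (with
   replacement) from the same feature's observed values. One seed; features
   in column order, missing cells in row order, so reruns are bit-identical.
5. **Deconfounding (brain only)** — each brain feature is replaced by its
   OLS residual on an intercept plus head-size and motion confounds;
   residuals have |r| < 1e-10 with every confound. Pain features are *not*
   deconfounded: age/sex/BMI-linked variation is part of the clinically
   relevant signal the decomposition is meant to capture.

Missingness fractions are computed on the raw input, before any recoding
failures.

## Association batteries

Each battery correlates one profile's pain scores with every clinical column
(Pearson r, two-sided p, Fisher z = atanh(r) with |r| clipped at 1 − 1e-12),
on pairwise-complete observations minus any control-exclusion mask. Columns
that end up constant or with < 3 observations are recorded as missing and
excluded from the multiplicity count m. Two flags per column: Bonferroni at
0.05/m and Benjamini–Hochberg at 5% FDR (step-up via statsmodels).

- **Phecode matrix (DiWAS):** ICD-9/10 records map to phecodes by
  longest-prefix match within coding version; only phecodes represented in
  the cohort get (binary) columns. Each phecode's exclusion ranges mark
  participants with a *related* code — but not the phecode itself — for
  removal from that column's control group, reducing case contamination.
  Masking never changes a case's status.
- **ATC matrix (MedWAS):** per-participant prescription counts over ATC
  level-3 categories (code prefix of length 4). A medication with several
  ATC codes takes the first in alpha-numeric order; combination products are
  excluded; codeine is classified under its cough-suppressant code and never
  counted under N02A opioids; unmapped names are logged and skipped. The
  shipped map is a small synthetic stand-in (the licensed catalogues are
  user-supplied tables in real use).
- **Phenotype curation (PheWAS):** listed categories (default
  "mental health") are dropped; categorical-unordered columns are one-hot
  expanded; columns with fewer than 500 observed participants are dropped;
  within any group correlated above 0.99 only the first column in file order
  is kept.

**Concordance** correlates two profiles' Fisher-z vectors over shared
testable columns, per battery; a per-battery mean off-diagonal summarises
which batteries make the profiles look most alike. Flipping one profile's
sign orientation flips its concordances exactly.

## Classifier comparison

- **Body-part labels** use a fixed precedence: an "area most bothered"
  answer wins; otherwise an all-over-body flag maps to region code 900
  ("more than three major sites"); otherwise more than two listed sites map
  to 900 and exactly two sites take the first listed; one site maps through
  the site→region table; no sites is the no-pain code.
- **Profile labels** come from pain-agnostic scores: location fields are
  zeroed in the data (the pain-side vectors are untouched), each score
  column's sign is flipped if needed so it correlates positively with the
  count of reported painful sites, columns are z-scored (the modes' raw
  scales are not commensurate, and zeroing location fields shifts each
  column by a different constant), and each participant takes the argmax
  class — except that the floor(0.34 · n) participants with the smallest
  maximum score form a separate no-pain class, mirroring the no-pain
  fraction of the location-based labeling. Argmax ties break by fixed
  profile order. Ranking by the maximum (rather than mean or sum) keeps the
  no-pain rule consistent with the argmax class rule.
- **Classifier:** Gaussian LDA with shared covariance. Evaluation is
  stratified 5-fold cross-validation; within each training fold, classes are
  balanced by oversampling minorities with replacement to the majority size
  (preserves all training data), independently for each of 10 resamples
  (50 iterations total). The held-out fold is never resampled, and reported
  performance is on the untouched fold. Metrics: accuracy and micro-averaged
  AUC (one-vs-rest indicators and scores pooled across classes, then a
  single rank-based AUC), plus per-class one-vs-rest AUCs.

## Mood × medication crosstab

Summed instrument totals are rounded half-up and binned: pain interference
(BPI) into mild (1–4) / moderate (5–6) / severe (7–10); depression (PHQ-9)
into minimal (1–4) / mild (5–9) / moderate (10–14) / moderately severe
(15–19) / severe (20–27). A total of exactly 0 falls below every named bin
and is kept in a "none" stratum excluded from the grid. Within each
BPI × PHQ-9 cell, participants split into opioid-only (N02A > 0, N06A = 0),
antidepressant-only, both, and neither; within-cell proportions sum to 1 in
every non-empty cell.

## Synthetic cohorts

The generator plants: latent scores Z ~ N(0, I_K) per participant;
orthonormal pain-side vectors U (each mode dominant on its own disjoint
symptom-domain block, with mode 1 also loading moderately on the location
block) and orthonormal brain-side vectors V (random); strictly decreasing
mode strengths s (default 1.0, 0.85, 0.7, 0.55, K = 4); view signals
`Z diag(s) U'` and `Z diag(s) V'`.

Noise and observation model:

- Per-view noise at scale `noise_sd` (default 0.5) mixes an isotropic floor
  with **private low-rank structure** (rank 30, decaying weights): real
  questionnaire and volumetric data are strongly autocorrelated within view,
  and without that structure the per-index permutation null is
  anticonservative for post-signal modes (see above). Head-size/motion
  confound leakage into the brain view also scales with `noise_sd`. Setting
  `noise_sd = 0` therefore yields an exactly rank-K cross-covariance.
- Each pain feature is affinely standardised onto the 0–10 scale (centred at
  5, unit sd, clipped only beyond ±5 sd) and then raw-coded by a per-feature
  rule: a mixture of identity, reversed, 1–4 ordinal, and binary codings by
  default. The discrete codings are deliberately *nonlinear* observations of
  the planted structure: they attenuate and distort loadings (as real coarse
  codings do), so exact-vector recovery claims are assessed under the
  affine-only coding configuration (`discrete_coding=False`), while
  detection, domain dominance, and all clinical analyses are exercised under
  the full mixture. The affine 0–10 standardisation itself rescales features
  individually, so even then the fitted vectors match the planted ones up to
  a per-feature scaling — |corr| > 0.9 per mode at the default noise, > 0.99
  when fitting directly constructed linear data.
- Missingness is completely at random within three tiers: a fraction of
  participants with 95% of their pain cells removed, a fraction of pain
  fields with 80% removed, and cell-level MCAR (defaults 2% / 3% / 5%).
- Pain-location sites are Bernoulli with log-odds mildly increasing in the
  leading latent score (weight 0.4) and base prevalences drawn in
  0.09–0.17, so the marginal no-site fraction is close to the 34% no-pain
  study condition while *which* site hurts stays idiosyncratic — keeping
  body-part labels only weakly predictable from behavioural features, as in
  the population finding the classifier comparison mirrors.
- Clinical events are logistic in designated latent scores at 0.5 log-odds
  per SD (opioids on mode 1; antidepressants on the mood modes; analgesics,
  anti-gout and metabolic drugs on the medical-pain mode; several null
  categories). These effect sizes are free parameters of the generator,
  chosen so association batteries show Bonferroni-significant hits at
  n = 5000; they are not calibrated to any reported value.
- The null-cohort variant redraws the latent scores independently for the
  brain view, so the true cross-view association is exactly zero while all
  marginals are preserved.

One master seed drives every sub-stream (structure, latents, noise, codings,
missingness, clinical, locations, confounds) through spawned child
generators, so bundles are bit-reproducible.

What the generator does **not** emulate: informative (non-MCAR) missingness,
non-Gaussian latent scores, longitudinal visit structure, realistic
ICD/ATC/phenotype catalogues (the shipped maps are toy synthetic tables), or
the cohort's demographic composition. Passing tests show the pipeline's
operations are correct and calibrated under these planted conditions; they
do not certify effect sizes or profile content on real populations.

## Numerical choices and degenerate inputs

- Power iteration: tolerance 1e-6 on the weight update, max 500 iterations;
  start vector is the largest-norm row of the cross-covariance.
- Fisher z clips |r| at 1 − 1e-12. Zero-variance columns are errors in the
  decomposition (named in the message) and recorded-as-missing in batteries.
- Rank-deficient confound matrices raise an error naming the collinear
  columns (rank-revealing QR pivot order).
- LDA falls back to a small ridge (shrinkage 1e-4, logged) if the pooled
  covariance is singular.
- Dominant-profile argmax ties break by fixed profile order; dedup of
  correlated phenotypes keeps the first column in file order.
- Study sizes used by the shipped tests and the acceptance script: planted
  runs at n = 5000 with 200 permutations; calibration over 100 null cohorts
  of n = 1000 with 100 permutations each; chance-level classification at
  n = 4000 with 50 CV iterations. These are the package's chosen synthetic
  study sizes; the inferential machinery is identical at any n.

## Known limitations

- The per-index permutation null inherits the anticonservativeness described
  above whenever the data lack within-view structure; the package documents
  rather than repairs this property of the published procedure.
- Recovery of planted vectors is assessed up to the observation model's
  per-feature scaling; no attempt is made to invert the 0–10
  standardisation.
- The concordance module reports standard Pearson p-values for the
  similarity of Fisher-z vectors; no test of *differences between*
  concordances is provided.
- `run_was` treats clinical columns as exchangeable Pearson targets; count
  columns are not modelled as counts.
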