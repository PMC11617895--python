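# Methods

## Scope and data model

The package starts from an identified-feature DI-MS intensity table; peak
picking, spectral conversion and lipid identification are upstream and out of
scope. The in-memory container (`IntensityTable`) is a samples × features
matrix with per-sample role (plasma / qc / ltr / blank), measurement batch
(nominally 96 plasma samples each) and temporal batch (two large measurement
epochs), plus a raw/log2 scale flag. Lipids are named at sum-composition
level, `<CLASS> <C>:<D>`, over 14 classes (CAR, CE, DAG, TAG, Cer, SM, PE,
PE P-, LPE, PC, PC O-, LPC, LPC O-, PI); the ether suffix (`O-`/`P-`) is part
of the class token and attaches directly to the carbon count (`PC O-34:3`).

The double-bond index of a species is DBI = D / k with k = 3 for TAG, k = 1
for lyso-species, CE and CAR, and k = 2 for all other classes. DBI is kept as
an exact rational; medians of even-length sets are midpoints of the central
pair.

## Post-processing chain

Applied strictly in this order, with strict inequalities throughout:

1. remove features with > 10% zeros across plasma samples (other roles do not
   enter the fraction);
2. replace remaining zeros by 0.9 × the feature's minimum non-zero plasma
   value — the minimum is computed on plasma only but applied to every role,
   because blank and QC values are needed later at log2 scale and log2(0) is
   undefined;
3. log2 transform;
4. remove contaminants: mean(log2 plasma) − mean(log2 blanks) < 1;
5. per-batch correction: subtract the feature's QC median within each batch,
   add back its pooled QC median over all batches ("grand" median of the
   pooled QC samples, not the median of per-batch medians; the two readings
   differ only by a per-feature constant that cancels in all downstream
   correlations);
6. remove unstable features: SD over all QC samples > 0.5 (sample SD, n − 1);
7. temporal alignment: shift every sample of temporal batch 2 by
   median(LTR, batch 1) − median(LTR, batch 2). This is the "align 2 to 1"
   reading: the alternative literal reading (add the 2−1 difference to
   batch 2) would widen the gap instead of closing it.

Filters remove features, never samples; every removed feature is attributable
to exactly one audit record (`FilterReport`). Degenerate inputs fail loudly:
no plasma samples, no blanks, a batch without QC (named in the error), fewer
than two QC samples, or an all-zero plasma feature reaching imputation.

## Association analysis

Each lipid is residualized by OLS on intercept + age + sex (female = 1) +
BMI; any affine covariate encoding gives identical residuals, and
rank-deficient designs are rejected. Pearson correlations of residuals with
the raw HADS subscale scores get two-sided p-values from the exact
t-transform, BH adjustment across the panel, and 95% percentile-bootstrap CIs
over (residual, score) pairs (default 10,000 resamples; the workflow default
is 2,000, which changes CI endpoints by well under the reporting precision).

The study-level test shuffles the score vector across subjects (after
residualization), recomputes the number of lipids with BH q < 0.1 per
shuffle, and reports the plain proportion of B = 1000 shuffles whose count
reaches the observed one — no +1/(B+1) smoothing, so the smallest attainable
p is 0. Permutation i draws from an independent substream of (seed, i), so
the result is independent of evaluation order.

One calibration subtlety: the hit count is heavily discrete under the null
(about 90% of null datasets have zero BH hits), so the plain proportion is a
conservative, visibly non-uniform p-value — most null datasets report p = 1.
`PermutationResult` therefore also carries a randomized tie-broken rank
p-value (observation pooled with the B nulls, ties broken uniformly), which
is exactly uniform on {1/(B+1), …, 1} under exchangeability and is the right
statistic for calibration diagnostics. Reported study p-values use the plain
proportion.

## Enrichment and unsaturation

Class over-representation among the FDR-significant lipids uses the one-sided
hypergeometric upper tail and the enrichment ratio
`n_hits / (N_sign × N_group / N_total)`; group sizes always come from the
panel at hand, never from a fixed inventory, and classes absent from the
panel are skipped. The ether classes (PC O-, PE P-, LPC O-) are additionally
tested as one merged group. DBI of significant vs remaining lipids is
compared two-sided by Mann–Whitney U — exact enumeration for tie-free groups
of ≤ 8, tie-corrected normal approximation otherwise (the test's sidedness is
a design choice; two-sided is the conservative default).

## Congruence

Clinical alterations are per-lipid mean log2 fold-changes of patients versus
the full volunteer cohort (raw means, not covariate-adjusted — the
matched-control contrast is available but not the default). Agreement with
the volunteer association coefficients is Spearman (midranks on ties) with a
percentile bootstrap over lipid pairs, reported for all lipids, excluding
TAGs, ether phospholipids only, and (descriptively) TAGs only.

Note an intrinsic ceiling: the per-lipid coefficient vector is estimated with
sampling noise ≈ 1/√n ≈ 0.04 at n = 604, while the generator's true effect
vector is sparse (eight sizeable effects plus a weak background). The rank
correlation between the *estimated* vectors is therefore attenuated to
roughly half the true-vector congruence; the subset ordering (no-TAG > all,
ether ≥ all) is the robust, tested property, not the magnitude.

## Risk model

`LogisticRegression` with a pure L1 penalty (liblinear coordinate descent,
tol 1e-6); a predictor counts as selected when |w| > 1e-8. Training
standardization (mean/SD over all training samples) is stored on the model
and reused verbatim when scoring new cohorts — a deliberate reproduction of
the original protocol, which standardizes across the full training set
*before* cross-validation splitting (a mild leak); `strict_cv=True`
standardizes within each training fold instead, and both paths are tested.

Randomized CV draws k = 10 test samples per class (without replacement,
independent substream per split), trains on the remainder, and accumulates
rank-based ROC AUC plus accuracy / sensitivity (patients) / specificity
(controls) at the 0.5 probability cutoff; summaries are means with (2.5%,
97.5%) subsampling intervals. Because C is sensitive to training-set size, C
is chosen by the mean selected-predictor count over the grid
{0.01, 0.1, 0.5, 10, 100, 500, 1000}, targeting ≈ 15 predictors; the mean
count is monotone in C at protocol level, though a single fit in the
interpolating regime (n = 68 < p = 186) can shed a feature between very large
C values.

Transfer: the final model (C = 0.3, all 68 training samples: 32 patients,
21 controls, 15 volunteers with HADS-A and HADS-D ≤ 7 chosen at random among
eligibles) scores the volunteer cohort; the 15 training volunteers are
flagged and excluded from every downstream evaluation (n = 589 at study
scale). Volunteer scores are related to HADS by Spearman over all subjects
and Pearson over per-score mean predictions, and by bracket ROC: subjects
with HADS-D ≥ t versus controls (HADS-D ≤ 7), AUC by the rank identity with
tie correction. One fixed label shuffle retains chance train/test-shared
structure at these sample sizes, so null calibration of the CV protocol is
assessed on average over shuffles.

## Synthetic cohorts

**Phenotypes.** Each subject has age (truncated normal 30 ± 10 on [18, 70]),
sex (72% female), BMI (truncated normal 24 ± 4 on [15, 45]; a generic healthy
adult default — the study reports no BMI summary), and two latent traits
(anxiety, depression). The latents load on standardized age/sex
(anxiety: age −0.245, sex +0.17 ≙ R² 6% / 3%; depression: age −0.10 ≙ R² 1%)
plus bivariate-normal residuals with correlation ρ_e = 0.6875; covariates are
standardized by their truncated-distribution moments so the latents are
mean-zero by construction. Each HADS subscale is the sum of 7 ordinal items:
item propensity = latent + N(0, 1), cut at per-subscale thresholds
τ_A = (−0.528, 1.142, 2.679), τ_D = (0.338, 1.406, 2.995) into {0, 1, 2, 3}.
These constants come from `scripts/calibrate_phenotypes.py`, which solves by
Gauss–Hermite quadrature for the thresholds matching the target category
proportions (HADS-D: 81% ≤ 7, 92% ≤ 10, 98.5% ≤ 14; HADS-A: 65% / 85% / 97%)
and for the latent correlation giving a score-level Pearson correlation of
0.55. Building scores from items (rather than discretizing a Gaussian)
attenuates the score correlation relative to the latent one, exactly as in
real questionnaire data; the calibrated attenuation factor is
λ_D = corr(score, latent) = 0.861.

**Lipid panel.** 186 species over the 14 classes with declared per-class
counts (TAG 60, PC 30, SM 18, PC O- 14, LPC 10, PE/PE P-/DAG/CE 8 each,
Cer 6, LPE/LPC O-/CAR/PI 4 each — the real per-class inventory is not
published, so these are plausible, config-editable defaults for a
positive-mode DI-MS plasma panel). Names are drawn from class-appropriate
carbon/double-bond ranges (deterministically from `panel_seed`, so the "true
study" is fixed across run seeds), always including the eight designated
effect carriers and at least 12 saturated TAGs (DBI < 1). Baselines: per-lipid
log2 mean U(12, 20), SD lognormal (median ≈ 0.47), equicorrelation 0.4 within
class blocks, and N(0, 0.12) log2 loadings on each standardized covariate.

**Effects.** The eight designated ether/PUFA species carry association
targets r = −0.15 … −0.12 (entering as β × standardized depression latent
with β = r / (λ_D × 0.96); the 0.96 compensates the measured residual
attenuation through covariate residualization and post-processing, so
analysis-level correlations land on target). The background is a weak
structured vector (ether shift −0.012, DBI slope −0.006, noise SD 0.012,
clipped at |r| ≤ 0.05); saturated TAGs get a guaranteed-negative background
effect. Clinical fold-changes are δ = 2·r + N(0, 0.08), except the
saturated-TAG block where δ is a positive discordance (+0.30), giving a
congruent profile overall (true-vector Spearman ≈ 0.47) that rises when TAGs
are excluded. The δ amplitude was set so the clinical CV ROC AUC lands near
0.91–0.94 at the study's cohort sizes. `effect_scale=0` switches the whole
effect vector off for null calibration.

**Technical layer.** The clean log2 volunteer table is exponentiated and
wrapped in an acquisition structure: batches of 96 plasma samples with one QC
at the start plus one QC and one LTR per 12 samples, 6 extraction blanks
spread over batches, per-(batch, feature) shifts N(0, 0.3) applied to every
role (QCs track them, so QC correction removes them), and a per-feature
temporal drift N(0, 0.4) applied to plasma/LTR/blank — but not QC — samples
of the second epoch. The QC exemption models batch-local QC pools: a
long-term drift of sample material is invisible to batch-fresh pools and only
detectable against the long-term reference; without it, QC correction would
already remove the drift and the LTR stage would be unidentifiable. Zeros are
detection-limit censoring (the lowest ~2% of raw plasma intensities per
feature read as zero; ~20% for the planted high-zero features), which is both
how DI-MS zeros arise and the regime in which the 0.9 × min imputation is
nearly exact — uniform-at-random dropout would make the imputation rule
systematically wrong. Planted features (8 high-zero, 10 contaminants with
blank delta ≈ 0.2, 6 unstable with QC noise SD 0.9) each violate exactly one
filter rule.

What the generator does **not** emulate: within-class correlation beyond a
single equicorrelated block, intensity-dependent noise, instrument drift
within batches, missing phenotype data, item-level HADS psychometrics beyond
a single latent per subscale, and medication effects. Passing tests therefore
demonstrate that the pipeline's logic and calibration are correct under this
generative model, not that the biological effect sizes would replicate in new
cohorts.

## Numerical choices and degenerate inputs

All stochastic operations take explicit seeds; substreams are spawned per
permutation / split / stage, so results are order-independent and
byte-reproducible. Thresholds are strict as stated; boundary cases (zero
fraction exactly 10%, blank delta exactly 1, QC SD exactly at the cap) are
retained. ROC AUC uses average ranks (ties ½). Bootstrap resamples that
produce a constant vector contribute NaN and are excluded from percentile
CIs. Pearson p-values use the t-transform with the variance guard
1 − r² ≥ 1e-300. The workflow defaults scale the heavier resampling loops
(2,000 bootstrap resamples, 1,000 permutations, 1,000 CV splits); the test
suite uses smaller replicate counts chosen so each check's discriminating
power is preserved.

## Known limitations

* The per-lipid effect targets are the published observed coefficients of a
  selected (FDR-passing) set; planting them as true effects yields an
  expected recovery of ≈ 5/8 at FDR 10% and n = 604 — selection ("winner's
  curse") means the printed values overstate what is recoverable on average.
  The package treats them as calibration anchors regardless, since no
  unbiased effect estimates are available.
* Estimated congruence magnitudes are attenuated well below the true-vector
  congruence (see above); only orderings are asserted.
* The default CV protocol reproduces the original standardization leak by
  design; use `strict_cv=True` for leak-free estimates.
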