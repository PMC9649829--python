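# Methods

This note documents the statistical procedures implemented in `uhrsleepwm`,
the assumptions they make, the tunable parameters that matter, and the design
choices taken where the methodology was genuinely open.

## Scientific setting

The pipeline targets a two-group observational design: individuals at
ultra-high risk (UHR) for psychosis and healthy controls (HC), each
characterized by (i) mean fractional anisotropy (FA) in the 48 white-matter
tracts of the JHU ICBM-DTI-81 atlas, (ii) subjective sleep quality from a
modified Karolinska Sleep Questionnaire, (iii) one night of wrist actigraphy
with a sleep diary, and (iv) nuisance covariates (age, sex, absolute and
relative head motion in the scanner), optionally extended with medication
flags and symptom totals. The analysis asks whether white-matter
microstructure covaries with sleep-wake disturbance, univariately (two FA
summaries against six sleep measures) and multivariately (all 48 tracts
against all six measures at once).

## Sleep measures

**Subjective indices.** Seven questionnaire items are each scored 1–5
(1 = never … 5 = always, higher = worse). The Disturbed Sleep Index is the
sum of the four sleep items (difficulty falling asleep, disturbed/restless
sleep, repeated awakenings, premature awakening), range 4–20; the Disturbed
Awakening Index is the sum of the three awakening items (difficulty waking,
non-refreshing sleep, exhaustion at awakening), range 3–15. A respondent
missing any contributing item receives a missing index and is excluded
listwise from analyses that use it.

**Actigraphy.** Counts arrive on a strict 1-minute epoch grid (half-open
epochs `[t, t+60 s)`); an epoch is "in bed" iff its start lies in
`[bed_time, rise_time)`, with the diary taken as the authoritative rest
interval. Each epoch is scored sleep/wake by the Cole–Kripke one-minute
weighted-sum classifier: with counts `A_i`, epoch `i` is sleep iff

    1e-5 * (404 A[i-4] + 598 A[i-3] + 326 A[i-2] + 441 A[i-1]
            + 1408 A[i] + 508 A[i+1] + 350 A[i+2]) < 1,

zero-padded at the recording edges. The vendor scoring used in such studies
is proprietary and undocumented; Cole–Kripke is the standard published
alternative and is fully reproducible. From the scored labels: sleep onset is
the first sleep epoch; TST counts sleep epochs (minutes); WASO counts wake
epochs after onset; SE = 100·TST / time-in-bed. The fragmentation summary is
SFI = MI + FI with MI = 100 · (wake minutes in bed) / (time in bed, minutes)
and FI = 100 · (# sleep bouts of length exactly 1 epoch) / (# sleep bouts).
MI is sometimes printed elsewhere with an "hours" denominator, which is not
dimensionally a percentage; the minutes/minutes form is used here because it
is bounded and consistent with SFI magnitudes near 25. A night scored with no
sleep epoch at all yields TST = SE = WASO = 0, a missing onset, and an
explicit quality flag; such nights are excluded from the actigraphy measures.
The accounting identity `latency + TST + WASO = time in bed` holds
epoch-exactly whenever onset exists and is enforced by tests.

## White-matter summaries

Global FA is the weighted mean of the 48 tract means, Σ wᵢFAᵢ / Σ wᵢ.
Weights are optional (per-ROI skeleton voxel counts when available) and
default to equal, since a bare FA table carries no weighting information.
Callosal FA is (genu + body + splenium)/3. Input tables are validated against
the packaged canonical label list (exact match after whitespace
normalization); missing ROIs raise errors naming the label.

## Univariate inference

* **Group test**: nested-model F. `y ~ 1 + covariates + group` against
  `y ~ 1 + covariates`; F = ΔRSS / (RSS_full / df_den) with the exact
  F(1, df_den) reference. With one binary factor plus continuous covariates
  this is unambiguous (no Type II/III distinction arises).
* **Partial correlation**: Pearson correlation of the OLS residuals of x and
  y on `[1, covariates]`; two-tailed p from the t transform with
  df = n − k − 2 (k covariates); 95% CI from a subject-level nonparametric
  percentile bootstrap (default B = 1,000, seeded) in which the
  residualization is refit within every resample. Degenerate resamples
  (zero residual variance) are redrawn, capped at 10·B attempts.
* **FDR**: Benjamini–Hochberg step-up adjustment, applied over one family =
  the full grid of {global FA, callosal FA} × {six sleep measures} within
  each analysis population (ALL / UHR / HC). Post-hoc confounder-sweep models
  are corrected only within their own family, mirroring how such sensitivity
  analyses are usually reported uncorrected across sweeps.
* **Mediation**: simple three-variable mediation; a from `m ~ x + cov`,
  b and c′ from `y ~ x + m + cov`, c from `y ~ x + cov`; indirect = a·b with
  a percentile bootstrap CI. For linear models c = c′ + a·b exactly, which
  tests assert to 1e-10.

OLS fits use ordinary least squares via `numpy.linalg.lstsq`; statsmodels and
pingouin serve as independent cross-checks in the test suite.

## PLS correlation

Both blocks are residualized column-wise on `[1, covariates]` and scaled to
unit sample variance (divisor n − 1) **before** the decomposition — the
standard behavioural-PLS way of "co-varying" nuisance variables. The
cross-block matrix R = Xr′Yr/(n−1) then contains correlations of
standardized residuals, making the singular values scale-free. The SVD
R = VΣU′ pairs X-saliences (columns of V) with Y-saliences (columns of U);
latent-variable scores are Lx = XrV, Ly = YrU, and cov(Lx_k, Ly_k) = σ_k.
Signs are fixed deterministically: per LV the largest-magnitude Y-salience
element is made positive.

* **Omnibus test**: the Inertia index Σ_k σ_k, with a permutation null built
  by shuffling the rows of Yr (default 10,000 permutations, configurable up
  to 100,000). p = (1 + #{Inertia_perm ≥ Inertia_obs}) / (1 + n_perm); the
  +1 correction keeps p above the 1/(n_perm+1) floor.
* **Per-LV tests**: the non-rotated k-th singular value is compared against
  its permutation distribution, same estimator. No Procrustes alignment is
  applied in the permutation branch — rotation correction belongs to the
  bootstrap, where the quantity of interest is the salience, not the rank.
* **Bootstrap CIs**: subjects resampled jointly with replacement (default
  10,000 resamples); each resampled pair of blocks is re-centered,
  re-standardized and refit; the resampled saliences are aligned to the
  point estimate by the orthogonal Procrustes rotation solved on the
  Y-saliences and applied to both blocks (removing axis rotation/reflection
  indeterminacy); percentile 2.5/97.5 bounds per element. An element is
  *reliable* when its CI excludes zero. Rank-collapsed resamples are
  redrawn, capped.
* **Reporting rule**: an LV is flagged reportable when its covariance share
  σ_k²/Σσ_j² exceeds 5% and its permutation p < 0.05. The share is defined
  on squared singular values so the shares sum to one.
* **Group-wise analysis**: within-group analyses are run independently after
  within-group residualization. The group-contrast omnibus test is a design
  choice (the construction is not standardized in the literature): both
  blocks are residualized across the pooled sample, each group's cross-block
  matrix R_g is computed, the group-average matrix is subtracted, the
  centered matrices are stacked, and the Inertia of the stack is the test
  statistic; the null permutes group membership with group sizes preserved.
  This is the mean-centered "task PLS" construction adapted to a
  two-block contrast.

Permutation and bootstrap loops are vectorized (batched cross-products and
batched SVD in chunks of ≈ 8 MB) so that 10,000 iterations on a 100 × 48
problem take seconds on one core.

## Synthetic cohort generator

The generator produces datasets with the structure the analysis assumes,
for calibration, power and recovery testing. It emulates the *measured*
quantities only — FA tables, questionnaire items, epoch-level counts — not
raw diffusion imaging or raw 30 Hz accelerometry.

Per subject (each with an independent random stream spawned from the master
seed, so generation is reproducible bit-for-bit and order-independent):

* **Covariates**: age ~ N(23.6, 3.9²); sex female with probability 0.42
  (patients) / 0.60 (controls); absolute and relative scanner motion
  ~ N(1.26, 0.35²) and N(0.18, 0.08²) truncated positive. Clinical scores
  (depressive-symptom total, UHR-symptom composite) are drawn at study-scale
  means/SDs and correlate mildly with the sleep latent so mediation and
  confounder sweeps are non-trivial.
* **Latent sleep disturbance** z ~ N(0, latent_sd²), recorded as ground truth.
* **ROI FA** = per-ROI baseline (frozen draws from U(0.4, 0.8)) − 0.013 for
  patients + covariate effects + a shared per-subject offset
  ~ N(0, 0.012²) + x-loadings·z + independent N(0, 0.01²) noise per ROI,
  rejected and redrawn if any value leaves (0, 1). The shared offset gives
  the 48-ROI average the between-subject SD (~0.012) real global-FA tables
  show; without it the group F on global FA would be absurdly large. The
  planted x-loadings are sparse: ±0.012 FA per latent s.d. on six tracts
  (fornix positive; bilateral corticospinal tract, left cerebral peduncle,
  left medial lemniscus, left cingulum-hippocampus negative), zero elsewhere.
* **Questionnaire**: latent-Gaussian ordinal model. Item i is
  1 + #{cut-points below tᵢ}, tᵢ = baseline + loadingᵢ·z + N(0,1), with
  fixed symmetric cut-points (−1.5, −0.5, 0.5, 1.5). Item baselines
  (−0.9 sleep items, −0.35 awakening items, +0.8 for patients) put the group
  index means at study scale (HC ≈ 8.5/7.9, UHR ≈ 11.5/10.5). The per-item
  loading is the natural-scale index loading (default 1.5 DSI points, 1.2
  AWI points per latent s.d.) divided by (#items × the ordinal model's
  slope at zero), a first-order linearization of the threshold model. Both
  recall periods are generated; "last night" adds extra latent noise
  (SD 0.3).
* **Actigraphy**: a 24-h whole-minute epoch grid. Out-of-bed epochs carry
  Poisson(250) counts. In bed, a two-state semi-Markov bout process runs: an
  initial Poisson wake latency whose mean slope in z is derived from the TST
  and WASO loadings through TST = TIB − latency − WASO; then alternating
  geometric sleep bouts (mean 13 min at z = 0, shortened by the SFI loading
  as exp(−(l_SFI/26)·z)) and wake bouts whose mean is set so the stationary
  wake fraction matches the target WASO (48 min underlying at z = 0 +
  14 min per latent s.d.). Wake epochs carry Poisson(80) counts, sleep
  epochs Poisson(0.3·e^{z/2}) — so a deeply asleep limit (z → −∞) yields
  all-zero in-bed counts. The SE loading is emergent (SE = TST/TIB) rather
  than separately enforced; the default −3.1 %/s.d. is the value implied by
  the TST loading at TIB = 480 min.

**Measurement amplification.** The Cole–Kripke window smears high-count wake
epochs into their neighbours, so *scored* WASO exceeds the underlying bout
process's wake time by roughly 1.5× — exactly the kind of systematic
measurement behaviour real actigraphy scoring shows. The bout-process
defaults were therefore calibrated once so the scored z = 0 summaries sit at
study scale (WASO ≈ 57 min, SE ≈ 85%, SFI ≈ 24); the planted WASO loading
acts on the underlying process and appears amplified (~21 scored min per
latent s.d.) after scoring. Recovery tests use the scored measures, i.e.
they exercise the full measurement chain.

**What the generator does not emulate**: multi-night actigraphy, circadian
phase, weekday structure, item-specific questionnaire thresholds,
site/scanner batch effects, spatially structured FA covariance beyond the
single shared offset, and missingness mechanisms other than the ones the
pipeline's exclusion rules name. Passing recovery tests on this generator
shows the estimators work under the assumed data-generating model; it cannot
certify performance under violations of those assumptions.

## Null and calibration behaviour

Setting both loadings vectors to zero severs every path from z to the data,
so FA and sleep are conditionally independent given group and covariates;
tests verify that within-group cross-block correlations centre on zero and
that the omnibus permutation test rejects at the nominal rate (the
acceptance suite runs 500 null datasets at n = 60, p = 10, q = 4 with 1,000
permutations and requires the α = 0.05 rejection rate inside the exact
binomial 95% interval [0.033, 0.071]).

## Numerical choices

* p-value estimators use the +1 correction (never exactly zero).
* Residualization raises on columns whose residual SD falls below a relative
  floor (1e-12 of the block scale), naming the offending column.
* Bootstrap/permutation chunk sizes are chosen to bound temporary arrays at
  ≈ 8 MB; results are independent of chunking because each resample draws
  from its own counter position in a single seeded generator sequence.
* Default iteration counts are 10,000 (library), overridable to 100,000;
  the test suite and the bundled pipeline example run at 200–2,000, which
  keeps a full run on one core under two minutes while leaving the
  estimators unchanged.
* Seeds: every stochastic entry point takes a seed; nested procedures derive
  child streams via `SeedSequence.spawn`, so per-stage and per-subject
  randomness is independent of execution order.

## Known limitations

* The group-contrast PLS-C construction is one defensible choice among
  several; published analyses rarely specify theirs, and results may differ
  across constructions.
* The global-FA weighting ("weighted" average) is configurable but defaults
  to equal weights; with skeleton voxel counts available the weighted
  version should be preferred.
* Single-night actigraphy is inherently noisy; the pipeline treats the six
  sleep measures symmetrically and leaves any subjective-vs-objective
  weighting to the analyst.
* Bootstrap CIs are percentile intervals; no BCa correction is applied.
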