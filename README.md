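# uhrsleepwm

Analysis pipeline linking white-matter microstructure to sleep-wake
disturbance in a two-group (patient/control) cohort — built for studies of
individuals at ultra-high risk (UHR) for psychosis, but applicable to any
design with a 48-ROI fractional-anisotropy (FA) table, Karolinska-style
sleep questionnaires, wrist actigraphy and nuisance covariates.

The package implements, as tested reusable code:

* **Sleep indices** — Disturbed Sleep Index (DSI = sum of four items, 4–20)
  and Disturbed Awakening Index (AWI = sum of three items, 3–15) from the
  seven 1–5 questionnaire items, with listwise exclusion on missing items.
* **Actigraphy summaries** — Cole–Kripke 1-min weighted-sum sleep/wake
  scoring inside the diary-defined rest interval, then TST, WASO,
  SE = 100·TST/TIB, and SFI = MI + FI.
* **FA aggregation** — weighted global mean FA over the 48 JHU-atlas tracts
  and callosal FA = (genu + body + splenium)/3, with strict label validation.
* **Univariate statistics** — covariate-adjusted nested-model F-tests for
  group, partial Pearson correlations with percentile-bootstrap CIs,
  Benjamini–Hochberg FDR over each analysis family, and percentile-bootstrap
  simple mediation.
* **PLS correlation (PLS-C)** — the core multivariate method, exposed as a
  statsmodels-style model/results pair. For residualized, standardized
  blocks Xr (n×48) and Yr (n×6), the SVD of the cross-block correlation
  matrix

      R = Xrᵀ Yr / (n−1) = V Σ Uᵀ

  pairs X-saliences V with Y-saliences U; σ_k is each latent variable's
  cross-block covariance and σ_k²/Σσ_j² its covariance share. Inference:
  omnibus permutation test on the Inertia index Σσ_k, per-LV non-rotated
  permutation p-values, and Procrustes-aligned bootstrap 95% CIs per
  salience element (CI excluding zero ⇒ "reliable"). LVs with > 5%
  covariance share and p < 0.05 are flagged reportable.
* **Synthetic cohort generator** — a full data-generating model (group FA
  deficit, covariate effects, a planted latent dimension coupling sparse
  regional FA loadings to the six sleep measures, latent-Gaussian ordinal
  questionnaire items, a semi-Markov actigraphy bout process) used by the
  calibration, power and recovery test suites. See `docs/methods.md`.

## Worked example

```python
from uhrsleepwm import (PLSC, SyntheticCohortConfig, generate_cohort,
                        glm_group_test, partial_correlation, JHU_LABELS)
from uhrsleepwm.pipeline import BASE_COVARIATES, CohortData, build_analysis_table
from uhrsleepwm.synthetic import SLEEP_MEASURES

coh = generate_cohort(SyntheticCohortConfig(seed=7))   # 64 patients, 35 controls
merged, _ = build_analysis_table(
    CohortData(coh.covariates, coh.roi_fa, coh.responses, coh.actigraphy))
merged = merged.dropna(subset=list(SLEEP_MEASURES))

g = glm_group_test(merged["global_fa"],
                   (merged["group"] == "patient").astype(float),
                   merged[BASE_COVARIATES])
print(f"global FA group F = {g.f_stat:.2f}, p = {g.p_value:.4g}")

pat = merged[merged["group"] == "patient"]
pc = partial_correlation(pat["callosal_fa"], pat["waso"],
                         pat[BASE_COVARIATES], B=1000, seed=7)
print(f"UHR callosal FA ~ WASO partial r = {pc.r:.3f}, p = {pc.p_value:.3f}")

model = PLSC.from_dataframe(pat, x_cols=list(JHU_LABELS),
                            y_cols=list(SLEEP_MEASURES),
                            cov_cols=BASE_COVARIATES)
print(model.fit(n_perm=10000, n_boot=10000, seed=7).summary())
```

Output:

```
global FA group F = 28.29, p = 7.158e-07
UHR callosal FA ~ WASO partial r = -0.219, p = 0.093
PLS correlation results
================================================================
n subjects: 64   p (X): 48   q (Y): 6
Inertia (sum of singular values): 5.9933   omnibus permutation p = 0.0007999
----------------------------------------------------------------
 LV     sigma   % covar    perm p  report
  1    4.1891    95.15% 0.0007999     yes
  2    0.7120     2.75%    0.6265      no
  3    0.4459     1.08%    0.8986      no
  4    0.3697     0.74%     0.641      no
  5    0.2209     0.26%    0.9454      no
  6    0.0557     0.02%    0.7579      no
----------------------------------------------------------------
bootstrap: 10000 resamples, 95% CIs; 20/48 X-saliences reliable on LV1
```

Reading this: the simulated patients carry a planted latent dimension
coupling six tracts to worse sleep; the covariate-adjusted group F detects
the planted 0.013 FA deficit; the patient-only partial correlation between
callosal FA and wake-after-sleep-onset is negative (more wake, lower FA);
and the PLS-C finds one dominant latent variable (95% of the cross-block
covariance, permutation p ≈ 0.0008) whose reliable saliences include the six
planted tracts.

## Command line

```bash
uhrsleepwm simulate --seed 7 --out cohort/           # write synthetic dataset
uhrsleepwm sleep --ksq cohort/ksq.csv --acti cohort/actigraphy.csv \
                 --diary cohort/diary.csv --covariates cohort/covariates.csv \
                 --out sleep_summary.csv
uhrsleepwm fa --roi cohort/roi_fa.csv --out derived_fa.csv
uhrsleepwm run --config cfg.yaml                     # full pipeline + report
```

`uhrsleepwm run` executes simulate/load → sleep → FA → univariate → PLS-C
from one YAML config and writes `report.json`, `univariate_results.tsv`,
`plsc_result.json`, `salience_table.tsv` and `exclusions.tsv`; identical
config + seed reproduces every output byte-for-byte.

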