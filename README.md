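# prostamics

Longitudinal prostate multiparametric-MRI (mpMRI) radiomics, built as a
tested, reusable pipeline and exercised end-to-end on synthetic
digital-phantom cohorts.

## What problem this addresses

After definitive prostate radiotherapy, residual cancer can stay
clinically silent for years; a post-treatment biopsy at ~2 years is a
strong marker of eventual failure, but it is invasive. Quantitative
mpMRI features — the apparent diffusion coefficient (ADC, mm²/s) from
diffusion imaging and pharmacokinetic parameters from dynamic
contrast-enhanced (DCE) imaging — are candidate noninvasive biomarkers.
This package implements the full analysis chain that such a study
needs:

1. **ROI geometry** — from prostate, peripheral-zone (PZ), and gross
   tumor volume (GTV) masks, derive the five analysis regions: GTV, the
   5 mm peritumoral ring split into PZ/TZ parts (PT-PZ, PT-TZ), and
   normally-appearing tissue outside tumor and ring (NAT-PZ, NAT-TZ).
   The ring is a 3-D Euclidean shell in physical millimeters under
   anisotropic voxel spacing.
2. **Grid standardization** — resampling to 0.5 × 0.5 mm in-plane /
   3 mm slices and cropping to the prostate with 10-pixel in-plane
   padding.
3. **ADC features** — eleven first-order statistics per ROI
   (percentiles 10/25/50/75/90, mean, SD, skewness, excess kurtosis,
   min, max), named `ROI_ADC_Feature` (e.g. `GTV_ADC_90`).
4. **DCE pharmacokinetics** — the extended Tofts model fit to the
   ROI-averaged contrast-time curve using the Parker population
   arterial input function:

   C_t(t) = v_p·C_p(t−t₀) + K^trans ∫₀^{t−t₀} C_p(u)·e^{−k_ep(t−t₀−u)} du

   yielding K^trans (min⁻¹), k_ep (min⁻¹), v_e = K^trans/k_ep, v_p,
   plus model-free t_onset, AUC90, AUC120.
5. **Longitudinal statistics** — per-feature mean ± SD at each scan
   point (baseline S1 and three post-treatment scans S2–S4), percent
   changes, and two-tailed t-tests.
6. **Outcome modeling** — for each of ten comparisons (4 scan points +
   6 pairwise Δ-feature differences): univariate logistic screen
   (p < 0.05), Welch-t ranking with Pearson-|r| > 0.85 decorrelation,
   multivariate logistic regression, and leave-one-out ROC/AUC,
   confusion matrix, and F1.
7. **Synthetic cohorts** — a digital-phantom generator (ellipsoidal
   prostate, posterior-shell PZ, spherical tumors) with tissue-class
   distributions for ADC and PK parameters, longitudinal trajectory
   multipliers, and endpoint-biopsy labels drawn from a known logistic
   rule on baseline features, so every stage has recoverable truth.

## Worked example

```python
from prostamics import PipelineConfig, GridSpec, PhantomSpec, CohortSpec, run_pipeline

config = PipelineConfig(
    phantom=PhantomSpec(grid_shape=(32, 32, 8), spacing_mm=(2.0, 2.0, 3.0),
                        prostate_radius_mm=(22.0, 18.0, 11.0), gtv_radius_mm=6.0, seed=4),
    cohort=CohortSpec(n_patients=25, scan_points=("S1", "S2"), seed=4),
    grid=GridSpec(in_plane_mm=2.0, slice_mm=3.0, pad_px=2),
)
info = run_pipeline(config, "demo_run")
print(info["models"])
```

runs in a few seconds and prints (exact numbers depend only on the seed):

```
{'S1': {'auc': 0.915, 'f1': 0.6, 'selected_features': ['GTV_ADC_Max', 'NAT-PZ_DCE_tonset', 'GTV_DCE_ve']},
 'S2': {'auc': 0.9, 'f1': 0.4444444444444444, 'selected_features': ['GTV_ADC_10', 'NAT-PZ_ADC_Skew', 'NAT-PZ_ADC_SD', 'GTV_ADC_SD']},
 'S2-S1': {'auc': 0.77, 'f1': 0.6666666666666666, 'selected_features': ['GTV_ADC_SD_dS2S1', 'GTV_ADC_10_dS2S1', 'GTV_ADC_Min_dS2S1']}}
```

The labels of this 25-patient demo cohort were generated from baseline
GTV ADC and GTV v_e; the baseline (S1) model recovers both (a GTV ADC
percentile proxy plus `GTV_DCE_ve` itself) and separates positive from
negative endpoint biopsies with leave-one-out AUC 0.92. The
longitudinal report for `GTV_ADC_Mean` in the same run reads

```
     feature scan_point  n        mean         sd  pct_change_vs_baseline  p_vs_baseline
GTV_ADC_Mean         S1 25 1145.787750 211.761737                     NaN            NaN
GTV_ADC_Mean         S2 25 1325.615153 246.730230               15.694652       0.008046
```

recovering the generator's +15.7% post-treatment rise in tumor ADC.
The run directory holds `features_wide.csv`
(one row per patient-scan), `longitudinal_report.csv` (mean ± SD,
percent changes and p-values per feature and scan), and one
`model_*.json` per comparison with coefficients, held-out
probabilities, ROC points, confusion matrix, and flags.

The same stages are available as subcommands of the `prostamics` CLI:
`synth`, `rois`, `features`, `report`, `fit-outcome`, `run-all`,
`write-config`.

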