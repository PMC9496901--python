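# Methods

This note documents the models, numerical choices, and design decisions
behind `prostamics`, and what the synthetic-data studies do and do not
demonstrate about real data.

## ROI geometry

The five analysis regions are pure mask algebra on one common grid:

* **TZ** = prostate − PZ. Up to 1% of PZ voxels may fall outside the
  prostate (resampling slivers) and are clipped; beyond that tolerance
  the inputs are rejected as inconsistent. The tolerance is a
  parameter of `derive_tz` / `derive_rois`.
* **Peritumoral ring** = all non-tumor voxels whose center lies within
  5 mm (Euclidean, physical millimeters, anisotropic spacing) of a
  tumor voxel center, computed with an exact Euclidean distance
  transform. The ring is built in 3-D rather than slice-by-slice: a
  "5 mm thickness" is a physical quantity, and with 3 mm slices a 2-D
  ring would under-reach axially. The ring is clipped to the prostate,
  since features are only computed inside prostate tissue; both
  choices are explicit parameters. Multifocal tumors are merged by
  voxelwise union before the ring is built, so overlapping per-lesion
  shells are not double counted.
* **PT-PZ / PT-TZ** = ring ∩ zone; **NAT-PZ / NAT-TZ** = zone − (ring ∪
  tumor). The `RoiSet.validate` method asserts the full invariant set
  (rings exclude the tumor, ring parts partition the clipped ring,
  normal tissue excludes tumor and ring, everything inside the
  prostate) and is run on every pipeline output.

The ring operation is verified against a brute-force per-voxel distance
scan on grids up to 64 voxels per axis, including anisotropic spacings.

## Grid standardization

Volumes are resampled to 0.5 × 0.5 mm in-plane / 3.0 mm slices by
default. Images use linear interpolation — a deliberate choice for
quantitative maps (ADC, concentration), which must not overshoot the
data range as higher-order splines can; the interpolation order is not
configurable below the API but the grid is. Masks use nearest-neighbor
so binarity is preserved; resampling of smooth shapes changes total
mask volume by < 5% (tested). Cropping pads the prostate bounding box
by 10 pixels in-plane only; the slice direction is cropped to the
prostate extent with no pad. The crop returns its index offset so all
coordinates map back to the original grid.

## DCE pharmacokinetics

**Model.** Extended Tofts on the ROI-averaged contrast-time curve:
C_t(t) = v_p·C_p(t−t₀) + K^trans ∫ C_p(u) e^{−k_ep(t−t₀−u)} du, zero
before the wash-in time t₀. Fitting the ROI-mean curve (not voxelwise
maps) is both the intended use and the robust choice at the low
temporal resolution the pipeline targets (6 s frames, 300 s duration).

**Units and scaling.** Curves are treated as proportional to
gadolinium concentration (mM); no signal-equation / T1 conversion is
modeled, so absolute K^trans units track the input scaling. All
recovery studies use self-consistent synthetic curves in mM. Rates are
in min⁻¹, times in seconds; conversions happen inside the forward
model.

**AIF.** The Parker population-average functional form — two Gaussians
plus a sigmoid-gated exponential recirculation tail — with the
published population constants as defaults, all exposed in the config.
Time constants are in minutes internally; the curve is evaluated at
times given in seconds.

**Quadrature.** The convolution is evaluated on an internal uniform
fine grid (0.5 s default) with the exact update for piecewise-linear
C_p, implemented as a linear IIR filter (C speed). The plasma term is
evaluated analytically at the frame times when the AIF is functional.
Halving the fine step changes the forward curve by far less than
0.25% (tested); errors against closed forms (boxcar AIF) are < 0.5%.

**Fitting.** Deterministic three-stage strategy: (1) the wash-in frame
is detected from the curve (below) to bracket t₀; (2) k_ep is profiled
over a 25-point log grid from 0.05 to 5 min⁻¹, with the two linear
amplitudes (v_p, K^trans) solved by non-negative least squares at each
grid point — this global, multi-start-equivalent stage cannot be
trapped by a bad initialization of the nonlinear parameters; (3) a
bounded trust-region least-squares polish over all four parameters.
k_ep is the fitted parameter and v_e = K^trans/k_ep is derived, so the
identity holds for every returned fit by construction; if the
unconstrained optimum implies v_e > 1 the model is refit in a
(v_e, k_ep) parameterization with v_e ≤ 1. v_p is bounded at 0.3
(plasma fractions above that are not physiologic in prostate).
Non-convergence is reported via a flag and the residual sum of squares,
never silently. Noise-free round trips over the physiologic grid
(K^trans 0.08–0.14, k_ep 0.16–0.49 min⁻¹) recover parameters to ~1e-11
relative error; at 1% noise the median error is well under 10%.

**Semi-quantitative features.** t_onset is the first time the curve
exceeds baseline mean + 3 SD for 2 consecutive frames (both constants
config-exposed; the baseline is the pre-bolus frames). AUC90/AUC120
are trapezoid integrals over the 90/120 s window anchored at onset,
baseline-subtracted; both behaviors are flags. If no onset is detected
— or a spurious late crossing leaves no 120 s window — the windows are
anchored at t = 0 and the result is flagged rather than failing.

## ADC features

Eleven first-order statistics per ROI: percentiles 10/25/50/75/90
(linear interpolation between closest ranks), mean, SD, skewness,
excess kurtosis (normal = 0), and min/max, each individually
switchable. Skewness and kurtosis of a constant sample are undefined
and emitted as missing, not zero. ROIs below a voxel-count floor
(default 10) yield missing features with a log entry instead of an
exception, so small ring fragments degrade gracefully.

## Longitudinal statistics

Percent changes are computed on scan means relative to baseline and to
the previous scan, sign retained. Change tests default to unpaired
two-sample t-tests because per-scan sample sizes differ under
attrition; paired and Welch variants are available. No
multiple-testing correction is applied in the descriptive report (raw
p-values are what the report shows); a Benjamini–Hochberg option
exists and is off by default.

## Outcome modeling

Ten comparisons per cohort: features at S1–S4 and the six pairwise
differences, each difference restricted to patients present at both
scans. The selection procedure is exactly: univariate logistic
likelihood-ratio screen at p < 0.05; ranking of survivors by ascending
Welch-t p-value (ties broken lexicographically); greedy decorrelation
dropping remaining features with |Pearson r| > 0.85 against each pick;
stop at `max_k` (default 4). Complete separation in the screen is
detected (runaway standardized coefficients or iteration cap) and
flagged; the capped likelihood still yields a usable LRT p-value.

Leave-one-out evaluation defaults to **flat** mode: selection is done
once on the full cohort and each fold refits only the coefficients.
This mirrors the procedure the pipeline emulates and is optimistically
biased — the held-out AUC partially reuses information through the
selection. A fully **nested** mode (selection redone in every fold) is
provided for honest error estimation. Logistic fits are unpenalized
maximum likelihood on training-standardized features with an iteration
cap; separation saturates the probabilities and raises a flag, it is
not shrunk away. The classification threshold for the confusion
matrix and F1 is 0.5 and configurable.

A known property worth stating: leave-one-out AUC under the null
(labels independent of features) is pessimistically biased *below* 0.5
at small n, because each fold's overfit model is anti-correlated with
its held-out case. At n = 200 the permutation null sits at ≈ 0.5; at
n = 25 it sits visibly below. The label-permutation control in the
validation studies therefore checks that permutation *destroys*
performance (mean permuted AUC far below the informative value), and
the unbiased ≈ 0.5 calibration is demonstrated at n = 200.

## Synthetic cohorts

The phantom is schematic by design: an ellipsoidal prostate, a
posterior shell as the PZ (35% of prostate volume by default),
spherical tumors placed inside the gland — predominantly in the PZ,
where most prostate cancers arise — and uniform tissue classes. The
analysis depends only on mask topology and intensity statistics, so
anatomical realism is out of scope (no T2 contrast, bias fields,
motion, or organ deformation).

Each tissue class (GTV, normal PZ, normal TZ) carries a population
(mean, SD) for ADC and for (K^trans, v_e, v_p); k_ep is derived as
K^trans/v_e. A patient draws one class-level value per parameter
(between-patient variation); voxels add independent Gaussian noise
(within-patient variation; ADC truncated at zero). Baseline anchors:
tumor ADC ≈ 1178 ± 217 (lowest, reflecting tumor cellularity), normal
PZ ≈ 1616 ± 304 (highest, glandular fluid), normal TZ ≈ 1382 ± 170;
tumor K^trans 0.12 ± 0.05 min⁻¹ with v_e 0.26 ± 0.08, normal PZ
K^trans 0.08 (low, intact gland basement membranes), normal TZ v_e
0.34. The DCE series is synthesized voxelwise from the extended Tofts
forward model in concentration units with a 15 s bolus arrival, 6 s
frames, 300 s duration (≥ 150 s is enforced so AUC120 is computable).

Longitudinal change is a deterministic per-scan multiplier on each
patient's baseline values, configurable per class and parameter. The
defaults encode the expected post-radiotherapy response — tumor ADC
rises (+15.7% at the first post-treatment scan, +25.2% at the second),
normal-tissue ADC dips (−11.2% PZ, −5.6% TZ), tumor k_ep falls
progressively, v_e rises in all compartments — via per-scan class-mean
anchors from which the multipliers are derived.

Endpoint-biopsy labels are Bernoulli draws from a logistic rule on
standardized baseline class-level truth. The default weights are −5 on
GTV ADC mean and +4 on GTV v_e with the intercept solved (bisection)
so the expected prevalence is 0.2, emulating a ~5/25-positive cohort;
the weights are strong because the generator's stated purpose is to
provide recoverable signal at n = 25 — with weak coupling the
Bernoulli label noise alone caps the achievable AUC below a usable
validation target. One global seed expands into per-patient
substreams (`SeedSequence.spawn`), so cohorts are reproducible
patient-by-patient and bit-identical under a fixed seed.

**What the studies show — and don't.** Passing the recovery studies
shows the pipeline's arithmetic, geometry, fitting, and selection
machinery are correct and unbiased on data that satisfy the model
assumptions exactly (homogeneous tissue classes, known AIF, Gaussian
noise, no registration error). They say nothing about scanner effects,
AIF mismatch, partial-volume contamination, or contouring variability
in real cohorts.

## Problem sizes in the validation studies

The simulation studies run on a compact configuration chosen to keep
the full validation reproducible on one CPU: 32 × 32 × 8 phantoms at
2 × 2 × 3 mm kept as the analysis grid, 25-patient single-scan
cohorts, 50 seeded replicates for the recovery study, 100 replicates
for the noisy Tofts round trip, and 2000 replicates for the t-test
null calibration. The statistical structure (tissue distributions,
label rule, prevalence) is identical to the full-scale defaults; only
the grid and scan count are reduced.

## Known limitations

* Flat-mode LOO AUC is optimistically biased (see above); nested mode
  is the honest estimate and is not the default only for fidelity to
  the emulated procedure.
* The univariate screen and the Welch ranking use two different
  statistics; this is implemented as specified by the emulated
  procedure, not because it is statistically optimal.
* Absolute K^trans/v_p units depend on the input curve scaling (no T1
  conversion); comparisons across cohorts require consistent scaling.
* The generator's longitudinal multipliers act on class means only;
  within-class spatial heterogeneity and scan-to-scan contour changes
  are not simulated.
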