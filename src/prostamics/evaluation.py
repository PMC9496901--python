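"""Self-validation studies: recovery, calibration, and oracle checks.

These routines exercise the package end-to-end on synthetic inputs with
known generating truth and report quantitative outcomes: percent-change
arithmetic on the longitudinal anchor means, F1 consistency of the
confusion-matrix formula, Tofts forward/fit round trips, a brute-force
oracle for the peritumoral ring, a hand-traceable run of the feature
selection rule, end-to-end label-signal recovery with leave-one-out
AUC, and the null calibration of the two-sample t-test.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dce import ContrastCurve, ParkerAif, ToftsParams, fit_tofts, tofts_forward
from .model import confusion_and_f1, fit_and_evaluate_loo, select_features
from .pipeline import cohort_feature_table
from .preprocess import GridSpec
from .roi import peritumoral_ring
from .stats import percent_change
from .synthetic import (
    DEFAULT_CLASS_MEANS,
    CohortSpec,
    LabelModel,
    PhantomSpec,
    generate_cohort,
)

__all__ = [
    "anchor_percent_changes",
    "f1_consistency",
    "tofts_recovery",
    "brute_force_ring",
    "ring_oracle_mismatch",
    "selection_trace",
    "small_study_config",
    "label_recovery_study",
    "ttest_null_calibration",
]


# --------------------------------------------------------------------------
# Percent-change arithmetic on the longitudinal anchor means
# --------------------------------------------------------------------------

def anchor_percent_changes() -> dict[str, float]:
    """Percent changes of the generator's per-scan ADC population means."""
    adc = {cls: DEFAULT_CLASS_MEANS[cls]["adc"] for cls in ("GTV", "PZ", "TZ")}
    return {
        "gtv_adc_s1_to_s2": percent_change(adc["GTV"][0], adc["GTV"][1]),
        "gtv_adc_s1_to_s3": percent_change(adc["GTV"][0], adc["GTV"][2]),
        "gtv_adc_s2_to_s3": percent_change(adc["GTV"][1], adc["GTV"][2]),
        "natpz_adc_s1_to_s2": percent_change(adc["PZ"][0], adc["PZ"][1]),
        "nattz_adc_s1_to_s2": percent_change(adc["TZ"][0], adc["TZ"][1]),
    }


# --------------------------------------------------------------------------
# F1 formula consistency
# --------------------------------------------------------------------------

def f1_consistency() -> dict[str, float]:
    """F1 from held-out probabilities realizing two reference confusion matrices.

    Both cases have 4 true positives and no false negatives; they differ
    in the number of false positives (2 vs 3) among 20 negatives.
    """
    out = {}
    for fp, key in ((2, "f1_tp4_fp2"), (3, "f1_tp4_fp3")):
        y = np.array([1] * 4 + [0] * 20)
        probs = np.array([0.9] * 4 + [0.9] * fp + [0.1] * (20 - fp))
        confusion, f1 = confusion_and_f1(probs, y, 0.5)
        assert confusion[1, 1] == 4 and confusion[0, 1] == fp and confusion[1, 0] == 0
        out[key] = f1
    return out


# --------------------------------------------------------------------------
# Tofts round trip
# --------------------------------------------------------------------------

def _forward_curve(theta: ToftsParams, t: np.ndarray, aif: ParkerAif) -> ContrastCurve:
    return ContrastCurve(t=t, c=tofts_forward(theta, aif, t), n_baseline=3)


def tofts_recovery(
    *,
    noise_frac: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    ktrans_grid=(0.08, 0.11, 0.14),
    kep_grid=(0.16, 0.30, 0.49),
    vp_grid=(0.01, 0.03),
) -> dict[str, float]:
    """Forward-simulate, fit, and report relative recovery errors.

    Noise-free: the maximum relative error over the parameter grid.
    Noisy: per replicate, a random grid point is simulated with
    ``noise_frac`` of the curve peak as Gaussian noise SD; the median
    relative error over replicates is reported per parameter.
    """
    aif = ParkerAif()
    t = np.arange(0.0, 300.1, 6.0)
    rng = np.random.default_rng(seed)
    thetas = [
        ToftsParams(ktrans=kt, kep=kep, vp=vp, t_onset=15.0)
        for kt, kep, vp in itertools.product(ktrans_grid, kep_grid, vp_grid)
        if kt / kep <= 1.0
    ]
    errs = {"ktrans": [], "kep": [], "ve": []}
    for rep in range(max(n_replicates, 1)):
        for theta in (thetas if n_replicates == 1 else [thetas[rng.integers(len(thetas))]]):
            c = tofts_forward(theta, aif, t)
            if noise_frac > 0:
                c = c + rng.normal(0.0, noise_frac * c.max(), size=c.shape)
            fit = fit_tofts(ContrastCurve(t=t, c=c, n_baseline=3), aif)
            errs["ktrans"].append(abs(fit.ktrans - theta.ktrans) / theta.ktrans)
            errs["kep"].append(abs(fit.kep - theta.kep) / theta.kep)
            errs["ve"].append(abs(fit.ve - theta.ve) / theta.ve)
    stat = np.max if noise_frac == 0 else np.median
    return {
        f"rel_err_{k}_pct": float(stat(v) * 100.0) for k, v in errs.items()
    } | {"n_fits": len(errs["ktrans"])}


# --------------------------------------------------------------------------
# Ring oracle
# --------------------------------------------------------------------------

def brute_force_ring(
    gtv: np.ndarray, spacing: tuple[float, float, float], thickness_mm: float
) -> np.ndarray:
    """O(N * |GTV|) reference: per-voxel minimum distance scan."""
    gtv = gtv.astype(bool)
    pts = np.argwhere(gtv) * np.asarray(spacing)
    out = np.zeros_like(gtv)
    for idx in np.argwhere(~gtv):
        d2 = ((pts - idx * np.asarray(spacing)) ** 2).sum(axis=1)
        if d2.min() <= thickness_mm**2 + 1e-12:
            out[tuple(idx)] = True
    return out


def ring_oracle_mismatch(seed: int = 0) -> dict[str, float]:
    """Mismatched voxels between the ring operation and the brute-force scan."""
    rng = np.random.default_rng(seed)
    total_mismatch = 0
    total_checked = 0
    cases = [
        ((16, 16, 8), (1.0, 1.0, 1.0), 5.0),
        ((20, 20, 8), (2.0, 2.0, 3.0), 5.0),
        ((12, 18, 10), (1.5, 0.8, 2.5), 4.0),
    ]
    for shape, spacing, thickness in cases:
        gtv = np.zeros(shape, dtype=bool)
        n_seeds = int(rng.integers(1, 4))
        for _ in range(n_seeds):
            center = [int(rng.integers(2, s - 2)) for s in shape]
            gtv[tuple(center)] = True
        fast = peritumoral_ring(gtv, spacing, thickness)
        slow = brute_force_ring(gtv, spacing, thickness)
        total_mismatch += int((fast != slow).sum())
        total_checked += int(np.prod(shape))
    return {"mismatch_voxels": total_mismatch, "voxels_checked": total_checked}


# --------------------------------------------------------------------------
# Selection hand trace
# --------------------------------------------------------------------------

def selection_trace(seed: int = 7) -> dict[str, object]:
    """Three-feature greedy-selection scenario with a known answer.

    A is the strongest feature; B is redundant with A (|r| > 0.85); C is
    weaker but independent.  The documented rule must return [A, C].
    """
    rng = np.random.default_rng(seed)
    n = 60
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    a = y * 2.0 + rng.normal(0, 0.6, n)
    b = a + rng.normal(0, 0.25, n)          # highly correlated copy of A
    c = y * 1.0 + rng.normal(0, 1.0, n)     # weaker, independent signal
    X = pd.DataFrame({"A": a, "B": b, "C": c})
    r_ab = float(np.corrcoef(a, b)[0, 1])
    r_ac = float(np.corrcoef(a, c)[0, 1])
    assert r_ab > 0.85 and abs(r_ac) < 0.85, "scenario preconditions violated"
    selected = select_features(X, pd.Series(y), p_pass=0.05, r_max=0.85, max_k=0)
    return {"selected": selected, "r_ab": r_ab, "r_ac": r_ac,
            "matches_expected": float(selected == ["A", "C"])}


# --------------------------------------------------------------------------
# End-to-end label recovery
# --------------------------------------------------------------------------

def small_study_config(seed: int = 0, scan_points=("S1",)) -> PipelineConfig:
    """A compact cohort configuration for simulation studies.

    The phantom keeps its native 2 x 2 x 3 mm grid as the analysis grid
    so the geometry and feature stages run at simulation scale; all
    statistical structure (tissue distributions, label model, scan
    design) is unchanged.
    """
    phantom = PhantomSpec(
        grid_shape=(32, 32, 8),
        spacing_mm=(2.0, 2.0, 3.0),
        prostate_radius_mm=(22.0, 18.0, 11.0),
        gtv_radius_mm=6.0,
        seed=seed,
    )
    cohort = CohortSpec(n_patients=25, scan_points=tuple(scan_points), seed=seed)
    grid = GridSpec(in_plane_mm=2.0, slice_mm=3.0, pad_px=2)
    return PipelineConfig(phantom=phantom, cohort=cohort, grid=grid)


def label_recovery_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_permutations: int = 20,
) -> dict[str, float]:
    """End-to-end signal recovery across seeded cohort replicates.

    Labels are generated from standardized baseline GTV ADC mean
    (negative weight) and GTV ve (positive weight).  Per replicate the
    full pipeline runs on a fresh 25-patient cohort; reported are the
    median flat-LOO AUC, the fraction of replicates in which each
    generating feature (or a proxy with |r| > 0.85 to it) is selected,
    and the mean LOO AUC after label permutation (selection held fixed).
    """
    gen_features = ("GTV_ADC_Mean", "GTV_DCE_ve")
    aucs, hits_any, hits_all = [], [], []
    per_feature_hits = {gf: [] for gf in gen_features}
    perm_aucs: list[float] = []
    rng = np.random.default_rng(base_seed + 10_000)
    for k in range(n_seeds):
        seed = base_seed + k
        config = small_study_config(seed=seed)
        cohort = generate_cohort(config.cohort, config.phantom, aif=config.aif)
        table = cohort_feature_table(cohort, config)
        X = table.xs("S1", level="scan_point").dropna(axis=1, how="any")
        y = cohort.labels.loc[X.index]
        selected = select_features(X, y, max_k=config.max_k)
        if selected:
            result = fit_and_evaluate_loo(X[selected], y, comparison="S1")
            aucs.append(result.auc)
        else:
            aucs.append(0.5)
        found = {
            gf: any(
                sel == gf or abs(float(X[sel].corr(X[gf]))) > 0.85
                for sel in selected
            )
            for gf in gen_features
        }
        for gf in gen_features:
            per_feature_hits[gf].append(float(found[gf]))
        hits_any.append(float(any(found.values())))
        hits_all.append(float(all(found.values())))
        if k == 0 and selected:
            for _ in range(n_permutations):
                y_perm = pd.Series(
                    rng.permutation(y.to_numpy()), index=y.index
                )
                if 0 < y_perm.sum() < len(y_perm):
                    perm_aucs.append(
                        fit_and_evaluate_loo(X[selected], y_perm).auc
                    )
    return {
        "median_loo_auc": float(np.median(aucs)),
        "selection_hit_rate_any_pct": float(np.mean(hits_any) * 100.0),
        "selection_hit_rate_both_pct": float(np.mean(hits_all) * 100.0),
        "adc_feature_hit_rate_pct": float(np.mean(per_feature_hits["GTV_ADC_Mean"]) * 100.0),
        "ve_feature_hit_rate_pct": float(np.mean(per_feature_hits["GTV_DCE_ve"]) * 100.0),
        "permuted_mean_auc": float(np.mean(perm_aucs)) if perm_aucs else float("nan"),
        "n_seeds": n_seeds,
    }


# --------------------------------------------------------------------------
# Null calibration of the two-sample t-test
# --------------------------------------------------------------------------

def ttest_null_calibration(
    n_replicates: int = 2000, n_per_group: int = 25, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Type-I error rate of the two-tailed t-test under identical distributions."""
    from .stats import compare_groups

    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_replicates, n_per_group))
    b = rng.normal(size=(n_replicates, n_per_group))
    rejections = sum(
        compare_groups(a[i], b[i]).p < alpha for i in range(n_replicates)
    )
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
    }
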