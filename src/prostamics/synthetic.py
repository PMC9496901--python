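"""Synthetic longitudinal cohort: digital prostate phantoms with known truth.

The phantom is schematic by design — an ellipsoidal prostate with a
posterior shell as the peripheral zone (PZ), the remainder as the
transition zone (TZ), and spherical tumors (GTV) placed inside the
gland, predominantly in the PZ where most prostate lesions arise.  The
downstream analysis depends only on mask topology and intensity
statistics, not anatomical realism.

Each tissue class carries a population distribution of ADC and of the
pharmacokinetic parameters (Ktrans, ve, vp).  A patient draws one
class-level value per parameter (between-patient variation); voxels add
independent Gaussian noise around it (within-patient variation).  The
dynamic contrast series is synthesized voxelwise from the extended
Tofts forward model in concentration units (mM) — no signal-equation /
T1 conversion is modeled.  Longitudinal change is a deterministic
per-scan multiplier on each patient's baseline parameter values, with
defaults that emulate the expected post-radiotherapy response: tumor
ADC rises while normal-tissue ADC dips, tumor reflux rate (kep) falls,
and ve rises in all compartments.

Endpoint-biopsy labels are drawn from a Bernoulli-logistic rule on
standardized baseline class-level features, so the outcome-modeling
stage has known, recoverable signal.

One global seed expands into independent per-patient substreams via
``numpy.random.SeedSequence.spawn``, so cohorts are reproducible
patient-by-patient.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageVolume
from .dce import ParkerAif, ToftsParams, tofts_forward

logger = logging.getLogger(__name__)

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "LabelModel",
    "CohortSpec",
    "Phantom",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
    "SCAN_POINTS",
    "DEFAULT_TISSUE_PARAMS",
    "DEFAULT_CLASS_MEANS",
]

SCAN_POINTS = ("S1", "S2", "S3", "S4")

# Per-class population means at each scan point (baseline, 3, 9, 24 months
# post-RT) used both as generator anchors and to derive the default
# longitudinal multipliers.  ADC in 1e-6 mm^2/s, Ktrans in min^-1, ve as a
# fraction.  kep is derived as Ktrans / ve throughout.
DEFAULT_CLASS_MEANS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "GTV": {
        "adc": (1177.84, 1362.45, 1474.76, 1388.68),
        "ktrans": (0.12, 0.12, 0.11, 0.09),
        "ve": (0.2554, 0.5880, 0.4637, 0.6658),
    },
    "PZ": {
        "adc": (1616.37, 1435.44, 1493.89, 1445.18),
        "ktrans": (0.08, 0.13, 0.09, 0.10),
        "ve": (0.2282, 0.5513, 0.6634, 0.6515),
    },
    "TZ": {
        "adc": (1381.76, 1303.92, 1357.37, 1361.00),
        "ktrans": (0.12, 0.14, 0.09, 0.12),
        "ve": (0.3355, 0.5266, 0.4662, 0.5930),
    },
}


@dataclass
class TissueClass:
    """Population (mean, SD) per parameter for one tissue class.

    The SDs are between-patient; within-patient voxel noise is governed
    separately by ``PhantomSpec.noise_sd_adc`` / ``noise_sd_dce``.
    """

    adc: tuple[float, float]
    ktrans: tuple[float, float]
    ve: tuple[float, float]
    vp: tuple[float, float] = (0.02, 0.01)


DEFAULT_TISSUE_PARAMS: dict[str, TissueClass] = {
    "GTV": TissueClass(adc=(1177.84, 217.12), ktrans=(0.12, 0.05), ve=(0.2554, 0.0821)),
    "PZ": TissueClass(adc=(1616.37, 304.02), ktrans=(0.08, 0.05), ve=(0.2282, 0.1112)),
    "TZ": TissueClass(adc=(1381.76, 170.34), ktrans=(0.12, 0.06), ve=(0.3355, 0.1273)),
}


def default_trajectories() -> dict[str, dict[str, tuple[float, ...]]]:
    """Per-class, per-parameter multipliers for S1..S4 relative to baseline."""
    out: dict[str, dict[str, tuple[float, ...]]] = {}
    for cls, params in DEFAULT_CLASS_MEANS.items():
        out[cls] = {
            p: tuple(v / means[0] for v in means) for p, means in params.items()
        }
    return out


@dataclass
class PhantomSpec:
    """Geometry, tissue statistics, and acquisition layout of one phantom."""

    grid_shape: tuple[int, int, int] = (40, 40, 10)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    prostate_radius_mm: tuple[float, float, float] = (24.0, 20.0, 13.0)
    pz_fraction: float = 0.35
    n_gtv: int = 1
    gtv_radius_mm: float = 7.0
    tissue_params: dict[str, TissueClass] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PARAMS)
    )
    noise_sd_adc: float = 40.0     # voxel noise, same units as ADC
    noise_sd_dce: float = 0.03     # voxel noise on concentration, mM
    dce_dt_s: float = 6.0
    dce_duration_s: float = 300.0
    dce_onset_s: float = 15.0
    background_adc: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm) or any(r <= 0 for r in self.prostate_radius_mm):
            raise ValueError("spacings and radii must be strictly positive")
        if not 0.0 < self.pz_fraction < 1.0:
            raise ValueError("pz_fraction must be in (0, 1)")
        if self.n_gtv not in (1, 2, 3):
            raise ValueError("n_gtv must be 1, 2, or 3")
        if self.gtv_radius_mm <= 0:
            raise ValueError("gtv_radius_mm must be strictly positive")
        if self.dce_duration_s < 150.0:
            raise ValueError("dce_duration_s must be >= 150 s so AUC120 is computable")
        if self.noise_sd_adc < 0 or self.noise_sd_dce < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def dce_times(self) -> np.ndarray:
        return np.arange(0.0, self.dce_duration_s + self.dce_dt_s / 2, self.dce_dt_s)


@dataclass
class LabelModel:
    """Logistic rule linking standardized baseline features to biopsy labels.

    Coefficients apply to class-level baseline truth, standardized by the
    generating population (mean, SD); supported feature names are the
    ``{GTV,NAT-PZ,NAT-TZ}_{ADC_Mean, DCE_Ktrans, DCE_kep, DCE_ve}`` grid.
    """

    intercept: float = -1.5
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"GTV_ADC_Mean": -5.0, "GTV_DCE_ve": 4.0}
    )


@dataclass
class CohortSpec:
    """Cohort layout: patients, scan points, outcome model, attrition."""

    n_patients: int = 25
    scan_points: tuple[str, ...] = SCAN_POINTS
    label_model: LabelModel = field(default_factory=LabelModel)
    positive_fraction_target: float | None = 0.2
    trajectories: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=default_trajectories
    )
    n_present: dict[str, int] | None = None  # patients retained per scan point
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 6:
            raise ValueError("need >= 6 patients so LOO folds keep both classes")
        unknown = set(self.scan_points) - set(SCAN_POINTS)
        if unknown:
            raise ValueError(f"unknown scan points: {sorted(unknown)}")


@dataclass
class Phantom:
    """One patient-scan volume set plus its generating truth."""

    adc: ImageVolume
    dce: ImageVolume
    masks: dict[str, np.ndarray]      # prostate, pz, gtv (+ gtv_1..n)
    class_map: dict[str, np.ndarray]  # GTV / PZ / TZ voxel masks
    truth: dict[str, dict[str, float]]


@dataclass
class Cohort:
    patients: list[dict]          # {patient_id, masks, class_map, scans: {sp: Phantom}}
    labels: pd.Series             # patient_id -> 0/1
    truth: dict                   # generating parameters per patient per scan


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def _voxel_centers(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def _build_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Masks for prostate, PZ, and the GTV spheres."""
    X, Y, Z = _voxel_centers(spec)
    cx = spec.grid_shape[0] * spec.spacing_mm[0] / 2
    cy = spec.grid_shape[1] * spec.spacing_mm[1] / 2
    cz = spec.grid_shape[2] * spec.spacing_mm[2] / 2
    rx, ry, rz = spec.prostate_radius_mm
    prostate = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0
    if not prostate.any():
        raise ValueError("prostate ellipsoid does not intersect the grid")
    # posterior (+y) shell of the prostate is the PZ
    y_thresh = np.quantile(Y[prostate], 1.0 - spec.pz_fraction)
    pz = prostate & (Y >= y_thresh)

    gtvs: list[np.ndarray] = []
    r = spec.gtv_radius_mm
    for i in range(spec.n_gtv):
        zone = pz if i < 2 else (prostate & ~pz)  # lesions 1-2 in PZ, lesion 3 in TZ
        # candidate centers: zone voxels whose sphere fits inside the prostate
        cand = np.argwhere(zone)
        order = rng.permutation(len(cand))
        placed = None
        for j in order:
            ix, iy, iz = cand[j]
            px, py, pzc = X[ix, iy, iz], Y[ix, iy, iz], Z[ix, iy, iz]
            sphere = (X - px) ** 2 + (Y - py) ** 2 + (Z - pzc) ** 2 <= r**2
            if not sphere.any():
                continue
            if np.any(sphere & ~prostate):
                continue
            if any(np.any(sphere & g) for g in gtvs):
                continue
            placed = sphere
            break
        if placed is None:
            raise ValueError(
                f"GTV lesion {i + 1} of radius {r} mm cannot be placed inside the prostate"
            )
        gtvs.append(placed)
    gtv = np.zeros_like(prostate)
    for g in gtvs:
        gtv |= g
    masks = {"prostate": prostate, "pz": pz, "gtv": gtv}
    for i, g in enumerate(gtvs, 1):
        masks[f"gtv_{i}"] = g
    class_map = {
        "GTV": gtv,
        "PZ": pz & ~gtv,
        "TZ": prostate & ~pz & ~gtv,
    }
    return masks, class_map


# --------------------------------------------------------------------------
# Parameter draws and volume synthesis
# --------------------------------------------------------------------------

def _draw_patient_params(
    tissue_params: dict[str, TissueClass], rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """One class-level baseline value per parameter per tissue class."""
    out: dict[str, dict[str, float]] = {}
    for cls, tp in tissue_params.items():
        out[cls] = {
            "adc": max(float(rng.normal(*tp.adc)), 1e-6),
            "ktrans": float(np.clip(rng.normal(*tp.ktrans), 0.005, 2.0)),
            "ve": float(np.clip(rng.normal(*tp.ve), 0.02, 0.95)),
            "vp": float(np.clip(rng.normal(*tp.vp), 0.001, 0.1)),
        }
    return out


def _scale_params(
    base: dict[str, dict[str, float]],
    trajectories: dict[str, dict[str, tuple[float, ...]]],
    scan_index: int,
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for cls, params in base.items():
        mult = trajectories.get(cls, {})
        out[cls] = {
            p: float(np.clip(v * mult.get(p, (1.0,) * 4)[scan_index], 1e-6, None))
            if p != "ve"
            else float(np.clip(v * mult.get(p, (1.0,) * 4)[scan_index], 0.01, 0.95))
            for p, v in params.items()
        }
    return out


def _synthesize_volumes(
    spec: PhantomSpec,
    class_map: dict[str, np.ndarray],
    params: dict[str, dict[str, float]],
    rng: np.random.Generator,
    aif: ParkerAif,
) -> tuple[ImageVolume, ImageVolume]:
    """ADC map and DCE series for one scan, given class-level parameters."""
    t = spec.dce_times
    adc = np.full(spec.grid_shape, spec.background_adc, dtype=float)
    dce = np.zeros(spec.grid_shape + (len(t),), dtype=np.float32)
    for cls, mask in class_map.items():
        p = params[cls]
        adc[mask] = p["adc"]
        tofts = ToftsParams(
            ktrans=p["ktrans"], kep=p["ktrans"] / p["ve"], vp=p["vp"],
            t_onset=spec.dce_onset_s,
        )
        curve = tofts_forward(tofts, aif, t)
        dce[mask] = curve.astype(np.float32)
    if spec.noise_sd_adc > 0:
        adc += rng.normal(0.0, spec.noise_sd_adc, size=adc.shape)
        np.maximum(adc, 0.0, out=adc)
    if spec.noise_sd_dce > 0:
        dce += rng.normal(0.0, spec.noise_sd_dce, size=dce.shape).astype(np.float32)
    return (
        ImageVolume(adc, spec.spacing_mm),
        ImageVolume(dce, spec.spacing_mm, times=t),
    )


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None, aif: ParkerAif | None = None
) -> Phantom:
    """One single-scan phantom: masks, ADC map, DCE series, and truth.

    Identical spec and seed yield bit-identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    aif = aif or ParkerAif()
    masks, class_map = _build_geometry(spec, rng)
    params = _draw_patient_params(spec.tissue_params, rng)
    adc, dce = _synthesize_volumes(spec, class_map, params, rng, aif)
    return Phantom(adc=adc, dce=dce, masks=masks, class_map=class_map, truth=params)


# --------------------------------------------------------------------------
# Labels
# --------------------------------------------------------------------------

_TRUTH_FEATURES = {
    "ADC_Mean": "adc",
    "DCE_Ktrans": "ktrans",
    "DCE_ve": "ve",
    "DCE_kep": None,  # derived: ktrans / ve
}
_ROI_TO_CLASS = {"GTV": "GTV", "NAT-PZ": "PZ", "NAT-TZ": "TZ"}


def known_label_features() -> list[str]:
    return sorted(f"{roi}_{feat}" for roi in _ROI_TO_CLASS for feat in _TRUTH_FEATURES)


def _truth_feature(params: dict[str, dict[str, float]], name: str) -> float:
    roi, _, feat = name.partition("_")
    if roi not in _ROI_TO_CLASS or feat not in _TRUTH_FEATURES:
        raise ValueError(
            f"label model references unknown feature {name!r}; known: {known_label_features()}"
        )
    cls = _ROI_TO_CLASS[roi]
    if feat == "DCE_kep":
        return params[cls]["ktrans"] / params[cls]["ve"]
    return params[cls][_TRUTH_FEATURES[feat]]


def _feature_scale(tissue_params: dict[str, TissueClass], name: str) -> tuple[float, float]:
    roi, _, feat = name.partition("_")
    tp = tissue_params[_ROI_TO_CLASS[roi]]
    if feat == "ADC_Mean":
        return tp.adc
    if feat == "DCE_Ktrans":
        return tp.ktrans
    if feat == "DCE_ve":
        return tp.ve
    # kep: first-order propagation from the (ktrans, ve) scales
    m = tp.ktrans[0] / tp.ve[0]
    s = m * np.hypot(tp.ktrans[1] / tp.ktrans[0], tp.ve[1] / tp.ve[0])
    return (m, s)


def _draw_labels(
    baselines: list[dict[str, dict[str, float]]],
    model: LabelModel,
    tissue_params: dict[str, TissueClass],
    target: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    for name in model.coefficients:
        _truth_feature(baselines[0], name)  # validates the name
    Z = np.array(
        [
            [
                (_truth_feature(b, name) - _feature_scale(tissue_params, name)[0])
                / _feature_scale(tissue_params, name)[1]
                for name in model.coefficients
            ]
            for b in baselines
        ]
    )
    betas = np.array(list(model.coefficients.values()))
    lp = Z @ betas
    intercept = model.intercept
    if target is not None:
        # shift the intercept so the expected prevalence hits the target
        lo, hi = -20.0, 20.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if np.mean(1 / (1 + np.exp(-(lp + mid)))) < target:
                lo = mid
            else:
                hi = mid
        intercept = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(-(lp + intercept)))
    for _ in range(50):
        labels = (rng.uniform(size=len(p)) < p).astype(int)
        if 0 < labels.sum() < len(labels):
            return labels
    raise RuntimeError("could not draw labels with both classes present")


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

def generate_cohort(
    cohort: CohortSpec, phantom: PhantomSpec, aif: ParkerAif | None = None
) -> Cohort:
    """A full longitudinal cohort with geometry fixed per patient.

    Masks (prostate/PZ/GTV) are drawn once per patient and reused across
    scan points, emulating contours propagated across time points; tissue
    parameters follow the per-scan trajectory multipliers.
    """
    aif = aif or ParkerAif()
    ss = np.random.SeedSequence(cohort.seed)
    child_seeds = ss.spawn(cohort.n_patients + 1)
    label_rng = np.random.default_rng(child_seeds[-1])

    patients, baselines = [], []
    scan_indices = [SCAN_POINTS.index(sp) for sp in cohort.scan_points]
    for i in range(cohort.n_patients):
        rng = np.random.default_rng(child_seeds[i])
        pid = f"P{i + 1:03d}"
        masks, class_map = _build_geometry(phantom, rng)
        base = _draw_patient_params(phantom.tissue_params, rng)
        baselines.append(base)
        scans: dict[str, Phantom] = {}
        for sp, si in zip(cohort.scan_points, scan_indices):
            if cohort.n_present is not None and i >= cohort.n_present.get(sp, cohort.n_patients):
                continue
            params = _scale_params(base, cohort.trajectories, si)
            adc, dce = _synthesize_volumes(phantom, class_map, params, rng, aif)
            scans[sp] = Phantom(adc=adc, dce=dce, masks=masks, class_map=class_map, truth=params)
        patients.append(
            {"patient_id": pid, "masks": masks, "class_map": class_map, "scans": scans}
        )

    labels = _draw_labels(
        baselines, cohort.label_model, phantom.tissue_params,
        cohort.positive_fraction_target, label_rng,
    )
    label_series = pd.Series(labels, index=[p["patient_id"] for p in patients], name="biopsy")
    truth = {
        p["patient_id"]: {
            "baseline": baselines[i],
            "scans": {sp: ph.truth for sp, ph in p["scans"].items()},
            "label": int(labels[i]),
        }
        for i, p in enumerate(patients)
    }
    return Cohort(patients=patients, labels=label_series, truth=truth)
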