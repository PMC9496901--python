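"""End-to-end orchestration: phantom cohort -> ROIs -> features -> stats -> model.

`extract_scan_features` turns one patient-scan volume set into a flat
feature map; `cohort_feature_table` assembles the longitudinal feature
table for a synthetic cohort; `run_pipeline` writes the full artifact
directory (features.csv, longitudinal_report.csv, per-comparison model
JSONs, truth, config, log) deterministically for a given config.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .adc import extract_adc_features
from .config import PipelineConfig, save_config
from .core import ImageVolume
from .dce import fit_tofts, roi_curve
from .io import save_json, save_nifti
from .model import COMPARISONS, build_comparisons, run_outcome_model
from .preprocess import crop_to_prostate, resample
from .roi import RoiSet, derive_rois
from .stats import longitudinal_report
from .synthetic import Cohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["extract_scan_features", "cohort_feature_table", "run_pipeline"]

DCE_FEATURES = ("Ktrans", "kep", "ve", "AUC90", "AUC120", "tonset")


def derive_scan_rois(
    masks: dict[str, np.ndarray],
    native_spacing: tuple[float, float, float],
    config: PipelineConfig,
) -> RoiSet:
    """Resample masks to the analysis grid and run the ROI geometry."""
    grid = config.grid
    res = {
        k: resample(ImageVolume(m, native_spacing), grid, kind="mask").data
        for k, m in masks.items()
        if k in ("prostate", "pz", "gtv")
    }
    return derive_rois(
        res["prostate"], res["pz"], res["gtv"], grid.spacing,
        ring_thickness_mm=config.ring_thickness_mm,
        pz_tolerance_frac=config.pz_tolerance_frac,
    )


def extract_scan_features(
    adc: ImageVolume,
    dce: ImageVolume,
    masks: dict[str, np.ndarray],
    config: PipelineConfig,
) -> dict[str, float]:
    """All ADC and DCE features of one scan, on the analysis grid."""
    grid = config.grid
    adc_r = resample(adc, grid, kind="image")
    prostate_r = resample(ImageVolume(masks["prostate"], adc.spacing), grid, kind="mask").data
    rois = derive_scan_rois(masks, adc.spacing, config)

    adc_c, offset = crop_to_prostate(adc_r, prostate_r, grid)
    crop = (
        slice(offset[0], offset[0] + adc_c.shape[0]),
        slice(offset[1], offset[1] + adc_c.shape[1]),
        slice(offset[2], offset[2] + adc_c.shape[2]),
    )
    rois_c = RoiSet(
        gtv=rois.gtv[crop], pt_pz=rois.pt_pz[crop], pt_tz=rois.pt_tz[crop],
        nat_pz=rois.nat_pz[crop], nat_tz=rois.nat_tz[crop], spacing_mm=grid.spacing,
    )
    features = extract_adc_features(
        adc_c, rois_c, min_voxels=config.min_voxels, include_min_max=config.include_min_max
    )

    dce_r = resample(dce, grid, kind="image") if config.resample_dce else dce
    dce_rois = rois if config.resample_dce else derive_rois(
        masks["prostate"], masks["pz"], masks["gtv"], dce.spacing,
        ring_thickness_mm=config.ring_thickness_mm,
        pz_tolerance_frac=config.pz_tolerance_frac,
    )
    for roi_name, mask in dce_rois.as_dict().items():
        if mask.sum() < config.min_voxels:
            logger.warning("ROI %s below min_voxels; DCE features missing", roi_name)
            for f in DCE_FEATURES:
                features[f"{roi_name}_DCE_{f}"] = float("nan")
            continue
        curve = roi_curve(dce_r, mask)
        fit = fit_tofts(
            curve, config.aif,
            dt_fine=config.fit_dt_fine, polish=config.fit_polish,
            vp_max=config.vp_max, k_sd=config.onset_k_sd,
        )
        features[f"{roi_name}_DCE_Ktrans"] = fit.ktrans
        features[f"{roi_name}_DCE_kep"] = fit.kep
        features[f"{roi_name}_DCE_ve"] = fit.ve
        features[f"{roi_name}_DCE_AUC90"] = fit.auc90
        features[f"{roi_name}_DCE_AUC120"] = fit.auc120
        features[f"{roi_name}_DCE_tonset"] = fit.t_onset
    return features


def cohort_feature_table(
    cohort: Cohort, config: PipelineConfig
) -> pd.DataFrame:
    """Feature table indexed by (patient_id, scan_point) for a cohort."""
    rows = []
    for patient in cohort.patients:
        for sp, phantom in patient["scans"].items():
            feats = extract_scan_features(phantom.adc, phantom.dce, patient["masks"], config)
            feats["patient_id"] = patient["patient_id"]
            feats["scan_point"] = sp
            rows.append(feats)
    table = pd.DataFrame(rows).set_index(["patient_id", "scan_point"]).sort_index()
    return table


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write the artifact directory.

    Layout: ``volumes/`` (optional NIfTI dumps), ``features.csv`` (tidy),
    ``features_wide.csv``, ``longitudinal_report.csv``,
    ``model_<comparison>.json``, ``labels.csv``, ``truth.json``,
    ``config_used.yaml``, ``log.txt``.  Identical config implies
    byte-identical tabular outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("prostamics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        chash = config.config_hash()
        logger.info("config hash %s", chash)
        save_config(config, out / "config_used.yaml")

        cohort = generate_cohort(config.cohort, config.phantom, aif=config.aif)
        logger.info(
            "generated cohort: %d patients, %d scans",
            len(cohort.patients), sum(len(p["scans"]) for p in cohort.patients),
        )
        if config.write_volumes:
            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            manifest = []
            for p in cohort.patients:
                pid = p["patient_id"]
                for name in ("prostate", "pz", "gtv"):
                    mpath = vol_dir / f"{pid}_{name}.nii.gz"
                    save_nifti(
                        ImageVolume(p["masks"][name].astype(np.uint8), config.phantom.spacing_mm),
                        mpath,
                    )
                for sp, ph in p["scans"].items():
                    apath = vol_dir / f"{pid}_{sp}_adc.nii.gz"
                    dpath = vol_dir / f"{pid}_{sp}_dce.nii.gz"
                    save_nifti(ph.adc, apath)
                    save_nifti(ph.dce, dpath)
                    manifest.append(
                        {
                            "patient_id": pid, "scan_point": sp,
                            "adc": apath.name, "dce": dpath.name,
                            "prostate": f"{pid}_prostate.nii.gz",
                            "pz": f"{pid}_pz.nii.gz", "gtv": f"{pid}_gtv.nii.gz",
                        }
                    )
            pd.DataFrame(manifest).to_csv(vol_dir / "manifest.csv", index=False)

        table = cohort_feature_table(cohort, config)
        table.to_csv(out / "features_wide.csv")
        tidy = (
            table.stack().rename("value").reset_index()
            .rename(columns={"level_2": "feature"})
        )
        tidy.to_csv(out / "features.csv", index=False)
        cohort.labels.to_csv(out / "labels.csv")
        save_json(cohort.truth, out / "truth.json")

        report = longitudinal_report(table)
        report.insert(0, "config_hash", chash)
        report.to_csv(out / "longitudinal_report.csv", index=False)

        comparisons = build_comparisons(table, cohort.labels)
        model_summaries = {}
        for name in COMPARISONS:
            if name not in comparisons.matrices:
                continue
            X, y = comparisons[name]
            result = run_outcome_model(
                X, y, p_pass=config.p_pass, r_max=config.r_max, max_k=config.max_k,
                threshold=config.threshold, nested=config.nested_loo, comparison=name,
            )
            fname = f"model_{name.replace('-', 'm')}.json"
            if result is None:
                logger.info("comparison %s: nothing passed the screen; model skipped", name)
                save_json({"comparison": name, "skipped": "no feature passed screen",
                           "config_hash": chash}, out / fname)
                continue
            d = result.to_dict()
            d["config_hash"] = chash
            save_json(d, out / fname)
            model_summaries[name] = {
                "auc": result.auc, "f1": result.f1,
                "selected_features": result.selected_features,
            }
        save_json({"config_hash": chash, "models": model_summaries}, out / "summary.json")
        return {"out_dir": str(out), "config_hash": chash, "models": model_summaries}
    finally:
        root.removeHandler(handler)
        handler.close()
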