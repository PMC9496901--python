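"""First-order ADC statistics per ROI.

Eleven first-order statistics are computed from the ADC values inside
each ROI: the 10/25/50/75/90th percentiles, mean, standard deviation,
skewness, kurtosis, and min/max.  Percentiles use linear interpolation
between closest ranks; kurtosis is reported as excess kurtosis (normal
distribution = 0).  Skewness and kurtosis of a constant sample are
undefined and emitted as missing rather than 0.

Feature names follow the ``ROI_Sequence_Feature`` convention, e.g.
``GTV_ADC_90`` or ``NAT-TZ_ADC_SD``.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats as sps

from .core import ImageVolume
from .roi import RoiSet

logger = logging.getLogger(__name__)

__all__ = ["ADC_FEATURES", "first_order_stats", "extract_adc_features"]

PERCENTILES = (10, 25, 50, 75, 90)
ADC_FEATURES = ("10", "25", "50", "75", "90", "Mean", "SD", "Skew", "Kurt", "Min", "Max")


def first_order_stats(
    values: np.ndarray,
    *,
    min_voxels: int = 10,
    include_min_max: bool = True,
) -> dict[str, float]:
    """First-order statistics of a voxel-value sample.

    Returns an ordered ``feature -> value`` map.  If the sample has fewer
    than ``min_voxels`` values, every feature is emitted as missing (NaN)
    rather than raising, so a small ROI degrades gracefully.
    """
    values = np.asarray(values, dtype=float).ravel()
    names = [f for f in ADC_FEATURES if include_min_max or f not in ("Min", "Max")]
    if values.size < min_voxels:
        logger.warning("sample of %d voxels below min_voxels=%d; features missing",
                       values.size, min_voxels)
        return {f: float("nan") for f in names}
    pct = np.percentile(values, PERCENTILES)  # linear interpolation between ranks
    out = {str(p): float(v) for p, v in zip(PERCENTILES, pct)}
    out["Mean"] = float(values.mean())
    sd = float(values.std(ddof=0))
    out["SD"] = sd
    if sd == 0.0:
        out["Skew"] = float("nan")
        out["Kurt"] = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["Skew"] = float(sps.skew(values, bias=True))
            out["Kurt"] = float(sps.kurtosis(values, fisher=True, bias=True))
    if include_min_max:
        out["Min"] = float(values.min())
        out["Max"] = float(values.max())
    return {f: out[f] for f in names}


def extract_adc_features(
    adc: ImageVolume,
    rois: RoiSet,
    *,
    min_voxels: int = 10,
    include_min_max: bool = True,
) -> dict[str, float]:
    """One first-order fragment per ROI, named ``ROI_ADC_Feature``."""
    if adc.data.shape[:3] != rois.gtv.shape:
        raise ValueError("ADC volume and ROI masks are on different grids")
    features: dict[str, float] = {}
    for roi_name, mask in rois.as_dict().items():
        frag = first_order_stats(
            adc.data[mask], min_voxels=min_voxels, include_min_max=include_min_max
        )
        for feat, val in frag.items():
            features[f"{roi_name}_ADC_{feat}"] = val
    return features
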