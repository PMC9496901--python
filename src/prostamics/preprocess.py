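"""Grid standardization: resampling to the analysis grid and prostate crop.

All volumes (ADC maps, dynamic frames, masks) are brought to a common
analysis grid — by default 0.5 x 0.5 mm in-plane and 3 mm slices — and
cropped to the prostate bounding box with a 10-pixel in-plane pad.
Images use linear interpolation (no overshoot on quantitative maps);
masks use nearest-neighbor so binarity is preserved.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume

__all__ = ["GridSpec", "resample", "crop_to_prostate", "uncrop_indices"]


@dataclass
class GridSpec:
    """Target analysis grid.

    ``in_plane_mm`` applies to the x and y axes, ``slice_mm`` to z;
    ``pad_px`` is the in-plane crop padding in pixels of the target grid.
    """

    in_plane_mm: float = 0.5
    slice_mm: float = 3.0
    pad_px: int = 10

    def __post_init__(self) -> None:
        if self.in_plane_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("grid spacings must be strictly positive")
        if self.pad_px < 0:
            raise ValueError("pad_px must be non-negative")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.in_plane_mm, self.in_plane_mm, self.slice_mm)


def _zoom3(data: np.ndarray, factors: tuple[float, float, float], order: int) -> np.ndarray:
    # grid_mode=True treats voxels as cells, so the physical field of view
    # is preserved when the spacing changes.
    return ndimage.zoom(
        data, factors, order=order, mode="nearest", grid_mode=True, prefilter=order > 1
    )


def resample(volume: ImageVolume, grid: GridSpec, kind: str = "image") -> ImageVolume:
    """Resample a volume onto the analysis grid.

    ``kind='image'`` interpolates linearly; ``kind='mask'`` uses
    nearest-neighbor and returns a boolean array.  A volume already on
    the target grid is passed through unchanged (copy).
    """
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    if volume.spacing is None or any(s <= 0 for s in volume.spacing):
        raise ValueError("volume is missing valid spacing metadata")
    target = grid.spacing
    factors = tuple(s / t for s, t in zip(volume.spacing, target))
    if np.allclose(factors, 1.0):
        out = volume.data.astype(bool) if kind == "mask" else volume.data.copy()
        return ImageVolume(out, target, None if volume.times is None else volume.times.copy())
    order = 0 if kind == "mask" else 1
    if volume.is_4d:
        frames = [_zoom3(volume.data[..., k], factors, order) for k in range(volume.data.shape[3])]
        data = np.stack(frames, axis=-1)
    else:
        data = _zoom3(volume.data, factors, order)
    if kind == "mask":
        data = data.astype(bool)
    return ImageVolume(data, target, None if volume.times is None else volume.times.copy())


def crop_to_prostate(
    volume: ImageVolume, prostate: np.ndarray, grid: GridSpec
) -> tuple[ImageVolume, tuple[int, int, int]]:
    """Crop to the prostate bounding box, padded in-plane.

    The x/y extent is the prostate bounding box expanded by ``grid.pad_px``
    pixels (clamped at the image edge); z is cropped to the prostate's
    slice extent with no pad.  Returns the cropped volume and the index
    offset of the crop origin, so ``original_index = cropped_index + offset``.
    """
    prostate = np.asarray(prostate).astype(bool)
    if prostate.shape != volume.data.shape[:3]:
        raise ValueError("prostate mask and volume are on different grids")
    if not prostate.any():
        raise ValueError("prostate mask is empty; nothing to crop to")
    idx = np.nonzero(prostate)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    pad = grid.pad_px
    lo[0] = max(lo[0] - pad, 0)
    lo[1] = max(lo[1] - pad, 0)
    hi[0] = min(hi[0] + pad, prostate.shape[0])
    hi[1] = min(hi[1] + pad, prostate.shape[1])
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    data = volume.data[sl] if not volume.is_4d else volume.data[sl + (slice(None),)]
    out = ImageVolume(
        data.copy(), volume.spacing, None if volume.times is None else volume.times.copy()
    )
    return out, (lo[0], lo[1], lo[2])


def uncrop_indices(
    cropped_indices: np.ndarray, offset: tuple[int, int, int]
) -> np.ndarray:
    """Map voxel indices of a cropped volume back to the original grid."""
    return np.asarray(cropped_indices) + np.asarray(offset)
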