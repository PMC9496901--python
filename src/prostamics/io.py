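"""NIfTI-1 and tabular I/O."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ImageVolume

__all__ = ["save_nifti", "load_nifti", "save_mask", "load_mask", "save_json", "load_json"]


def save_nifti(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; spacing goes into the affine/zooms.

    For 4-D series the frame interval is stored in the 4th zoom and the
    full time-stamp vector in a JSON sidecar next to the file.
    """
    path = Path(path)
    data = volume.data
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(volume.spacing)
    if volume.is_4d:
        dt = float(np.median(np.diff(volume.times)))
        zooms.append(dt)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    if volume.is_4d:
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii / .nii.gz
        save_json({"times_s": volume.times.tolist()}, str(sidecar) + ".times.json")


def load_nifti(path: str | Path, times: np.ndarray | None = None) -> ImageVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if data.ndim == 4 and times is None:
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".times.json")
        if sidecar.exists():
            times = np.asarray(load_json(sidecar)["times_s"])
        else:
            dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
            times = np.arange(data.shape[3]) * dt
    return ImageVolume(data, spacing, times if data.ndim == 4 else None)


def save_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    save_nifti(ImageVolume(np.asarray(mask).astype(np.uint8), spacing), path)


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    vol = load_nifti(path)
    return vol.data.astype(bool), vol.spacing


def save_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
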