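"""Shared volumetric containers.

Arrays are indexed ``(x, y, z)`` for 3-D volumes and ``(x, y, z, t)`` for
dynamic series; ``spacing`` gives the physical voxel size in millimeters
along each spatial axis.  Time stamps are in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A scalar 3-D volume or a 4-D dynamic series on a regular grid.

    Parameters
    ----------
    data
        3-D array ``(x, y, z)`` or 4-D array ``(x, y, z, t)``.
    spacing
        Voxel size in mm along the three spatial axes.
    times
        Frame time stamps in seconds, required for 4-D data; strictly
        increasing, ``times[0] == 0`` by convention for dynamic series.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be 3-D or 4-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.data.ndim == 4:
            if self.times is None:
                raise ValueError("4-D volumes require frame time stamps")
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.data.shape[3],):
                raise ValueError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        elif self.times is not None:
            raise ValueError("times only apply to 4-D volumes")

    @property
    def is_4d(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "ImageVolume":
        t = None if self.times is None else self.times.copy()
        return ImageVolume(self.data.copy(), self.spacing, t)


def check_same_grid(*shapes_spacings) -> None:
    """Raise if any (shape, spacing) pair disagrees with the first."""
    ref_shape, ref_spacing = shapes_spacings[0]
    for shape, spacing in shapes_spacings[1:]:
        if tuple(shape) != tuple(ref_shape):
            raise ValueError(f"grid shape mismatch: {shape} vs {ref_shape}")
        if spacing is not None and ref_spacing is not None:
            if not np.allclose(spacing, ref_spacing):
                raise ValueError(f"spacing mismatch: {spacing} vs {ref_spacing}")
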