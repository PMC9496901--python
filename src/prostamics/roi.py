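"""ROI geometry: transition zone, peritumoral ring, and normal-tissue masks.

Five analysis regions are derived from three input masks (prostate,
peripheral zone, gross tumor volume):

* ``GTV`` — the tumor itself (union of all lesions);
* ``PT-PZ`` / ``PT-TZ`` — the 5 mm peritumoral ring split by zone;
* ``NAT-PZ`` / ``NAT-TZ`` — normally-appearing tissue: the zone outside
  both the tumor and its ring.

The ring is a 3-D morphological shell: all non-tumor voxels whose center
lies within ``thickness_mm`` (Euclidean, physical millimeters, honoring
anisotropic spacing) of a tumor voxel center.  The ring is clipped to the
prostate, since features are only ever computed inside prostate tissue.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RoiSet",
    "derive_tz",
    "peritumoral_ring",
    "split_ring_and_nat",
    "merge_multifocal",
    "derive_rois",
]

ROI_NAMES = ("GTV", "PT-PZ", "PT-TZ", "NAT-PZ", "NAT-TZ")


@dataclass
class RoiSet:
    """The five analysis masks on one common grid."""

    gtv: np.ndarray
    pt_pz: np.ndarray
    pt_tz: np.ndarray
    nat_pz: np.ndarray
    nat_tz: np.ndarray
    spacing_mm: tuple[float, float, float]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "GTV": self.gtv,
            "PT-PZ": self.pt_pz,
            "PT-TZ": self.pt_tz,
            "NAT-PZ": self.nat_pz,
            "NAT-TZ": self.nat_tz,
        }

    def validate(self, prostate: np.ndarray | None = None) -> None:
        """Assert the disjointness/containment invariants; raise on violation."""
        m = self.as_dict()
        shapes = {k: v.shape for k, v in m.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"ROI masks on different grids: {shapes}")
        ring = self.pt_pz | self.pt_tz
        if np.any(self.pt_pz & self.gtv) or np.any(self.pt_tz & self.gtv):
            raise ValueError("peritumoral ring overlaps the GTV")
        if np.any(self.pt_pz & self.pt_tz):
            raise ValueError("PT-PZ and PT-TZ overlap")
        for name in ("nat_pz", "nat_tz"):
            nat = getattr(self, name)
            if np.any(nat & (self.gtv | ring)):
                raise ValueError(f"{name} overlaps the tumor or its ring")
        if np.any(self.nat_pz & self.nat_tz):
            raise ValueError("NAT-PZ and NAT-TZ overlap")
        if prostate is not None:
            for k, v in m.items():
                if np.any(v & ~prostate):
                    raise ValueError(f"{k} extends outside the prostate")

    def voxel_counts(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.as_dict().items()}


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def derive_tz(prostate: np.ndarray, pz: np.ndarray, *, tolerance_frac: float = 0.01) -> np.ndarray:
    """Transition zone = prostate minus peripheral zone.

    A small fraction of PZ voxels (default 1%) may fall outside the
    prostate — resampling slivers — and are clipped; beyond that the
    inputs are considered inconsistent and an error is raised.
    """
    prostate = _as_bool(prostate)
    pz = _as_bool(pz)
    if prostate.shape != pz.shape:
        raise ValueError(f"grid mismatch: prostate {prostate.shape} vs PZ {pz.shape}")
    outside = int(np.count_nonzero(pz & ~prostate))
    n_pz = int(pz.sum())
    if n_pz > 0 and outside > tolerance_frac * n_pz:
        raise ValueError(
            f"PZ not contained in prostate: {outside} of {n_pz} PZ voxels outside "
            f"(tolerance {tolerance_frac:.1%})"
        )
    if outside:
        logger.info("clipped %d stray PZ voxels outside the prostate", outside)
    return prostate & ~pz


def peritumoral_ring(
    gtv: np.ndarray,
    spacing_mm: tuple[float, float, float],
    thickness_mm: float = 5.0,
) -> np.ndarray:
    """Peritumoral shell: non-GTV voxels within ``thickness_mm`` of the GTV.

    Distance is the Euclidean distance between voxel centers, computed in
    physical millimeters with the (possibly anisotropic) voxel spacing.
    A non-positive thickness yields an empty ring.
    """
    gtv = _as_bool(gtv)
    if not gtv.any():
        raise ValueError("GTV mask is empty; cannot build a peritumoral ring")
    if thickness_mm <= 0:
        return np.zeros_like(gtv)
    dist = ndimage.distance_transform_edt(~gtv, sampling=spacing_mm)
    return (dist <= thickness_mm) & ~gtv


def split_ring_and_nat(
    ring: np.ndarray,
    gtv: np.ndarray,
    pz: np.ndarray,
    tz: np.ndarray,
    prostate: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> RoiSet:
    """Partition the ring by zone and carve out the normal-tissue masks.

    ``PT-PZ``/``PT-TZ`` are the ring's intersections with each zone;
    ``NAT-PZ``/``NAT-TZ`` are the zone remainders outside tumor and ring.
    Ring voxels outside the prostate are discarded.
    """
    masks = {"ring": ring, "gtv": gtv, "pz": pz, "tz": tz, "prostate": prostate}
    for name, m in masks.items():
        if m is None:
            raise ValueError(f"required mask '{name}' is missing")
    ring, gtv, pz, tz, prostate = (_as_bool(m) for m in (ring, gtv, pz, tz, prostate))
    shapes = {m.shape for m in (ring, gtv, pz, tz, prostate)}
    if len(shapes) != 1:
        raise ValueError(f"masks on different grids: {shapes}")
    gtv_in = gtv & prostate
    ring_in = ring & prostate & ~gtv_in
    rois = RoiSet(
        gtv=gtv_in,
        pt_pz=ring_in & pz,
        pt_tz=ring_in & tz,
        nat_pz=pz & ~ring_in & ~gtv_in,
        nat_tz=tz & ~ring_in & ~gtv_in,
        spacing_mm=tuple(spacing_mm),
    )
    rois.validate(prostate=prostate)
    return rois


def merge_multifocal(gtvs: list[np.ndarray]) -> np.ndarray:
    """Voxelwise union of per-lesion masks.

    Multifocal disease is handled by merging lesions before the ring is
    built, so overlapping per-lesion shells are never double counted.
    """
    if not gtvs:
        raise ValueError("need at least one GTV mask")
    out = _as_bool(gtvs[0]).copy()
    for m in gtvs[1:]:
        m = _as_bool(m)
        if m.shape != out.shape:
            raise ValueError(f"grid mismatch among GTV masks: {m.shape} vs {out.shape}")
        out |= m
    return out


def derive_rois(
    prostate: np.ndarray,
    pz: np.ndarray,
    gtvs: list[np.ndarray] | np.ndarray,
    spacing_mm: tuple[float, float, float],
    *,
    ring_thickness_mm: float = 5.0,
    pz_tolerance_frac: float = 0.01,
) -> RoiSet:
    """Full geometry chain: TZ, merged GTV, ring, and the five-ROI split."""
    if isinstance(gtvs, np.ndarray):
        gtvs = [gtvs]
    gtv = merge_multifocal(gtvs)
    prostate = _as_bool(prostate)
    pz = _as_bool(pz)
    tz = derive_tz(prostate, pz, tolerance_frac=pz_tolerance_frac)
    pz = pz & prostate  # clip slivers (within tolerance, checked above)
    ring = peritumoral_ring(gtv, spacing_mm, ring_thickness_mm)
    return split_ring_and_nat(ring, gtv, pz, tz, prostate, spacing_mm)
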