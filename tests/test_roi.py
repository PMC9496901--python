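"""ROI geometry: transition zone, peritumoral ring, five-ROI split."""
import numpy as np
import pytest

from prostamics.evaluation import brute_force_ring
from prostamics.roi import (
    derive_rois,
    derive_tz,
    merge_multifocal,
    peritumoral_ring,
    split_ring_and_nat,
)


def _ellipsoid(shape, spacing, center_mm, radii_mm):
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    return sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm)) <= 1.0


class TestDeriveTz:
    def test_full_subtraction_gives_empty_tz(self):
        prostate = _ellipsoid((20, 20, 8), (1, 1, 3), (10, 10, 12), (8, 8, 9))
        assert derive_tz(prostate, prostate).sum() == 0

    def test_empty_pz_gives_whole_prostate(self):
        prostate = _ellipsoid((20, 20, 8), (1, 1, 3), (10, 10, 12), (8, 8, 9))
        tz = derive_tz(prostate, np.zeros_like(prostate))
        assert np.array_equal(tz, prostate)

    def test_voxel_count_identity(self):
        prostate = _ellipsoid((24, 24, 8), (1, 1, 3), (12, 12, 12), (10, 9, 9))
        y = np.meshgrid(*[np.arange(n) for n in prostate.shape], indexing="ij")[1]
        pz = prostate & (y >= 14)
        tz = derive_tz(prostate, pz)
        assert tz.sum() == prostate.sum() - pz.sum()

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            derive_tz(np.ones((4, 4, 4), bool), np.ones((4, 4, 5), bool))

    def test_pz_outside_beyond_tolerance_raises(self):
        prostate = np.zeros((10, 10, 4), bool)
        prostate[2:8, 2:8, 1:3] = True
        pz = np.zeros_like(prostate)
        pz[0:4, 0:4, 1:3] = True  # mostly outside
        with pytest.raises(ValueError, match="outside"):
            derive_tz(prostate, pz)


class TestPeritumoralRing:
    @pytest.mark.parametrize(
        "shape,spacing,thickness",
        [
            ((16, 16, 8), (1.0, 1.0, 1.0), 5.0),
            ((20, 20, 8), (2.0, 2.0, 3.0), 5.0),
            ((12, 18, 10), (1.5, 0.8, 2.5), 4.0),
            ((64, 8, 8), (0.5, 2.0, 3.0), 5.0),
        ],
    )
    def test_matches_brute_force_distance_scan(self, shape, spacing, thickness, rng):
        gtv = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(1, 4))):
            gtv[tuple(int(rng.integers(2, s - 2)) for s in shape)] = True
        fast = peritumoral_ring(gtv, spacing, thickness)
        slow = brute_force_ring(gtv, spacing, thickness)
        assert np.array_equal(fast, slow)

    def test_single_voxel_isotropic_count(self):
        gtv = np.zeros((13, 13, 13), dtype=bool)
        gtv[6, 6, 6] = True
        ring = peritumoral_ring(gtv, (1.0, 1.0, 1.0), 5.0)
        # voxels with center distance <= 5 mm, excluding the seed
        offs = np.arange(-6, 7)
        dx, dy, dz = np.meshgrid(offs, offs, offs, indexing="ij")
        expected = (dx**2 + dy**2 + dz**2 <= 25).sum() - 1
        assert ring.sum() == expected

    def test_zero_thickness_is_empty(self):
        gtv = np.zeros((8, 8, 8), dtype=bool)
        gtv[4, 4, 4] = True
        assert peritumoral_ring(gtv, (1, 1, 1), 0.0).sum() == 0

    def test_empty_gtv_raises(self):
        with pytest.raises(ValueError, match="empty"):
            peritumoral_ring(np.zeros((8, 8, 8), bool), (1, 1, 1))

    def test_sphere_ring_is_shell(self):
        # fine isotropic grid: ring volume ~ analytic shell r..r+5
        spacing = (1.0, 1.0, 1.0)
        gtv = _ellipsoid((40, 40, 40), spacing, (20, 20, 20), (6, 6, 6))
        ring = peritumoral_ring(gtv, spacing, 5.0)
        shell = 4 / 3 * np.pi * ((6 + 5) ** 3 - 6**3)
        assert ring.sum() == pytest.approx(shell, rel=0.10)
        assert not np.any(ring & gtv)


class TestSplitAndInvariants:
    def _setup(self):
        shape, spacing = (32, 32, 8), (2.0, 2.0, 3.0)
        prostate = _ellipsoid(shape, spacing, (32, 32, 12), (22, 18, 11))
        y = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")[1]
        pz = prostate & (y >= 36)
        tz = prostate & ~pz
        gtv = _ellipsoid(shape, spacing, (32, 44, 12), (5, 5, 5)) & prostate
        return prostate, pz, tz, gtv, spacing

    def test_roiset_invariants_and_partitions(self):
        prostate, pz, tz, gtv, spacing = self._setup()
        ring = peritumoral_ring(gtv, spacing, 5.0)
        rois = split_ring_and_nat(ring, gtv, pz, tz, prostate, spacing)
        rois.validate(prostate=prostate)
        ring_in = ring & prostate & ~gtv
        # ring partition: pt_pz | pt_tz == clipped ring
        assert np.array_equal(rois.pt_pz | rois.pt_tz, ring_in)
        # zone partition: nat_pz | pt_pz | (gtv & pz) == pz
        assert np.array_equal(rois.nat_pz | rois.pt_pz | (gtv & pz), pz)
        assert np.array_equal(rois.nat_tz | rois.pt_tz | (gtv & tz), tz)

    def test_gtv_in_pz_far_from_tz_gives_empty_pt_tz(self):
        shape, spacing = (40, 40, 10), (1.0, 1.0, 1.0)
        prostate = np.ones(shape, dtype=bool)
        y = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")[1]
        pz = y >= 10
        tz = ~pz
        gtv = _ellipsoid(shape, spacing, (20.0, 30.0, 5.0), (3, 3, 3))
        ring = peritumoral_ring(gtv, spacing, 5.0)
        rois = split_ring_and_nat(ring, gtv, pz, tz, prostate, spacing)
        assert rois.pt_tz.sum() == 0

    def test_missing_mask_raises(self):
        prostate, pz, tz, gtv, spacing = self._setup()
        with pytest.raises(ValueError, match="missing"):
            split_ring_and_nat(None, gtv, pz, tz, prostate, spacing)

    def test_translation_equivariance(self):
        prostate, pz, tz, gtv, spacing = self._setup()
        shift = (2, 1, 1)
        rois = derive_rois(prostate, pz, gtv, spacing)
        rolled = derive_rois(
            np.roll(prostate, shift, (0, 1, 2)),
            np.roll(pz, shift, (0, 1, 2)),
            np.roll(gtv, shift, (0, 1, 2)),
            spacing,
        )
        for name, mask in rois.as_dict().items():
            assert np.array_equal(np.roll(mask, shift, (0, 1, 2)), rolled.as_dict()[name]), name


class TestMergeMultifocal:
    def test_single_mask_identity(self):
        m = np.zeros((6, 6, 6), bool)
        m[2, 2, 2] = True
        assert np.array_equal(merge_multifocal([m]), m)

    def test_disjoint_sum_and_overlap(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros_like(a)
        a[1:3, 1:3, 1:3] = True
        b[5:7, 5:7, 5:7] = True
        assert merge_multifocal([a, b]).sum() == a.sum() + b.sum()
        c = np.roll(a, 1, axis=0)  # overlapping
        assert merge_multifocal([a, c]).sum() < a.sum() + c.sum()

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            merge_multifocal([])
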