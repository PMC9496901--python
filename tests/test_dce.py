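"""Parker AIF, extended Tofts forward model, fitting, semi-quantitative features."""
import numpy as np
import pytest

from prostamics.core import ImageVolume
from prostamics.dce import (
    ContrastCurve,
    ParkerAif,
    ToftsParams,
    fit_tofts,
    roi_curve,
    semi_quant,
    tofts_forward,
)


class TestParkerAif:
    def test_prebolus_near_zero(self, aif):
        t = np.linspace(0, 300, 3001)
        cp = aif(t)
        assert aif(np.array([0.0]))[0] < 0.02 * cp.max()

    def test_single_first_pass_peak_within_first_minute(self, aif):
        t = np.linspace(0, 300, 3001)
        cp = aif(t)
        t_peak = t[cp.argmax()]
        assert 0 < t_peak < 60
        # decays toward recirculation tail after the peak region
        assert cp[t > 120].max() < 0.4 * cp.max()

    def test_gaussian_amplitude_linearity(self, aif):
        t = np.linspace(0, 300, 3001)
        doubled = ParkerAif(A=(2 * aif.A[0], 2 * aif.A[1]))
        tail = aif.alpha * np.exp(-aif.beta * t / 60) / (
            1 + np.exp(-aif.s * (t / 60 - aif.tau))
        )
        assert np.allclose(doubled(t) - tail, 2 * (aif(t) - tail), atol=1e-9)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            ParkerAif(sigma=(-0.05, 0.132))


class TestToftsForward:
    t = np.arange(0.0, 300.1, 6.0)

    def test_no_exchange_no_plasma_is_zero(self, aif):
        p = ToftsParams(ktrans=0.0, kep=0.5, vp=0.0, t_onset=0.0)
        assert np.allclose(tofts_forward(p, aif, self.t), 0.0)

    def test_pure_plasma_term(self, aif):
        p = ToftsParams(ktrans=0.0, kep=0.5, vp=0.05, t_onset=0.0)
        ct = tofts_forward(p, aif, self.t)
        assert np.allclose(ct[1:], 0.05 * aif(self.t[1:]), rtol=1e-9)

    def test_boxcar_aif_closed_form(self):
        box = lambda ts: np.where((np.asarray(ts) >= 0) & (np.asarray(ts) <= 400), 1.0, 0.0)
        ktrans, kep = 0.2, 0.5
        p = ToftsParams(ktrans=ktrans, kep=kep, vp=0.0, t_onset=0.0)
        ct = tofts_forward(p, box, self.t)
        closed = ktrans / kep * (1 - np.exp(-kep * self.t / 60.0))
        err = np.abs(ct[1:] - closed[1:]).max() / closed.max()
        assert err < 0.005

    def test_quadrature_halving_changes_under_quarter_percent(self, aif):
        p = ToftsParams(ktrans=0.12, kep=0.49, vp=0.02, t_onset=15.0)
        c1 = tofts_forward(p, aif, self.t, dt_fine=0.5)
        c2 = tofts_forward(p, aif, self.t, dt_fine=0.25)
        assert np.abs(c1 - c2).max() / np.abs(c2).max() < 0.0025

    def test_zero_before_onset(self, aif):
        p = ToftsParams(ktrans=0.12, kep=0.49, vp=0.02, t_onset=30.0)
        ct = tofts_forward(p, aif, self.t)
        assert np.all(ct[self.t <= 30.0] == 0.0)

    def test_nonpositive_kep_rejected(self):
        with pytest.raises(ValueError):
            ToftsParams(ktrans=0.1, kep=0.0, vp=0.0, t_onset=0.0)


class TestFitTofts:
    t = np.arange(0.0, 300.1, 6.0)

    @pytest.mark.parametrize("ktrans,kep,vp", [(0.12, 0.49, 0.02), (0.08, 0.16, 0.01), (0.14, 0.40, 0.05)])
    def test_noise_free_recovery_within_one_percent(self, aif, ktrans, kep, vp):
        truth = ToftsParams(ktrans=ktrans, kep=kep, vp=vp, t_onset=15.0)
        c = tofts_forward(truth, aif, self.t)
        fit = fit_tofts(ContrastCurve(t=self.t, c=c, n_baseline=3), aif)
        assert fit.converged
        assert fit.ktrans == pytest.approx(ktrans, rel=0.01)
        assert fit.kep == pytest.approx(kep, rel=0.01)
        assert fit.ve == pytest.approx(ktrans / kep, rel=0.01)

    def test_noisy_recovery_median_under_ten_percent(self, aif):
        truth = ToftsParams(ktrans=0.12, kep=0.49, vp=0.02, t_onset=15.0)
        c0 = tofts_forward(truth, aif, self.t)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(20):
            c = c0 + rng.normal(0, 0.01 * c0.max(), size=c0.shape)
            fit = fit_tofts(ContrastCurve(t=self.t, c=c, n_baseline=3), aif)
            errs.append(abs(fit.ktrans - truth.ktrans) / truth.ktrans)
        assert np.median(errs) < 0.10

    def test_flat_zero_curve_hits_lower_bound(self, aif):
        fit = fit_tofts(ContrastCurve(t=self.t, c=np.zeros_like(self.t), n_baseline=3), aif)
        assert fit.converged
        assert fit.ktrans == pytest.approx(0.0, abs=1e-6)
        assert fit.fit_rss == pytest.approx(0.0, abs=1e-12)

    def test_ve_identity_holds_for_fits(self, aif):
        truth = ToftsParams(ktrans=0.1, kep=0.3, vp=0.03, t_onset=15.0)
        c = tofts_forward(truth, aif, self.t)
        fit = fit_tofts(ContrastCurve(t=self.t, c=c, n_baseline=3), aif)
        assert fit.ve == fit.ktrans / fit.kep

    def test_deterministic_given_identical_inputs(self, aif):
        truth = ToftsParams(ktrans=0.12, kep=0.49, vp=0.02, t_onset=15.0)
        c = tofts_forward(truth, aif, self.t) + 0.01
        a = fit_tofts(ContrastCurve(t=self.t, c=c, n_baseline=3), aif)
        b = fit_tofts(ContrastCurve(t=self.t, c=c.copy(), n_baseline=3), aif)
        assert (a.ktrans, a.kep, a.vp, a.t_onset) == (b.ktrans, b.kep, b.vp, b.t_onset)

    def test_too_short_curve_rejected(self, aif):
        t = np.arange(0.0, 100.0, 6.0)
        with pytest.raises(ValueError, match="150"):
            fit_tofts(ContrastCurve(t=t, c=np.zeros_like(t), n_baseline=3), aif)


class TestSemiQuant:
    def test_zero_curve_no_onset_zero_aucs(self):
        t = np.arange(0.0, 200.0, 1.0)
        sq = semi_quant(ContrastCurve(t=t, c=np.zeros_like(t), n_baseline=3))
        assert not sq.onset_detected
        assert np.isnan(sq.t_onset)
        assert sq.auc90 == 0.0 and sq.auc120 == 0.0

    def test_step_curve_onset_and_auc(self):
        t = np.arange(0.0, 200.0, 1.0)
        c = np.where(t >= 30.0, 1.0, 0.0)
        sq = semi_quant(ContrastCurve(t=t, c=c, n_baseline=3))
        assert sq.onset_detected
        assert abs(sq.t_onset - 30.0) <= 1.0
        assert sq.auc90 == pytest.approx(90.0, abs=1.0)
        assert sq.auc120 == pytest.approx(120.0, abs=1.0)

    def test_auc120_not_less_than_auc90(self, aif):
        t = np.arange(0.0, 300.1, 6.0)
        p = ToftsParams(ktrans=0.12, kep=0.49, vp=0.02, t_onset=15.0)
        c = tofts_forward(p, aif, t)
        sq = semi_quant(ContrastCurve(t=t, c=c, n_baseline=2))
        assert sq.auc120 >= sq.auc90

    def test_short_window_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError, match="120"):
            semi_quant(ContrastCurve(t=t, c=np.zeros_like(t), n_baseline=3))


class TestRoiCurve:
    def test_constant_and_two_voxel_mean(self):
        times = np.arange(5) * 6.0
        data = np.zeros((4, 4, 2, 5))
        data[0, 0, 0, :] = 1.0
        data[1, 1, 1, :] = 3.0
        vol = ImageVolume(data, (1, 1, 3), times=times)
        roi = np.zeros((4, 4, 2), bool)
        roi[0, 0, 0] = roi[1, 1, 1] = True
        curve = roi_curve(vol, roi)
        assert np.allclose(curve.c, 2.0)

    def test_homogeneous_roi_mean_equals_voxel_curve(self, aif):
        times = np.arange(0.0, 300.1, 6.0)
        p = ToftsParams(ktrans=0.12, kep=0.49, vp=0.02, t_onset=15.0)
        ct = tofts_forward(p, aif, times)
        data = np.broadcast_to(ct, (3, 3, 2, len(times))).copy()
        vol = ImageVolume(data, (1, 1, 3), times=times)
        curve = roi_curve(vol, np.ones((3, 3, 2), bool))
        assert np.allclose(curve.c, ct)

    def test_empty_roi_raises(self):
        vol = ImageVolume(np.zeros((2, 2, 2, 5)), (1, 1, 3), times=np.arange(5.0) + 1)
        with pytest.raises(ValueError, match="empty"):
            roi_curve(vol, np.zeros((2, 2, 2), bool))
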