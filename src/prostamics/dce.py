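"""DCE-MRI pharmacokinetics on ROI-averaged contrast-time curves.

The model is the extended Tofts two-compartment exchange model driven by
the Parker population arterial input function (AIF):

    Ct(t) = vp * Cp(t - t0)
          + Ktrans * INT_0^{t-t0} Cp(u) * exp(-kep * (t - t0 - u)) du

with Ktrans (min^-1) the forward volume transfer constant, kep (min^-1)
the reflux rate constant, ve = Ktrans / kep the extravascular-
extracellular volume fraction, vp the plasma fraction, and t0 the
contrast wash-in time.  Curves are treated as (proportional to)
gadolinium concentration; no signal-equation/T1 conversion is applied,
so absolute Ktrans units track the input scaling.  Fitting operates on
the ROI-averaged curve, not voxelwise.

The convolution is evaluated on an internal fine time grid with an
exact piecewise-linear exponential update (the recursion is a linear
filter, run at C speed), then sampled at the frame times; the plasma
term is evaluated analytically at the frame times when the AIF is given
in functional form.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

__all__ = [
    "ParkerAif",
    "ContrastCurve",
    "ToftsParams",
    "SemiQuant",
    "parker_aif",
    "tofts_forward",
    "fit_tofts",
    "semi_quant",
    "roi_curve",
]


# --------------------------------------------------------------------------
# Arterial input function
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParkerAif:
    """Parker population AIF: two Gaussians plus a sigmoid-gated exponential.

    Cb(t) = sum_i A_i / (sigma_i sqrt(2 pi)) exp(-(t - T_i)^2 / (2 sigma_i^2))
          + alpha exp(-beta t) / (1 + exp(-s (t - tau)))

    Defaults are the published population-average constants; time in the
    constants is in minutes, amplitudes yield mM.  Calling the object
    evaluates Cb at times given in **seconds** (the package convention).
    """

    A: tuple[float, float] = (0.809, 0.330)          # mmol * min
    T: tuple[float, float] = (0.17046, 0.365)        # min
    sigma: tuple[float, float] = (0.0563, 0.132)     # min
    alpha: float = 1.050                             # mmol
    beta: float = 0.1685                             # min^-1
    s: float = 38.078                                # min^-1
    tau: float = 0.483                               # min

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sigma) or self.beta <= 0:
            raise ValueError("AIF widths and decay must be positive")

    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float) / 60.0  # seconds -> minutes
        c = np.zeros_like(t)
        for A, T, sig in zip(self.A, self.T, self.sigma):
            c += A / (sig * np.sqrt(2 * np.pi)) * np.exp(-((t - T) ** 2) / (2 * sig**2))
        c += self.alpha * np.exp(-self.beta * t) / (1.0 + np.exp(-self.s * (t - self.tau)))
        return np.where(np.asarray(t_s) < 0, 0.0, np.maximum(c, 0.0))


def parker_aif(t_s: np.ndarray, spec: ParkerAif | None = None) -> np.ndarray:
    """Evaluate the (population-default) Parker AIF at times in seconds."""
    return (spec or ParkerAif())(t_s)


# --------------------------------------------------------------------------
# Curve containers
# --------------------------------------------------------------------------

@dataclass
class ContrastCurve:
    """An ROI-averaged contrast-time curve.

    ``t`` in seconds, strictly increasing with ``t[0] == 0``; ``c`` in
    (units proportional to) mM; ``n_baseline`` pre-bolus frames define
    the baseline level for onset detection and AUC subtraction.
    """

    t: np.ndarray
    c: np.ndarray
    n_baseline: int = 3

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.t.shape != self.c.shape or self.t.ndim != 1:
            raise ValueError("t and c must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.n_baseline < 2:
            raise ValueError("need at least 2 pre-bolus baseline frames")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class ToftsParams:
    """Extended Tofts parameters plus semi-quantitative curve features.

    ``ve = Ktrans / kep`` holds by construction for every instance.
    """

    ktrans: float                # min^-1
    kep: float                   # min^-1
    vp: float                    # fraction
    t_onset: float               # s
    auc90: float = float("nan")  # concentration * s
    auc120: float = float("nan")
    fit_rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kep <= 0:
            raise ValueError("kep must be strictly positive")
        if self.ktrans < 0:
            raise ValueError("Ktrans must be non-negative")

    @property
    def ve(self) -> float:
        return self.ktrans / self.kep


@dataclass
class SemiQuant:
    """Model-free curve descriptors."""

    t_onset: float  # s; NaN if never detected
    auc90: float
    auc120: float
    onset_detected: bool


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def _expconv(c: np.ndarray, kappa: float, dt: float) -> np.ndarray:
    """I(t_k) = INT_0^{t_k} c(u) exp(-kappa (t_k - u)) du on a uniform grid.

    Exact for piecewise-linear ``c``; the recursion I_k = E I_{k-1} + b_k
    is evaluated as an IIR filter.
    """
    if kappa * dt < 1e-12:
        # kappa -> 0 limit: plain cumulative trapezoid
        out = np.zeros_like(c)
        out[1:] = np.cumsum(0.5 * dt * (c[1:] + c[:-1]))
        return out
    E = np.exp(-kappa * dt)
    c0, c1 = c[:-1], c[1:]
    w0 = (1.0 - E) / kappa
    w1 = 1.0 / kappa - (1.0 - E) / (kappa**2 * dt)
    b = c0 * w0 + (c1 - c0) * w1
    out = np.zeros_like(c)
    out[1:] = signal.lfilter([1.0], [1.0, -E], b)
    return out


def _aif_samples(aif, t: np.ndarray) -> np.ndarray:
    """Evaluate an AIF given as a callable or as a (t, c) sample pair."""
    if callable(aif):
        return aif(t)
    t_a, c_a = aif
    return np.interp(t, np.asarray(t_a, float), np.asarray(c_a, float), left=0.0)


def tofts_forward(
    params: ToftsParams,
    aif,
    t: np.ndarray,
    *,
    dt_fine: float = 0.5,
) -> np.ndarray:
    """Tissue concentration at the frame times ``t`` (seconds).

    ``aif`` is either a callable ``Cp(t_s) -> mM`` (e.g. a :class:`ParkerAif`)
    or a ``(t_aif, c_aif)`` sample pair, with its own time origin at the
    bolus arrival; the model is zero before ``params.t_onset``.
    """
    t = np.asarray(t, dtype=float)
    if params.kep <= 0:
        raise ValueError("kep must be strictly positive")
    ts = t - params.t_onset
    tmax = float(ts.max())
    if tmax <= 0:
        return np.zeros_like(t)
    n = int(np.ceil(tmax / dt_fine)) + 1
    tf = np.arange(n + 1) * dt_fine
    cp_f = _aif_samples(aif, tf)
    kappa_s = params.kep / 60.0  # min^-1 -> s^-1
    conv = _expconv(cp_f, kappa_s, dt_fine)
    ct = params.vp * _aif_samples(aif, np.maximum(ts, 0.0)) \
        + (params.ktrans / 60.0) * np.interp(np.maximum(ts, 0.0), tf, conv)
    return np.where(ts <= 0, 0.0, ct)


# --------------------------------------------------------------------------
# Semi-quantitative features
# --------------------------------------------------------------------------

def _window_trapezoid(t: np.ndarray, c: np.ndarray, t0: float, width: float) -> float:
    """Trapezoid integral of the sampled curve over [t0, t0 + width]."""
    t1 = t0 + width
    inside = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inside], [t1]))
    cc = np.interp(tt, t, c)
    return float(np.trapezoid(cc, tt))


def semi_quant(
    curve: ContrastCurve,
    *,
    k_sd: float = 3.0,
    n_consecutive: int = 2,
    baseline_subtract: bool = True,
    onset_anchor: bool = True,
) -> SemiQuant:
    """Wash-in time and 90/120 s areas under the curve.

    Onset is the first time the curve exceeds (baseline mean +
    ``k_sd`` * baseline SD) for ``n_consecutive`` consecutive frames.
    AUCs are trapezoid integrals of the (optionally baseline-subtracted)
    curve over the 90 s / 120 s window following onset; if no onset is
    detected the windows are anchored at t = 0 and the result is flagged.
    """
    t, c = curve.t, curve.c
    nb = curve.n_baseline
    base_mean = float(c[:nb].mean())
    base_sd = float(c[:nb].std(ddof=0))
    thr = base_mean + k_sd * base_sd
    above = c > thr
    onset_idx = None
    for i in range(len(c) - n_consecutive + 1):
        if above[i : i + n_consecutive].all():
            onset_idx = i
            break
    detected = onset_idx is not None
    t_onset = float(t[onset_idx]) if detected else float("nan")
    if detected and t_onset + 120.0 > t[-1] + 1e-9:
        # a crossing this late cannot be a bolus wash-in (no window left to
        # integrate); treat it as undetected and anchor the windows at t=0
        detected = False
        t_onset = float("nan")
    t0 = t_onset if (detected and onset_anchor) else float(t[0])
    if t0 + 120.0 > t[-1] + 1e-9:
        raise ValueError(
            f"curve spans only {t[-1]:.1f} s; need 120 s past the onset at {t0:.1f} s"
        )
    cs = c - base_mean if baseline_subtract else c
    return SemiQuant(
        t_onset=t_onset,
        auc90=_window_trapezoid(t, cs, t0, 90.0),
        auc120=_window_trapezoid(t, cs, t0, 120.0),
        onset_detected=detected,
    )


# --------------------------------------------------------------------------
# ROI curve
# --------------------------------------------------------------------------

def roi_curve(dce, roi: np.ndarray, *, n_baseline: int = 3) -> ContrastCurve:
    """Frame-wise mean over the ROI voxels of a 4-D dynamic series."""
    roi = np.asarray(roi).astype(bool)
    if not dce.is_4d:
        raise ValueError("roi_curve needs a 4-D dynamic series")
    if roi.shape != dce.data.shape[:3]:
        raise ValueError("ROI mask and DCE series are on different grids")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    c = dce.data[roi].mean(axis=0).astype(float)
    return ContrastCurve(t=dce.times.copy(), c=c, n_baseline=n_baseline)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _profile_linear(
    curve: ContrastCurve, aif, t_onset: float, kep_grid: np.ndarray, dt_fine: float
) -> tuple[float, float, float, float]:
    """Best (ktrans, kep, vp) for fixed t_onset by profiling kep.

    For fixed (kep, t_onset) the model is linear in (vp, Ktrans), so the
    amplitudes are solved by non-negative least squares on each kep of a
    log-spaced grid; the grid minimum seeds the nonlinear polish.
    """
    t = curve.t
    ts = np.maximum(t - t_onset, 0.0)
    active = (t - t_onset) > 0
    n = int(np.ceil(max(ts.max(), dt_fine) / dt_fine)) + 1
    tf = np.arange(n + 1) * dt_fine
    cp_f = _aif_samples(aif, tf)
    cp_t = _aif_samples(aif, ts) * active
    best = (0.0, float(kep_grid[0]), 0.0, np.inf)
    for kep in kep_grid:
        conv = np.interp(ts, tf, _expconv(cp_f, kep / 60.0, dt_fine)) * active / 60.0
        A = np.column_stack([cp_t, conv])
        coef, _ = optimize.nnls(A, curve.c)
        rss = float(((A @ coef - curve.c) ** 2).sum())
        if rss < best[3]:
            best = (float(coef[1]), float(kep), float(coef[0]), rss)
    return best


def fit_tofts(
    curve: ContrastCurve,
    aif=None,
    *,
    kep_grid: np.ndarray | None = None,
    dt_fine: float = 0.5,
    polish: bool = True,
    vp_max: float = 0.3,
    ktrans_max: float = 5.0,
    kep_max: float = 10.0,
    k_sd: float = 3.0,
) -> ToftsParams:
    """Fit the extended Tofts model to an ROI-averaged curve.

    Strategy: detect the wash-in frame to bracket ``t_onset``; profile
    ``kep`` over a log grid with the two amplitudes solved linearly
    (deterministic multi-start); then polish all four parameters with
    bounded nonlinear least squares.  ``ve <= 1`` is enforced by refitting
    in a ``(ve, kep)`` parameterization if the unconstrained optimum
    violates it.  The result is deterministic given identical inputs.
    """
    if aif is None:
        aif = ParkerAif()
    if len(curve.t) < 10 or curve.duration < 150.0:
        raise ValueError("need >= 10 frames spanning >= 150 s for a stable fit")
    if kep_grid is None:
        kep_grid = np.geomspace(0.05, 5.0, 25)
    dt_frame = float(np.median(np.diff(curve.t)))
    sq = semi_quant(curve, k_sd=k_sd)
    # the first supra-threshold frame is at or after the true onset
    t_on0 = max(sq.t_onset - dt_frame, 0.0) if sq.onset_detected else 0.0
    t_lo = max(t_on0 - dt_frame, 0.0)
    t_hi = (sq.t_onset if sq.onset_detected else 0.0) + dt_frame

    kt0, kep0, vp0, rss0 = _profile_linear(curve, aif, t_on0, kep_grid, dt_fine)
    scale = float((curve.c**2).sum()) or 1.0

    result = ToftsParams(
        ktrans=max(kt0, 0.0), kep=kep0, vp=vp0, t_onset=t_on0,
        fit_rss=rss0, converged=True,
    )
    if polish:
        def resid(x):
            p = ToftsParams(ktrans=x[0], kep=x[1], vp=x[2], t_onset=x[3])
            return tofts_forward(p, aif, curve.t, dt_fine=dt_fine) - curve.c

        x0 = np.clip(
            [kt0, kep0, vp0, t_on0],
            [0.0, 1e-3, 0.0, t_lo],
            [ktrans_max, kep_max, vp_max, t_hi],
        )
        sol = optimize.least_squares(
            resid, x0,
            bounds=([0.0, 1e-3, 0.0, t_lo], [ktrans_max, kep_max, vp_max, t_hi]),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        rss = float((sol.fun**2).sum())
        if rss <= rss0 + 1e-15:
            result = ToftsParams(
                ktrans=float(sol.x[0]), kep=float(sol.x[1]), vp=float(sol.x[2]),
                t_onset=float(sol.x[3]), fit_rss=rss, converged=bool(sol.success),
            )
    if result.ve > 1.0:
        # refit with ve as a bounded parameter; kep free, Ktrans = ve * kep
        def resid_ve(x):
            p = ToftsParams(ktrans=x[0] * x[1], kep=x[1], vp=x[2], t_onset=x[3])
            return tofts_forward(p, aif, curve.t, dt_fine=dt_fine) - curve.c

        x0 = [1.0, result.kep, result.vp, result.t_onset]
        sol = optimize.least_squares(
            resid_ve, x0,
            bounds=([0.0, 1e-3, 0.0, t_lo], [1.0, kep_max, vp_max, t_hi]),
            method="trf", xtol=1e-12, ftol=1e-12,
        )
        result = ToftsParams(
            ktrans=float(sol.x[0] * sol.x[1]), kep=float(sol.x[1]),
            vp=float(sol.x[2]), t_onset=float(sol.x[3]),
            fit_rss=float((sol.fun**2).sum()), converged=bool(sol.success),
        )
    if not np.isfinite(result.fit_rss) or result.fit_rss > 10.0 * scale:
        result = replace(result, converged=False)
    return replace(result, auc90=sq.auc90, auc120=sq.auc120)
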