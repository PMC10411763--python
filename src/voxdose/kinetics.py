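"""Time-activity integration: biexponential decay fits and per-voxel TIA.

The time-integrated activity (TIA) of a voxel or region is computed as

* a trapezoid over the uptake period — from injection (t = 0, A = 0 under the
  ramp model) through the sampled points up to the activity peak — plus
* the analytic tail of a double-exponential fit to the post-peak samples,
  integrated from the peak time to infinity.

The fitted model is A(t) = A1 e^(-lambda1 t) + A2 e^(-lambda2 t) with
amplitudes expressed on the absolute (injection-referenced) time axis, so the
tail integral is A1/lambda1 e^(-lambda1 t_peak) + A2/lambda2 e^(-lambda2 t_peak).
Internally the fit runs on peak-shifted time for numerical conditioning and
converts back.

With four-point sampling the double-exponential sits at the identifiability
edge: the *integral* is the contracted output, not the individual parameters
(a mono-exponential truth is matched by many (A1, A2) splits with the same
curve).  Fallbacks: mono-exponential when fewer than 3 post-peak points remain
or the double fit fails; physical-decay extrapolation from the last point when
a half-life is supplied and the mono fit also fails.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import warnings

import numpy as np
from scipy import optimize

from .errors import FitError, GeometryError
from .phantom_sim import CalibrationFactor
from .volumes_io import TimeSeriesVolume, ValueKind, Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "DecayFit",
    "TiaConfig",
    "CalibrationFactor",
    "fit_decay_double_exp",
    "integrate_tac",
    "tia_map",
]

_LAMBDA_BOUNDS = (1.0e-5, 10.0)  # 1/h


@dataclass
class DecayFit:
    """Fitted decay-segment model with analytic tail integral.

    Amplitudes are absolute-time (extrapolated to t = 0); ``tail_integral``
    is the MBq·h integral of the model from ``t_peak_h`` to infinity and is
    self-consistent with the stored parameters.
    """

    A1: float
    lambda1: float
    A2: float
    lambda2: float
    peak_index: int
    t_peak_h: float
    model: str                 # 'double_exp' | 'mono_exp' | 'physical_decay_fallback'
    fit_residual: float        # relative RMS on post-peak points

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise FitError("decay constants must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise FitError("amplitudes must be non-negative")

    def activity(self, t_h: np.ndarray) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        return self.A1 * np.exp(-self.lambda1 * t) + self.A2 * np.exp(-self.lambda2 * t)

    @property
    def tail_integral(self) -> float:
        """MBq·h from t_peak to infinity, evaluated from the stored parameters."""
        return float(
            self.A1 / self.lambda1 * np.exp(-self.lambda1 * self.t_peak_h)
            + self.A2 / self.lambda2 * np.exp(-self.lambda2 * self.t_peak_h)
        )


def _biexp_shifted(ts, a1, l1, a2, l2):
    return a1 * np.exp(-l1 * ts) + a2 * np.exp(-l2 * ts)


def _relative_rms(pred: np.ndarray, obs: np.ndarray) -> float:
    scale = float(np.max(np.abs(obs)))
    if scale == 0:
        return 0.0
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / scale)


def _peeling_init(ts: np.ndarray, a: np.ndarray,
                  lam_bounds=_LAMBDA_BOUNDS) -> tuple[float, float, float, float]:
    """Biexponential peeling: slow component from the last two points,
    fast component from the residual of the early points."""
    lo, hi = lam_bounds
    t1, t2 = ts[-2], ts[-1]
    a1v, a2v = max(a[-2], 1e-12), max(a[-1], 1e-12)
    l_slow = np.clip(np.log(a1v / a2v) / max(t2 - t1, 1e-9), lo, hi)
    amp_slow = a2v * np.exp(l_slow * t2)
    resid = a - amp_slow * np.exp(-l_slow * ts)
    pos = resid > 0
    if pos.sum() >= 2:
        coef = np.polyfit(ts[pos], np.log(resid[pos]), 1)
        l_fast = np.clip(-coef[0], lo, hi)
        amp_fast = np.exp(coef[1])
    else:
        l_fast = np.clip(10.0 * l_slow, lo, hi)
        amp_fast = max(resid.max(), 0.1 * amp_slow)
    if l_fast < l_slow:
        l_fast, l_slow = l_slow, l_fast
        amp_fast, amp_slow = amp_slow, amp_fast
    return amp_fast, l_fast, amp_slow, l_slow


def _fit_biexp_lm(tp: np.ndarray, ap: np.ndarray, p0,
                  lam_bounds=_LAMBDA_BOUNDS) -> tuple | None:
    """Fast biexponential fit: Levenberg-Marquardt on log-parameters
    (positivity by construction) with an analytic Jacobian.

    Returns (a1, l1, a2, l2) in shifted time, or None when the solution is
    unusable (failure or decay constants outside the admissible bounds), in
    which case the caller falls back to the bounded solver.
    """
    lo, hi = lam_bounds
    p0 = np.clip(np.asarray(p0, dtype=float),
                 [1e-10, lo, 1e-10, lo], [np.inf, hi, np.inf, hi])
    # amplitudes a = exp(u), rates l = lo + exp(u): positivity and the lower
    # decay-rate bound hold by construction
    u0 = np.array([
        np.log(p0[0]), np.log(max(p0[1] - lo, 1e-6)),
        np.log(p0[2]), np.log(max(p0[3] - lo, 1e-6)),
    ])

    def unpack(u):
        e = np.exp(np.minimum(u, 60.0))
        return e[0], lo + e[1], e[2], lo + e[3], e

    def resid(u):
        a1, l1, a2, l2, _ = unpack(u)
        return a1 * np.exp(-l1 * tp) + a2 * np.exp(-l2 * tp) - ap

    def jac(u):
        a1, l1, a2, l2, e = unpack(u)
        e1 = np.exp(-l1 * tp)
        e2 = np.exp(-l2 * tp)
        return np.column_stack([
            a1 * e1, -a1 * tp * e1 * e[1], a2 * e2, -a2 * tp * e2 * e[3]])

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            res = optimize.least_squares(resid, u0, jac=jac, method="lm",
                                         xtol=1e-14, ftol=1e-14, max_nfev=400)
    except Exception:
        return None
    if not res.success:
        return None
    a1, l1, a2, l2, _ = unpack(res.x)
    if not (l1 <= hi and l2 <= hi):
        return None
    return a1, l1, a2, l2


def fit_decay_double_exp(times_h, activities_mbq,
                         half_life_h: float | None = None) -> DecayFit:
    """Fit the post-peak decay segment of a time-activity curve.

    Nonlinear least squares of a positive-amplitude biexponential on the points
    from the activity maximum onward (inclusive); falls back to
    mono-exponential, then to physical-decay extrapolation (requires
    ``half_life_h``).  Raises :class:`FitError` when fewer than 2 post-peak
    points exist and no half-life is supplied.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities_mbq, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise FitError("times and activities must be matching 1-D arrays")
    if np.any(a < 0):
        raise FitError("activities must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise FitError("times must be strictly increasing")

    peak = int(np.argmax(a))
    t_peak = float(t[peak])
    tp = t[peak:] - t_peak     # shifted time for conditioning
    ap = a[peak:]

    if np.all(a == 0):
        return DecayFit(0.0, 1.0, 0.0, 1.0, peak, t_peak, "mono_exp", 0.0)

    n_post = len(ap)
    if n_post < 2 and half_life_h is None:
        raise FitError(
            f"only {n_post} post-peak point(s) and no half-life for physical fallback"
        )

    # effective decay cannot be slower than physical decay: when the
    # radionuclide half-life is known it sets the lower decay-rate bound
    lo, hi = _LAMBDA_BOUNDS
    if half_life_h is not None:
        lo = max(lo, np.log(2.0) / half_life_h)

    def finish(a1s, l1, a2s, l2, model):
        # convert shifted amplitudes (value at t_peak) to absolute time
        pred = _biexp_shifted(tp, a1s, l1, a2s, l2)
        return DecayFit(
            A1=float(a1s * np.exp(l1 * t_peak)), lambda1=float(l1),
            A2=float(a2s * np.exp(l2 * t_peak)), lambda2=float(l2),
            peak_index=peak, t_peak_h=t_peak, model=model,
            fit_residual=_relative_rms(pred, ap),
        )

    if n_post >= 3:
        p0 = _peeling_init(tp, ap, (lo, hi))
        fast = _fit_biexp_lm(tp, ap, p0, (lo, hi))
        if fast is not None:
            return finish(*fast, "double_exp")
        try:
            amp_hi = 100.0 * float(ap.max()) + 1e-9
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _biexp_shifted, tp, ap,
                    p0=np.clip(p0, [0, lo, 0, lo], [amp_hi, hi, amp_hi, hi]),
                    bounds=([0, lo, 0, lo], [amp_hi, hi, amp_hi, hi]), maxfev=10000,
                )
            return finish(*popt, "double_exp")
        except (RuntimeError, ValueError):
            logger.debug("double-exponential fit failed; falling back to mono")

    if n_post >= 2:
        try:
            pos = ap > 0
            if pos.sum() >= 2:
                coef = np.polyfit(tp[pos], np.log(ap[pos]), 1)
                p0m = [float(np.exp(coef[1])), float(np.clip(-coef[0], lo, hi))]
            else:
                p0m = [float(ap.max()), 0.01]
            amp_hi = 100.0 * float(ap.max()) + 1e-9
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    lambda ts, amp, lam: amp * np.exp(-lam * ts), tp, ap,
                    p0=np.clip(p0m, [0, lo], [amp_hi, hi]),
                    bounds=([0, lo], [amp_hi, hi]), maxfev=10000,
                )
            return finish(popt[0], popt[1], 0.0, 1.0, "mono_exp")
        except (RuntimeError, ValueError):
            logger.debug("mono-exponential fit failed; falling back to physical decay")

    if half_life_h is None:
        raise FitError("mono-exponential fit failed and no half-life for physical fallback")
    lam = np.log(2.0) / half_life_h
    # extrapolate physical decay from the last observed point
    a_last, t_last = float(a[-1]), float(t[-1])
    amp_at_peak = a_last * np.exp(lam * (t_last - t_peak))
    return finish(amp_at_peak, lam, 0.0, 1.0, "physical_decay_fallback")


def integrate_tac(times_h, activities_mbq, fit: DecayFit,
                  uptake_model: str = "ramp_from_zero") -> float:
    """Time-integrated activity (MBq·h): trapezoid up to the peak + analytic tail.

    ``ramp_from_zero`` prepends (0 h, 0 MBq); ``flat_from_first`` assumes the
    first observed activity held from t = 0.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities_mbq, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise FitError("times and activities must be matching 1-D arrays")
    if fit.peak_index >= len(t) or t[fit.peak_index] != fit.t_peak_h:
        raise FitError("fit is inconsistent with the supplied series")
    if uptake_model not in ("ramp_from_zero", "flat_from_first"):
        raise ValueError("uptake_model must be 'ramp_from_zero' or 'flat_from_first'")

    k = fit.peak_index
    if uptake_model == "ramp_from_zero":
        tt = np.concatenate([[0.0], t[: k + 1]])
        aa = np.concatenate([[0.0], a[: k + 1]])
    else:
        tt = np.concatenate([[0.0], t[: k + 1]])
        aa = np.concatenate([[a[0]], a[: k + 1]])
    uptake = float(np.trapezoid(aa, tt))
    return uptake + fit.tail_integral


@dataclass(frozen=True)
class TiaConfig:
    noise_floor_fraction: float = 0.01   # of the series max; below -> TIA 0
    uptake_model: str = "ramp_from_zero"
    half_life_h: float | None = None     # enables the physical-decay fallback
    warn_slower_than_physical_fraction: float = 0.05


def tia_map(series: TimeSeriesVolume, cal: CalibrationFactor,
            config: TiaConfig | None = None) -> Volume3D:
    """Per-voxel TIA map (MBq·s) from a co-registered count series.

    Counts are converted to MBq through the calibration factor; each voxel
    whose peak exceeds the noise floor gets a decay fit plus trapezoid-and-tail
    integral.  Identical time-activity vectors are fitted once (a large saving
    on piecewise-uniform synthetic data).  Scaling all inputs by k scales the
    map by k: the noise floor is relative, and the fit/integral are homogeneous.
    """
    config = config or TiaConfig()
    times = np.asarray(series.times_h, dtype=float)
    for v in series.volumes:
        if v.acquisition_time_h is None:
            raise GeometryError("every volume in the series needs an acquisition time")
    stack = series.stack() * cal.mbq_per_count      # (T, nx, ny, nz) MBq
    peak = stack.max(axis=0)
    floor = config.noise_floor_fraction * stack.max()
    active = peak >= max(floor, 0.0)
    if floor > 0:
        active &= peak > 0

    tia = np.zeros(stack.shape[1:])
    if active.any():
        tacs = stack[:, active].T                   # (N, T)
        uniq, inverse = np.unique(tacs, axis=0, return_inverse=True)
        vals = np.empty(len(uniq))
        slow_count = 0
        lam_phys = (np.log(2.0) / config.half_life_h) if config.half_life_h else None
        for i, tac in enumerate(uniq):
            fit = fit_decay_double_exp(times, tac, half_life_h=config.half_life_h)
            vals[i] = integrate_tac(times, tac, fit, uptake_model=config.uptake_model) * 3600.0
            if lam_phys is not None:
                lam_eff = min(fit.lambda1, fit.lambda2) if fit.A2 > 0 else fit.lambda1
                # a fit pinned at the physical lower bound means the data asked
                # for slower-than-physical decay
                if lam_eff <= 1.001 * lam_phys:
                    slow_count += 1
        if lam_phys is not None and slow_count > config.warn_slower_than_physical_fraction * len(uniq):
            logger.warning(
                "%d of %d fitted voxels decay slower than physical decay "
                "(half-life %.3g h)", slow_count, len(uniq), config.half_life_h,
            )
        tia[active] = vals[inverse]

    ref = series.volumes[0]
    out = ref.with_values(tia, value_kind=ValueKind.TIA_MBQ_S, acquisition_time_h=None)
    return out
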