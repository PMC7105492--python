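"""Stimulus-evoked current and field-potential analysis.

Decomposes astrocytic responses to Schaffer-collateral stimulation into the
fast glutamate-transporter current (I_GluT) and the slow potassium current
(I_K), and quantifies neuronal measures: NMDAR-EPSC charge transfer, input
resistance from a voltage step, input-output curves, and LTP magnitude.

Conventions: currents are stored signed with inward deflections negative;
reported amplitudes are magnitudes of the inward deflection.  The response to
the fifth stimulus of a 5 x 50 Hz train is isolated by subtracting the
4-stimulus trace from the 5-stimulus trace.  I_K amplitude is measured from
200 ms after the last stimulus (where it is no longer contaminated by I_GluT
or the field-potential transient), falling back to the value at +200 ms when
no later extremum exists, and its decay is fitted mono-exponentially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

__all__ = [
    "SweepSet",
    "MonoExpFit",
    "IKMeasure",
    "ChargeResult",
    "LTPResult",
    "baseline_subtract_average",
    "isolate_fifth_response",
    "measure_ik",
    "fit_monoexp",
    "reconstruct_residual_ik",
    "extract_iglut",
    "input_resistance",
    "epsc_charge",
    "charge_fractions",
    "ltp_magnitude",
    "input_output",
]


@dataclass
class SweepSet:
    """Stimulus-locked sweeps grouped by condition.

    ``traces`` maps a condition label (e.g. ``"1"``, ``"4"``, ``"5"``,
    ``"tboa"``) to an array of shape (n_sweeps, n_samples); all conditions
    share one sampling rate and time base.  ``stim_times_s`` lists the
    stimulus times of each condition and ``baseline_window_s`` the pre-stimulus
    window used for baseline subtraction.
    """

    traces: dict[str, np.ndarray]
    sampling_rate_hz: float
    stim_times_s: dict[str, np.ndarray]
    baseline_window_s: tuple[float, float]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {np.atleast_2d(v).shape[1] for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError(f"traces have mismatched lengths: {sorted(lengths)}")
        lo, hi = self.baseline_window_s
        stims = [t[0] for t in self.stim_times_s.values() if len(t)]
        if stims and hi > min(stims):
            raise ValueError("baseline window must precede the first stimulus")

    @property
    def n_samples(self) -> int:
        return next(iter(np.atleast_2d(v).shape[1] for v in self.traces.values()))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def index(self, t_s: float) -> int:
        return int(round(t_s * self.sampling_rate_hz))


@dataclass
class MonoExpFit:
    """Result of a mono-exponential fit y = A exp(-t/tau) + C."""

    amplitude: float
    tau_s: float
    offset: float
    converged: bool
    message: str = ""
    r_squared: float = np.nan
    tau_ci_s: tuple[float, float] = (np.nan, np.nan)

    @property
    def tau_ms(self) -> float:
        return self.tau_s * 1000.0


@dataclass
class IKMeasure:
    """Amplitude and decay of the slow potassium current."""

    amplitude_pa: float  # magnitude of the inward deflection
    amplitude_signed_pa: float
    t_amplitude_s: float
    used_fallback: bool  # True when no extremum after +200 ms: value at +200 ms
    decay_fit: MonoExpFit | None = None

    @property
    def tau_decay_ms(self) -> float:
        return np.nan if self.decay_fit is None else self.decay_fit.tau_ms


@dataclass
class ChargeResult:
    """Charge transfer (trapezoidal area under the baseline-subtracted
    current) over the peaks window and the tail window, in pA*s."""

    q_peaks_pas: float
    q_tail_pas: float
    peaks_window_s: tuple[float, float]
    tail_window_s: tuple[float, float]


@dataclass
class LTPResult:
    """Normalized fEPSP time course (% of baseline, baseline mean = 100%) and
    LTP magnitude over the analysis window."""

    times_min: np.ndarray
    normalized_pct: np.ndarray
    magnitude_pct: float
    window_min: tuple[float, float]  # relative to HFS


# --------------------------------------------------------------------------
# averaging and subtraction
# --------------------------------------------------------------------------

def baseline_subtract_average(sweeps: SweepSet) -> SweepSet:
    """Per-condition mean sweep minus its mean over the baseline window."""
    lo, hi = sweeps.baseline_window_s
    i0, i1 = sweeps.index(lo), max(sweeps.index(hi), sweeps.index(lo) + 1)
    out = {}
    for cond, arr in sweeps.traces.items():
        mean = np.atleast_2d(arr).mean(axis=0)
        out[cond] = (mean - mean[i0:i1].mean())[None, :]
    return SweepSet(out, sweeps.sampling_rate_hz, dict(sweeps.stim_times_s),
                    sweeps.baseline_window_s, sweeps.ground_truth)


def isolate_fifth_response(trace5: np.ndarray, trace4: np.ndarray) -> np.ndarray:
    """Pointwise difference: (5-stimulus trace) - (4-stimulus trace).

    For linearly superposed responses this is exactly the fifth-stimulus
    component.
    """
    trace5, trace4 = np.ravel(trace5), np.ravel(trace4)
    if trace5.shape != trace4.shape:
        raise ValueError("trace length mismatch")
    return trace5 - trace4


# --------------------------------------------------------------------------
# mono-exponential fitting
# --------------------------------------------------------------------------

def fit_monoexp(t_s: np.ndarray, y: np.ndarray, with_offset: bool = True,
                max_nfev: int = 10000) -> MonoExpFit:
    """Nonlinear least squares of y = A exp(-t/tau) (+ C).

    Initialized from a log-linear regression on the offset-corrected segment.
    Non-convergence (or an unphysical tau) is flagged on the returned record,
    never silently replaced.
    """
    t_s = np.asarray(t_s, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_s.size < 10:
        raise ValueError("need at least 10 samples for a mono-exponential fit")
    t0 = t_s[0]
    ts = t_s - t0

    c0 = float(np.mean(y[-max(3, y.size // 10):])) if with_offset else 0.0
    a0 = float(y[0] - c0)
    span = max(ts[-1], np.finfo(float).eps)
    # log-linear initialization on samples of consistent sign
    resid = (y - c0) * np.sign(a0 if a0 != 0 else 1.0)
    ok = resid > 0
    tau0 = span / 3.0
    if ok.sum() >= 3:
        slope = np.polyfit(ts[ok], np.log(resid[ok]), 1)[0]
        if slope < 0:
            tau0 = float(np.clip(-1.0 / slope, span / 200.0, span * 50.0))

    def model(t, a, tau, c=0.0):
        return a * np.exp(-t / tau) + c

    p0 = [a0 if a0 != 0 else 1.0, tau0] + ([c0] if with_offset else [])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, ts, y, p0=p0, maxfev=max_nfev,
                                   xtol=1e-8, ftol=1e-8)
        a, tau = popt[0], popt[1]
        c = popt[2] if with_offset else 0.0
        perr = np.sqrt(np.diag(pcov))
        tau_sd = perr[1]
        yhat = model(ts, *popt)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum((y - yhat) ** 2) / sst if sst > 0 else np.nan
        converged = bool(np.isfinite(tau) and tau > 0 and np.isfinite(tau_sd))
        msg = "" if converged else "fit did not converge to a positive tau"
        return MonoExpFit(float(a), float(tau), float(c), converged, msg, float(r2),
                          (float(tau - 1.96 * tau_sd), float(tau + 1.96 * tau_sd)))
    except RuntimeError as exc:
        return MonoExpFit(np.nan, np.nan, np.nan, False, str(exc))


# --------------------------------------------------------------------------
# potassium current
# --------------------------------------------------------------------------

def _smooth(y: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    n = max(int(round(window_s * fs)), 1)
    return ndimage.uniform_filter1d(y, n) if n > 1 else y.copy()


def measure_ik(trace: np.ndarray, fs: float, last_stim_s: float,
               search_delay_s: float = 0.2, smooth_s: float = 0.02,
               fit_decay: bool = True) -> IKMeasure:
    """I_K amplitude and decay time constant.

    The amplitude is the extremum of the (lightly smoothed) current in
    [last stimulus + ``search_delay_s``, end of sweep].  If the current only
    decays over that window — no extremum beyond its first sample — the value
    at +``search_delay_s`` is taken instead (fallback).  The decay from the
    amplitude point is fitted mono-exponentially.
    """
    trace = np.ravel(trace)
    i0 = int(round((last_stim_s + search_delay_s) * fs))
    if i0 >= trace.size - 10:
        raise ValueError("trace does not extend far enough past the last stimulus")
    s = _smooth(trace, fs, smooth_s)
    win = s[i0:]
    i_ext = int(np.argmax(np.abs(win)))
    used_fallback = i_ext == 0
    amp_signed = float(win[i_ext])
    t_amp = (i0 + i_ext) / fs

    decay_fit = None
    if fit_decay:
        seg = trace[i0 + i_ext:]
        t_seg = np.arange(seg.size) / fs
        if seg.size >= 10:
            decay_fit = fit_monoexp(t_seg, seg)
    return IKMeasure(abs(amp_signed), amp_signed, t_amp, used_fallback, decay_fit)


# --------------------------------------------------------------------------
# transporter current
# --------------------------------------------------------------------------

def reconstruct_residual_ik(trace: np.ndarray, fs: float, stim_time_s: float,
                            smooth_s: float = 0.004) -> np.ndarray:
    """Smooth reconstruction of the transporter-insensitive residual current.

    The single-stimulus response recorded under glutamate-transporter
    blockade is reduced to a noise-free wave: a saturating mono-exponential
    ``peak * (1 - exp(-(t - t0)/tau_rise))`` fitted to the rise (10-90% of
    peak) spliced at the empirical peak to a mono-exponential (+offset)
    fitted to the decay.  Both limbs are tied to the peak value, so the
    splice is exactly continuous.  A zero trace reconstructs to zero.
    """
    trace = np.ravel(trace)
    n = trace.size
    i_stim = int(round(stim_time_s * fs))
    s = _smooth(trace, fs, smooth_s)
    post = s[i_stim:]
    if post.size < 20:
        raise ValueError("trace too short after the stimulus")
    i_peak_rel = int(np.argmax(np.abs(post)))
    peak = float(post[i_peak_rel])
    if peak == 0.0:
        return np.zeros(n)
    if i_peak_rel == 0:
        raise ValueError("no identifiable peak after the stimulus")
    i_peak = i_stim + i_peak_rel
    t_peak = i_peak / fs

    # saturating mono-exponential through the 10-90% rise segment
    mag = np.abs(s[i_stim:i_peak])
    idx = np.nonzero((mag >= 0.1 * abs(peak)) & (mag <= 0.9 * abs(peak)))[0]
    tau0 = max(i_peak_rel / fs / 3.0, 1.0 / fs)
    t00 = 0.0

    def rise_model(t, t0, tau):
        return abs(peak) * -np.expm1(-np.maximum(t - t0, 0.0) / tau)

    if idx.size >= 3:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(rise_model, idx / fs, mag[idx],
                                    p0=[t00, tau0], maxfev=10000)
            if popt[1] > 0:
                t00, tau0 = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass
    tau_rise, t0_rise = tau0, t00

    decay_seg = trace[i_peak:]
    t_seg = np.arange(decay_seg.size) / fs
    dfit = fit_monoexp(t_seg, decay_seg)
    if not dfit.converged:
        raise ValueError(f"decay fit failed: {dfit.message or 'not converged'}")

    t = np.arange(n) / fs
    out = np.zeros(n)
    pre = (t >= stim_time_s) & (t < t_peak)
    # rescaled so the rise limb reaches exactly the empirical peak at t_peak
    denom = -np.expm1(-max(t_peak - stim_time_s - t0_rise, 1.0 / fs) / tau_rise)
    rel = -np.expm1(-np.maximum(t[pre] - stim_time_s - t0_rise, 0.0) / tau_rise)
    out[pre] = peak * rel / max(denom, np.finfo(float).tiny)
    post_m = t >= t_peak
    # amplitude tied to the empirical peak so both limbs meet exactly
    out[post_m] = (peak - dfit.offset) * np.exp(-(t[post_m] - t_peak) / dfit.tau_s) \
        + dfit.offset
    return out


def extract_iglut(trace: np.ndarray, residual: np.ndarray, fs: float,
                  stim_time_s: float, residual_stim_time_s: float | None = None,
                  smooth_s: float = 0.001,
                  decay_window_s: float | None = 0.1) -> tuple[np.ndarray, IKMeasure]:
    """Pure transporter current: recorded trace minus the reconstructed
    residual potassium wave (time-shifted to the stimulus of interest).

    Returns the subtracted trace and an amplitude/decay measurement taken at
    its extremum after the stimulus.  The decay is fitted over
    ``decay_window_s`` after the extremum (transporter decays last ~10 ms;
    a bounded window keeps the fit conditioned on the transient rather than
    the long flat tail); pass ``None`` to fit to the end of the sweep.
    """
    trace, residual = np.ravel(trace), np.ravel(residual)
    if trace.shape != residual.shape:
        raise ValueError("trace length mismatch")
    if residual_stim_time_s is not None:
        shift = int(round((stim_time_s - residual_stim_time_s) * fs))
        residual = np.roll(residual, shift)
        if shift > 0:
            residual[:shift] = 0.0
        elif shift < 0:
            residual[shift:] = 0.0
    pure = trace - residual

    i_stim = int(round(stim_time_s * fs))
    s = _smooth(pure, fs, smooth_s)
    post = s[i_stim:]
    i_ext = int(np.argmax(np.abs(post)))
    amp_signed = float(post[i_ext])
    i_end = pure.size if decay_window_s is None \
        else min(pure.size, i_stim + i_ext + int(round(decay_window_s * fs)))
    seg = pure[i_stim + i_ext:i_end]
    decay = fit_monoexp(np.arange(seg.size) / fs, seg) if seg.size >= 10 else None
    measure = IKMeasure(abs(amp_signed), amp_signed, (i_stim + i_ext) / fs,
                        False, decay)
    return pure, measure


# --------------------------------------------------------------------------
# input resistance
# --------------------------------------------------------------------------

def input_resistance(trace: np.ndarray, fs: float,
                     step_window_s: tuple[float, float], dv_mv: float = -5.0,
                     steady_s: float = 0.02, settle_tol: float = 0.02):
    """Input resistance from a voltage-step current response: R = dV / dI.

    dI is the steady-state plateau (mean over the last ``steady_s`` of the
    step) minus the pre-step baseline.  The plateau is checked for settling:
    a residual linear drift exceeding ``settle_tol`` x |dI| over the window is
    flagged.  Returns ``(r_mohm, di_pa, settled)``.
    """
    trace = np.ravel(trace)
    t_on, t_off = step_window_s
    i_on, i_off = int(round(t_on * fs)), int(round(t_off * fs))
    n_st = int(round(steady_s * fs))
    if n_st < 5 or i_off - i_on < n_st:
        raise ValueError("steady-state region must contain >= 5 samples")
    baseline = trace[:i_on].mean()
    plateau = trace[i_off - n_st:i_off]
    di_pa = float(plateau.mean() - baseline)
    if di_pa == 0.0:
        raise ValueError("zero current step")
    drift = np.polyfit(np.arange(n_st) / fs, plateau, 1)[0] * steady_s
    settled = bool(abs(drift) <= settle_tol * abs(di_pa))
    r_mohm = dv_mv / (di_pa / 1000.0)  # mV / nA = MΩ
    return float(r_mohm), di_pa, settled


# --------------------------------------------------------------------------
# EPSC charge transfer
# --------------------------------------------------------------------------

def epsc_charge(trace: np.ndarray, fs: float,
                peaks_window_s: tuple[float, float],
                tail_window_s: tuple[float, float],
                baseline_window_s: tuple[float, float]) -> ChargeResult:
    """Charge transfer (trapezoidal AUC of the baseline-subtracted current)
    over the peaks region and the tail region of a burst-evoked EPSC."""
    trace = np.ravel(trace)
    t_end = trace.size / fs
    for lo, hi in (peaks_window_s, tail_window_s, baseline_window_s):
        if not 0.0 <= lo < hi <= t_end + 1e-9:
            raise ValueError(f"window ({lo}, {hi}) out of range")
    if peaks_window_s[1] > tail_window_s[0]:
        raise ValueError("peaks and tail windows overlap")

    b0, b1 = (int(round(v * fs)) for v in baseline_window_s)
    y = trace - trace[b0:b1].mean()

    def auc(win):
        # inclusive right edge, so adjacent windows tile the trace exactly
        i0, i1 = int(round(win[0] * fs)), int(round(win[1] * fs))
        return float(np.trapezoid(y[i0:min(i1 + 1, y.size)], dx=1.0 / fs))

    return ChargeResult(auc(peaks_window_s), auc(tail_window_s),
                        tuple(peaks_window_s), tuple(tail_window_s))


def charge_fractions(drug: ChargeResult, untreated: ChargeResult) -> dict[str, float]:
    """Drug-condition charge as percent of the untreated charge, per window."""
    return {
        "peaks_pct": 100.0 * drug.q_peaks_pas / untreated.q_peaks_pas,
        "tail_pct": 100.0 * drug.q_tail_pas / untreated.q_tail_pas,
    }


# --------------------------------------------------------------------------
# LTP and input-output
# --------------------------------------------------------------------------

def ltp_magnitude(times_min: np.ndarray, amplitudes: np.ndarray,
                  hfs_time_min: float, baseline_minutes: float = 15.0,
                  window_min: tuple[float, float] = (50.0, 60.0)) -> LTPResult:
    """LTP magnitude: potentiated fEPSP amplitude as percent of baseline.

    Amplitudes are normalized so that the mean over the ``baseline_minutes``
    before HFS equals 100%; the magnitude is the mean normalized amplitude
    over ``window_min`` (minutes after HFS; the 50-60 min window is the
    default, the 40-50 min variant is selectable).
    """
    times_min = np.asarray(times_min, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if window_min[0] < 0 or window_min[1] <= window_min[0]:
        raise ValueError("analysis window must follow the HFS")
    base = (times_min >= hfs_time_min - baseline_minutes) & (times_min < hfs_time_min)
    if not base.any():
        raise ValueError("no baseline samples before HFS")
    norm = 100.0 * amplitudes / amplitudes[base].mean()
    win = ((times_min >= hfs_time_min + window_min[0])
           & (times_min < hfs_time_min + window_min[1]))
    if not win.any():
        raise ValueError("no samples in the analysis window")
    return LTPResult(times_min, norm, float(norm[win].mean()), tuple(window_min))


def input_output(stim_ua: np.ndarray, amplitudes: np.ndarray,
                 group: np.ndarray | None = None) -> pd.DataFrame:
    """Input-output table: mean +- SEM response amplitude per stimulus level
    (optionally per group), sorted by stimulation current."""
    df = pd.DataFrame({"stim_ua": np.ravel(stim_ua), "amplitude": np.ravel(amplitudes)})
    keys = ["stim_ua"]
    if group is not None:
        df["group"] = np.ravel(group)
        keys = ["group", "stim_ua"]
    out = (df.groupby(keys)["amplitude"]
           .agg(mean="mean", sem=lambda x: x.sem() if len(x) > 1 else 0.0, n="count")
           .reset_index()
           .sort_values(keys, ignore_index=True))
    return out
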