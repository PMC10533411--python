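"""Receptor kinetics: desensitization decay, recovery, PPF and rectification.

All times are in ms and currents in pA.  Junction-potential and
series-resistance corrections are applied at acquisition, upstream of this
module.

Desensitization entry is fitted as one or two exponentials plus a
steady-state offset, over the window from the 90 %-of-peak crossing after
the current peak to the end of the agonist pulse.  Where two components are
used the amplitude-weighted time constant is reported:

    τ_w = τ_f · A_f / (A_f + A_s) + τ_s · A_s / (A_f + A_s)

Recovery from desensitization uses a two-pulse protocol: the ratio of test-
to conditioning-pulse peaks as a function of the inter-pulse interval t is
fitted with a single exponential, ratio(t) = 1 − (1 − r₀)·exp(−t/τ_rec),
with the intercept r₀ fitted (bounded to [0, 1)) rather than pinned.

Paired-pulse behaviour in a stimulus train is expressed by normalizing peak
amplitudes to the first response; the rectification index of the I–V
relation is −(I₊₄₀ − I₀)/(I₋₆₀ − I₀).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Exponential fit failed to converge or data were degenerate."""


@dataclass
class SweepTrace:
    """Uniformly sampled current sweep with its stimulus protocol."""

    time: np.ndarray  # ms, uniform grid, strictly increasing
    current: np.ndarray  # pA
    protocol: list  # [(pulse_onset_ms, pulse_duration_ms), ...]
    baseline_window: tuple  # (t0_ms, t1_ms)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.current = np.asarray(self.current, float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be matching 1-D arrays")
        dt = np.diff(self.time)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class DecayFit:
    tau_f: float  # ms
    tau_s: float  # ms
    A_f: float  # pA (amplitude at the peak time)
    A_s: float  # pA
    tau_w: float  # ms
    n_components: int
    fit_window: tuple  # (t_start_ms, t_end_ms)
    residual_rms: float  # pA
    offset: float = 0.0  # steady-state current, pA

    def __post_init__(self) -> None:
        if self.tau_f > self.tau_s + 1e-12:
            raise ValueError("tau_f must be <= tau_s")
        if self.A_f * self.A_s < 0:
            raise ValueError("amplitudes must have equal sign")
        lo, hi = min(self.tau_f, self.tau_s), max(self.tau_f, self.tau_s)
        if not (lo - 1e-9 <= self.tau_w <= hi + 1e-9):
            raise ValueError("tau_w must lie between tau_f and tau_s")


@dataclass
class RecoveryFit:
    intervals: np.ndarray  # ms
    ratios: np.ndarray  # second/first peak
    tau_rec: float  # ms
    r0: float  # fitted zero-interval intercept
    residual_rms: float

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, float)
        self.ratios = np.asarray(self.ratios, float)
        if np.any(self.ratios < 0) or np.any(self.ratios > 1.2):
            raise ValueError("peak ratios outside [0, 1.2]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")


def weighted_tau(tau_f: float, A_f: float, tau_s: float, A_s: float) -> float:
    """Amplitude-weighted mean of fast and slow decay time constants."""
    if tau_f <= 0 or tau_s <= 0:
        raise ValueError("time constants must be positive")
    total = A_f + A_s
    if total == 0:
        raise ValueError("total amplitude A_f + A_s must be nonzero")
    return tau_f * (A_f / total) + tau_s * (A_s / total)


def _baseline(trace: SweepTrace) -> tuple[float, float]:
    t0, t1 = trace.baseline_window
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    seg = trace.current[mask]
    return float(seg.mean()), float(seg.std())


def pulse_peaks(trace: SweepTrace) -> np.ndarray:
    """Baseline-subtracted signed peak amplitude within each protocol pulse.

    The peak is the extremum of the baseline-subtracted current inside the
    pulse window, with the sign of the larger |extremum|.
    """
    base, _ = _baseline(trace)
    sig = trace.current - base
    peaks = []
    for onset, duration in trace.protocol:
        mask = (trace.time >= onset) & (trace.time <= onset + duration)
        if not mask.any():
            raise ValueError(f"pulse at {onset} ms lies outside the trace")
        seg = sig[mask]
        peaks.append(seg[np.argmax(np.abs(seg))])
    return np.asarray(peaks, float)


def _multiexp_residual(params, t, y, n_components):
    offset = params[0]
    model = np.full_like(t, offset)
    for i in range(n_components):
        A, tau = params[1 + 2 * i], params[2 + 2 * i]
        model = model + A * np.exp(-t / tau)
    return model - y


def fit_decay(trace: SweepTrace, n_components: int = 2) -> DecayFit:
    """Fit the desensitization decay of the conditioning pulse.

    The fit window runs from the first sample after the peak at which the
    baseline-subtracted current has fallen to 90 % of the peak, to the end
    of the pulse.  Exponential amplitudes are referenced to the peak time,
    so noiseless model-class data are recovered exactly.  Bounded least
    squares with three deterministic starts guards against the
    bi-exponential identifiability trap.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if not trace.protocol:
        raise ValueError("trace has no stimulus protocol")
    onset, duration = trace.protocol[0]
    base, base_sd = _baseline(trace)
    sig = trace.current - base
    mask = (trace.time >= onset) & (trace.time <= onset + duration)
    if not mask.any():
        raise ValueError("conditioning pulse lies outside the trace")
    idx = np.nonzero(mask)[0]
    seg = sig[idx]
    peak_local = int(np.argmax(np.abs(seg)))
    peak = float(seg[peak_local])
    threshold = 5.0 * base_sd
    if abs(peak) <= threshold or peak == 0.0:
        raise FitError(
            f"no detectable peak (|peak| = {abs(peak):.3g} pA, "
            f"5 x baseline SD = {threshold:.3g} pA)"
        )
    after = np.abs(seg[peak_local:])
    below = np.nonzero(after <= 0.9 * abs(peak))[0]
    if below.size == 0 or idx[peak_local] + below[0] >= idx[-1]:
        raise FitError("current never decays to 90% of peak within the pulse")
    start = idx[peak_local] + below[0]
    t_peak = trace.time[idx[peak_local]]
    t = trace.time[start : idx[-1] + 1] - t_peak
    y = sig[start : idx[-1] + 1]

    window = float(t[-1] - t[0]) if t[-1] > t[0] else duration
    sign = np.sign(peak)
    # amplitude bounds keep both components on the side of the peak
    if sign > 0:
        amp_lo, amp_hi = 0.0, np.inf
    else:
        amp_lo, amp_hi = -np.inf, 0.0
    offset0 = float(y[-1])
    amp0 = peak - offset0

    starts = []
    for tf_frac, ts_frac, split in ((0.1, 1.0, 0.7), (0.05, 0.5, 0.5), (0.3, 2.0, 0.9)):
        if n_components == 1:
            starts.append([offset0, amp0, max(tf_frac * window, trace.dt)])
        else:
            starts.append(
                [
                    offset0,
                    split * amp0,
                    max(tf_frac * window, trace.dt),
                    (1 - split) * amp0,
                    max(ts_frac * window, trace.dt),
                ]
            )
    tau_lo, tau_hi = trace.dt / 10.0, 100.0 * window
    if n_components == 1:
        lb = [-np.inf, amp_lo, tau_lo]
        ub = [np.inf, amp_hi, tau_hi]
    else:
        lb = [-np.inf, amp_lo, tau_lo, amp_lo, tau_lo]
        ub = [np.inf, amp_hi, tau_hi, amp_hi, tau_hi]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(
                _multiexp_residual,
                x0,
                bounds=(lb, ub),
                args=(t, y, n_components),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except ValueError as exc:
            raise FitError(f"decay fit failed: {exc}") from exc
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("decay fit did not converge from any start")

    offset = float(best.x[0])
    if n_components == 1:
        A, tau = float(best.x[1]), float(best.x[2])
        tau_f = tau_s = tau
        A_f, A_s = A, 0.0
    else:
        A1, tau1, A2, tau2 = map(float, best.x[1:5])
        if tau1 <= tau2:
            (A_f, tau_f), (A_s, tau_s) = (A1, tau1), (A2, tau2)
        else:
            (A_f, tau_f), (A_s, tau_s) = (A2, tau2), (A1, tau1)
    if A_f + A_s == 0:
        raise FitError("degenerate fit: zero total amplitude")
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return DecayFit(
        tau_f=tau_f,
        tau_s=tau_s,
        A_f=A_f,
        A_s=A_s,
        tau_w=weighted_tau(tau_f, A_f, tau_s, A_s),
        n_components=n_components,
        fit_window=(float(trace.time[start]), float(trace.time[idx[-1]])),
        residual_rms=rms,
        offset=offset,
    )


def fit_recovery(pairs) -> RecoveryFit:
    """Single-exponential fit of peak-ratio recovery vs inter-pulse interval.

    ``pairs`` is a sequence of (interval_ms, second/first peak ratio).  The
    model is ratio(t) = 1 − (1 − r₀)·exp(−t/τ_rec); τ_rec and the intercept
    r₀ are fitted, r₀ bounded to [0, 1).
    """
    arr = np.asarray(list(pairs), float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need >= 4 (interval, ratio) pairs")
    t = arr[:, 0]
    r = arr[:, 1]
    if np.any(t <= 0):
        raise ValueError("intervals must be positive")
    if np.all(np.abs(r - 1.0) < 1e-3):
        raise FitError("all ratios ~ 1: response already recovered, tau undefined")

    def residual(params):
        tau, r0 = params
        return (1.0 - (1.0 - r0) * np.exp(-t / tau)) - r

    span = float(t.max() - t.min())
    r0_init = float(np.clip(r.min(), 0.0, 0.95))
    best = None
    for tau0 in (span / 5.0, span / 2.0, 2.0 * span):
        res = least_squares(
            residual,
            [tau0, r0_init],
            bounds=([1e-6, 0.0], [np.inf, 1.0 - 1e-9]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    tau_rec, r0 = map(float, best.x)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return RecoveryFit(
        intervals=t, ratios=r, tau_rec=tau_rec, r0=r0, residual_rms=rms
    )


def ppf_normalize(peaks, stim_freq: float = 20.0) -> np.ndarray:
    """Peak amplitudes of a stimulus train normalized to the first response."""
    peaks = np.asarray(peaks, float)
    if peaks.ndim != 1 or len(peaks) < 2:
        raise ValueError("need >= 2 peaks")
    if peaks[0] == 0:
        raise ValueError("first peak is zero; normalization undefined")
    if stim_freq <= 0:
        raise ValueError("stimulation frequency must be positive")
    return peaks / peaks[0]


def rectification_index(i_minus60: float, i_0: float, i_plus40: float) -> float:
    """Rectification index −(I₊₄₀ − I₀)/(I₋₆₀ − I₀) of an I–V relation."""
    denom = i_minus60 - i_0
    if denom == 0:
        raise ValueError("I(-60 mV) equals I(0 mV); rectification index undefined")
    return -(i_plus40 - i_0) / denom
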