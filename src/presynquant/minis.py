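"""Detection and kinetic analysis of miniature postsynaptic currents.

Miniature events (mEPSC/mIPSC, recorded in TTX) are detected on a
voltage-clamp trace as inward (negative) deflections from a running local
baseline that exceed both an amplitude threshold and an area threshold,
mirroring the classical peak-detector approach of MiniAnalysis-style tools.
Thresholds default to data-driven values: 5x the robust (MAD-based) noise SD
for amplitude, and amplitude x 1 ms for area.

Event kinetics follow standard conventions: 10-90% rise time on the rising
phase and a single-exponential time constant fitted to the 10-90% segment of
the decay.  Time-course summaries (e.g. a 2 min baseline followed by three
5 min windows after a chelator such as BAPTA-AM is washed in) are normalised
to the first window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .io import DataError, Trace

__all__ = [
    "MiniEvent",
    "MiniStats",
    "robust_noise_sd",
    "detect_minis",
    "event_kinetics",
    "mini_stats",
    "mini_timecourse",
]

#: default running-baseline window, s
BASELINE_WINDOW = 0.050
#: default pre-detection boxcar smoothing, s (short vs the ~5 ms decay of a PSC)
SMOOTH_WINDOW = 0.0005
#: a new event requires the signal to have returned below this fraction of the
#: previous peak (refractory rule for overlapping events)
REFRACTORY_FRACTION = 0.5
#: onset / decay-end crossing level as a fraction of peak
ONSET_FRACTION = 0.1


@dataclass(frozen=True)
class MiniEvent:
    """A single detected miniature event.  Amplitude is the unsigned
    deflection from local baseline; kinetics may be NaN when a fit failed or
    the event is clipped by the trace edge (``kinetics_valid`` False)."""

    onset_t: float
    peak_t: float
    amplitude: float
    area: float
    rise_10_90: float = float("nan")
    decay_tau: float = float("nan")
    kinetics_valid: bool = False

    def __post_init__(self) -> None:
        if self.peak_t < self.onset_t:
            raise DataError("peak before onset")
        if not self.amplitude > 0 or not self.area > 0:
            raise DataError("event amplitude and area must be positive")


@dataclass(frozen=True)
class MiniStats:
    """Per-cell (or per-window) summary of miniature activity."""

    frequency: float
    mean_amplitude: float
    median_amplitude: float
    n_events: int
    duration: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise DataError("duration must be positive")


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimated as 1.4826 * MAD, insensitive to sparse events."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _running_baseline(x: np.ndarray, window: int) -> np.ndarray:
    """Median over the preceding ``window`` samples (causal, event-robust)."""
    s = pd.Series(x)
    base = s.rolling(window, min_periods=1).median().shift(1).to_numpy()
    base[0] = x[0]
    return base


def detect_minis(
    trace: Trace,
    amp_threshold: float | None = None,
    area_threshold: float | None = None,
    baseline_window: float = BASELINE_WINDOW,
    smooth_window: float = SMOOTH_WINDOW,
    polarity: int = -1,
) -> list[MiniEvent]:
    """Detect miniature events on a continuous recording.

    Parameters
    ----------
    amp_threshold
        Minimum unsigned amplitude in pA.  Default: 5x robust noise SD.
    area_threshold
        Minimum event area in pA*ms.  Default: ``amp_threshold`` * 1 ms.
    baseline_window
        Length (s) of the causal running-median baseline.
    polarity
        -1 for inward (negative) currents at -70 mV, +1 for outward.

    Returns events satisfying both thresholds, non-overlapping at their
    peaks: after an accepted peak the deflection must fall below 50% of that
    peak before a new event can be accepted.
    """
    if trace.duration <= baseline_window:
        raise DataError("trace shorter than baseline window")
    x = trace.samples
    w = max(2, int(round(baseline_window / trace.dt)))
    baseline = _running_baseline(x, w)
    # deflection is positive in the direction of events
    d = polarity * (x - baseline)
    k = max(1, int(round(smooth_window / trace.dt)))
    d_s = np.convolve(d, np.ones(k) / k, mode="same") if k > 1 else d

    if amp_threshold is None:
        amp_threshold = 5.0 * robust_noise_sd(d)
    if amp_threshold <= 0:
        raise DataError("amp_threshold must be positive")
    if area_threshold is None:
        area_threshold = amp_threshold * 1.0  # pA * 1 ms
    if area_threshold <= 0:
        raise DataError("area_threshold must be positive")

    min_dist = max(1, int(round(0.002 / trace.dt)))  # peaks >= 2 ms apart
    # prominence (not just height) rejects noise bumps riding an event's decay
    peaks, _ = find_peaks(
        d_s, height=amp_threshold, prominence=amp_threshold, distance=min_dist
    )

    events: list[MiniEvent] = []
    prev_peak_idx: int | None = None
    prev_height = 0.0
    for p in peaks:
        if prev_peak_idx is not None:
            if np.min(d_s[prev_peak_idx : p + 1]) > REFRACTORY_FRACTION * prev_height:
                continue  # still riding the previous event
        height = d_s[p]
        # onset: walk back to the last crossing below ONSET_FRACTION of peak
        level = ONSET_FRACTION * height
        seg = d_s[:p]
        below = np.nonzero(seg < level)[0]
        onset_idx = int(below[-1]) + 1 if below.size else 0
        # amplitude from the unsmoothed deflection near the smoothed peak
        lo, hi = max(0, p - k), min(d.size, p + k + 1)
        amp = float(np.max(d[lo:hi]))
        # area until the deflection returns below the onset level (or 100 ms)
        end_cap = min(d.size, p + int(round(0.1 / trace.dt)))
        after = np.nonzero(d_s[p:end_cap] < level)[0]
        end_idx = p + int(after[0]) if after.size else end_cap
        area = float(np.trapezoid(d[onset_idx:end_idx], dx=trace.dt)) * 1e3  # pA*ms
        if amp < amp_threshold or area < area_threshold:
            continue
        events.append(
            MiniEvent(
                onset_t=trace.t0 + onset_idx * trace.dt,
                peak_t=trace.t0 + p * trace.dt,
                amplitude=amp,
                area=area,
            )
        )
        prev_peak_idx, prev_height = p, height
    return events


def _exp_decay(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * np.exp(-t / tau)


def event_kinetics(
    trace: Trace,
    event: MiniEvent,
    baseline_window: float = BASELINE_WINDOW,
    polarity: int = -1,
    max_decay_window: float = 0.1,
) -> MiniEvent:
    """Fill 10-90% rise time and single-exponential decay tau of one event.

    The decay tau comes from a least-squares fit of ``A*exp(-t/tau)`` to the
    segment of the falling phase between 90% and 10% of the peak.  If either
    crossing is clipped by the trace end or the fit fails, the event is
    returned with kinetics flagged missing rather than dropped.
    """
    i_peak = trace.index_at(event.peak_t)
    i_onset = trace.index_at(event.onset_t)
    w = max(2, int(round(baseline_window / trace.dt)))
    lo = max(0, i_onset - w)
    base = float(np.median(trace.samples[lo:i_onset])) if i_onset > lo else trace.samples[0]
    d = polarity * (trace.samples - base)
    peak_val = d[i_peak]
    if peak_val <= 0:
        return replace(event, kinetics_valid=False)

    # rise: last 10% upward crossing and following 90% crossing before peak
    rise = d[i_onset : i_peak + 1]
    t10 = _cross_time(rise, 0.1 * peak_val, trace.dt, forward=True)
    t90 = _cross_time(rise, 0.9 * peak_val, trace.dt, forward=True)
    rise_10_90 = (t90 - t10) * 1e3 if np.isfinite(t10) and np.isfinite(t90) else np.nan

    # decay segment: 90% -> 10% of peak after the peak
    i_end = min(trace.n, i_peak + int(round(max_decay_window / trace.dt)))
    fall = d[i_peak:i_end]
    below10 = np.nonzero(fall < 0.1 * peak_val)[0]
    if not below10.size:
        return replace(event, rise_10_90=rise_10_90, kinetics_valid=False)
    j10 = int(below10[0])
    below90 = np.nonzero(fall < 0.9 * peak_val)[0]
    j90 = int(below90[0]) if below90.size else 1
    if j10 - j90 < 3:
        return replace(event, rise_10_90=rise_10_90, kinetics_valid=False)
    seg = fall[j90:j10]
    t = np.arange(seg.size) * trace.dt
    tau0 = max((j10 - j90) * trace.dt / np.log(9.0), trace.dt)
    try:
        popt, _ = curve_fit(
            _exp_decay, t, seg, p0=[seg[0], tau0], maxfev=2000,
            bounds=([0, trace.dt * 0.1], [np.inf, np.inf]),
        )
    except (RuntimeError, ValueError):
        return replace(event, rise_10_90=rise_10_90, kinetics_valid=False)
    return replace(
        event,
        rise_10_90=float(rise_10_90),
        decay_tau=float(popt[1] * 1e3),
        kinetics_valid=bool(np.isfinite(rise_10_90)),
    )


def _cross_time(seg: np.ndarray, level: float, dt: float, forward: bool) -> float:
    """Linear-interpolated first (forward) crossing time of ``level``."""
    above = seg >= level
    idx = np.nonzero(above)[0]
    if not idx.size or idx[0] == 0:
        return 0.0 if idx.size else np.nan
    i = int(idx[0])
    y0, y1 = seg[i - 1], seg[i]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return (i - 1 + frac) * dt


def mini_stats(events: list[MiniEvent], duration: float) -> MiniStats:
    """Frequency / amplitude summary over a recording of known duration."""
    n = len(events)
    amps = np.array([e.amplitude for e in events]) if n else np.array([np.nan])
    return MiniStats(
        frequency=n / duration,
        mean_amplitude=float(np.mean(amps)),
        median_amplitude=float(np.median(amps)),
        n_events=n,
        duration=duration,
    )


def mini_timecourse(
    events: list[MiniEvent],
    windows: list[tuple[float, float]],
) -> pd.DataFrame:
    """Per-window frequency/amplitude, normalised to the first window.

    ``windows`` must be disjoint and ordered, e.g. a 2 min pre-treatment
    baseline followed by three 5 min windows: [(0, 120), (120, 420),
    (420, 720), (720, 1020)].  Normalised columns divide by window 1; if the
    first window contains no events its normalisation is undefined (NaN, with
    a warning).
    """
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if not (a0 < a1 <= b0 < b1):
            raise DataError("windows must be disjoint and ordered")
    if windows and not windows[0][0] < windows[0][1]:
        raise DataError("windows must be non-empty intervals")
    rows = []
    for i, (t0, t1) in enumerate(windows):
        in_w = [e for e in events if t0 <= e.peak_t < t1]
        st = mini_stats(in_w, t1 - t0)
        rows.append(
            {
                "window": i + 1,
                "t_start": t0,
                "t_end": t1,
                "n_events": st.n_events,
                "frequency_hz": st.frequency,
                "mean_amplitude_pa": st.mean_amplitude,
                "median_amplitude_pa": st.median_amplitude,
            }
        )
    df = pd.DataFrame(rows)
    f0 = df.loc[0, "frequency_hz"]
    a0 = df.loc[0, "mean_amplitude_pa"]
    if f0 == 0 or not np.isfinite(a0):
        warnings.warn("first window empty: normalisation undefined", stacklevel=2)
        df["frequency_norm"] = np.nan
        df["amplitude_norm"] = np.nan
    else:
        df["frequency_norm"] = df["frequency_hz"] / f0
        df["amplitude_norm"] = df["mean_amplitude_pa"] / a0
    return df
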