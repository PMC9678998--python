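"""Synaptophysin-pHluorin (sypHy) exo/endocytosis quantification.

sypHy fluorescence is quenched inside acidic vesicles and dequenched on
exocytosis, so a brief stimulus (20 AP @ 100 Hz) produces a step increase
whose normalised peak (dF/F0) indexes the readily releasable pool, and the
post-stimulus decay reports endocytosis plus re-acidification with a
mono-exponential time constant tau_endo:

    dF/F0(t) = (dF/F0)_inf + (dF/F0)_0 * exp(-t / tau)

F0 is the mean background-subtracted fluorescence over the 5 s preceding the
stimulus.  A terminal NH4Cl perfusion alkalinises all vesicles and gives the
total fluorescence Fmax for pool-fraction normalisation, and the ratio of
mean probe peaks after versus before a long conditioning train (600 AP @
20 Hz) measures pool recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io import DataError, ROISeries

__all__ = [
    "PhluorinResult",
    "EndocytosisFit",
    "dff",
    "fit_endocytosis",
    "rrp_recovery_ratio",
    "normalize_to_fmax",
]

#: default baseline used for F0, s before the first stimulus
F0_WINDOW = 5.0
#: default decay-fit window after the post-stimulus peak, s
DECAY_WINDOW = 90.0


@dataclass(frozen=True)
class EndocytosisFit:
    """Mono-exponential post-stimulus decay parameters."""

    tau_endo: float
    plateau_dff: float
    amplitude_dff: float
    r2: float = float("nan")
    valid: bool = True


@dataclass(frozen=True)
class PhluorinResult:
    """Per-ROI summary of one sypHy experiment."""

    F0: float
    peak_dff: float
    tau_endo: float
    plateau_dff: float
    Fmax: float = float("nan")
    recovery_ratio: float = float("nan")

    def __post_init__(self) -> None:
        if not self.F0 > 0:
            raise DataError("F0 must be positive")


def dff(
    roi: ROISeries,
    baseline_window: float = F0_WINDOW,
    background: float | np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Background-subtracted dF/F0 series and the F0 it used.

    F0 is the mean over the first ``baseline_window`` seconds after
    background subtraction; an F0 <= 0 (failed subtraction) raises.
    Returns ``(dff_series, F0)``.
    """
    bg = roi.F_background if background is None else background
    f = roi.F - np.asarray(bg, dtype=float)
    t = roi.frame_times
    mask = t < t[0] + baseline_window
    if not np.any(mask):
        raise DataError("no frames in the F0 baseline window")
    f0 = float(np.mean(f[mask]))
    if f0 <= 0:
        raise DataError("F0 <= 0 after background subtraction")
    return (f - f0) / f0, f0


def fit_endocytosis(
    frame_times: np.ndarray,
    dff_series: np.ndarray,
    post_stim_window: tuple[float, float] | None = None,
) -> EndocytosisFit:
    """Fit the post-stimulus dF/F0 decay with plateau + amp * exp(-t/tau).

    The segment starts at the post-stimulus peak (the maximum inside
    ``post_stim_window``, or the global maximum when no window is given) and
    runs to the window end (default peak + 90 s).  A non-decaying segment —
    fitted amplitude indistinguishable from zero or a best fit with the
    time constant pinned at the bound — is returned with ``valid=False``
    (tau unidentifiable) rather than raising.
    """
    t = np.asarray(frame_times, dtype=float)
    y = np.asarray(dff_series, dtype=float)
    if t.size != y.size:
        raise DataError("time and dF/F0 arrays must match")
    if post_stim_window is None:
        i_peak = int(np.argmax(y))
        t_end = t[i_peak] + DECAY_WINDOW
    else:
        in_w = (t >= post_stim_window[0]) & (t <= post_stim_window[1])
        if not np.any(in_w):
            raise DataError("no frames in post-stimulus window")
        i_peak = int(np.flatnonzero(in_w)[np.argmax(y[in_w])])
        t_end = post_stim_window[1]
    seg_mask = (t >= t[i_peak]) & (t <= t_end)
    ts = t[seg_mask] - t[i_peak]
    ys = y[seg_mask]
    if ts.size < 4:
        # peak at (or near) the last frame: a still-rising signal has no
        # decay segment, so tau is unidentifiable
        return EndocytosisFit(
            tau_endo=float("nan"), plateau_dff=float(y[-1]),
            amplitude_dff=0.0, valid=False,
        )

    def model(tt, plateau, amp, tau):
        return plateau + amp * np.exp(-tt / tau)

    plateau0 = float(np.mean(ys[-max(1, ys.size // 10):]))
    amp0 = max(float(ys[0] - plateau0), 1e-9)
    tau0 = max((ts[-1] - ts[0]) / 3.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            model, ts, ys, p0=[plateau0, amp0, tau0], maxfev=20000,
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, ValueError):
        return EndocytosisFit(
            tau_endo=float("nan"), plateau_dff=plateau0,
            amplitude_dff=0.0, valid=False,
        )
    plateau, amp, tau = popt
    resid = ys - model(ts, *popt)
    ss_tot = float(np.sum((ys - np.mean(ys)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    # identifiability guard: no decaying component, or increasing segment
    scale = max(abs(float(ys[0])), abs(plateau0), 1e-9)
    if amp < 1e-6 * scale or ys[-1] > ys[0]:
        return EndocytosisFit(
            tau_endo=float("nan"), plateau_dff=float(plateau),
            amplitude_dff=float(amp), r2=r2, valid=False,
        )
    return EndocytosisFit(
        tau_endo=float(tau), plateau_dff=float(plateau),
        amplitude_dff=float(amp), r2=r2, valid=True,
    )


def rrp_recovery_ratio(train1_peaks, train2_peaks) -> float:
    """Pool recovery after a conditioning train.

    ``train1_peaks`` are the normalised dF/F0 peaks of the probe stimuli
    before the long 20 Hz train (three in the reference protocol) and
    ``train2_peaks`` those after it (the operation accepts one or several);
    both normalised to the first probe of train 1.  Returns
    mean(train2) / mean(train1), invariant to any common normalisation.
    """
    a = np.asarray(train1_peaks, dtype=float)
    b = np.asarray(train2_peaks, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("empty probe-peak list")
    m1 = float(np.mean(a))
    if m1 == 0:
        raise DataError("train-1 mean peak is zero")
    return float(np.mean(b)) / m1


def normalize_to_fmax(
    roi: ROISeries,
    nh4cl_window: tuple[float, float],
    background: float | np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """F(t)/Fmax with Fmax from the NH4Cl alkalinisation segment.

    Returns ``(normalised_series, Fmax)``; raises when Fmax does not exceed
    the initial fluorescence (failed alkalinisation).  Invariant to camera
    gain.
    """
    bg = roi.F_background if background is None else background
    f = roi.F - np.asarray(bg, dtype=float)
    t = roi.frame_times
    win = (t >= nh4cl_window[0]) & (t <= nh4cl_window[1])
    if not np.any(win):
        raise DataError("no frames in NH4Cl window")
    fmax = float(np.mean(f[win]))
    f0 = float(np.mean(f[t < t[0] + F0_WINDOW])) if np.any(t < t[0] + F0_WINDOW) else f[0]
    if fmax <= f0:
        raise DataError("Fmax <= F0: failed alkalinisation")
    return f / fmax, fmax
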