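"""Ratiometric and single-wavelength presynaptic calcium measurements.

Fura-2 340/380 nm ratios are converted to absolute free calcium with the
Grynkiewicz relation

    [Ca2+] = Kd * (R - Rmin) / (Rmax - R) * beta,    beta = F380_max / F380_min

where Rmin and Rmax are the ratios at zero and saturating calcium and beta is
the 380 nm intensity ratio between those two states.  The indicator Kd is
estimated from a calibration series of known buffered concentrations by
linear regression in double-log space: the x-intercept of
log10[(R - Rmin)/(Rmax - R) * beta] versus log10[Ca2+] is log10(Kd)
(equivalently, Kd is the concentration at which the bracketed term equals 1).

SyGCaMP signals are semi-quantitative and are reported as background-
normalised basal fluorescence and baseline-noise-normalised evoked transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DataError, ROISeries

__all__ = [
    "FuraCalibration",
    "CaEstimate",
    "grynkiewicz_concentration",
    "estimate_ca",
    "fura_ratio_from_conc",
    "fit_fura_calibration",
    "sygcamp_basal",
    "sygcamp_evoked",
]

#: R within this fraction of Rmax is treated as saturated (equation diverges)
SATURATION_TOL = 0.01


@dataclass(frozen=True)
class FuraCalibration:
    """Fura-2 calibration constants.  Kd in nM; beta = F380_max/F380_min."""

    Kd: float
    Rmin: float
    Rmax: float
    beta: float
    r2: float = float("nan")
    conc_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.Rmax > self.Rmin > 0):
            raise DataError("require Rmax > Rmin > 0")
        if not self.Kd > 0 or not self.beta > 0:
            raise DataError("Kd and beta must be positive")


@dataclass(frozen=True)
class CaEstimate:
    R: float
    conc: float
    roi_id: str = ""
    valid: bool = True


def grynkiewicz_concentration(R, calib: FuraCalibration):
    """Free [Ca2+] in nM from a 340/380 ratio (scalar or array).

    The exact inverse of the forward ratio model: strictly increasing in R on
    [Rmin, Rmax).  R below Rmin is clamped to 0 nM with a warning; R at or
    above Rmax (where the equation diverges) returns NaN.  For measurement
    use, :func:`estimate_ca` additionally flags ratios within 1% of Rmax as
    saturated rather than trusting the diverging conversion.
    """
    R = np.asarray(R, dtype=float)
    scalar = R.ndim == 0
    R = np.atleast_1d(R)
    sat = R >= calib.Rmax
    low = R < calib.Rmin
    if np.any(low):
        warnings.warn("ratio below Rmin clamped to 0 nM", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = calib.Kd * (R - calib.Rmin) / (calib.Rmax - R) * calib.beta
    conc = np.where(low, 0.0, conc)
    conc = np.where(sat, np.nan, conc)
    if scalar:
        return float(conc[0])
    return conc


def estimate_ca(R: float, calib: FuraCalibration, roi_id: str = "") -> CaEstimate:
    """Measurement wrapper: converts one ratio, flagging near-saturation
    (R within 1% of the Rmin..Rmax span of Rmax) as invalid."""
    saturated = R >= calib.Rmax - SATURATION_TOL * (calib.Rmax - calib.Rmin)
    conc = float("nan") if saturated else grynkiewicz_concentration(R, calib)
    return CaEstimate(R=float(R), conc=conc, roi_id=roi_id, valid=bool(np.isfinite(conc)))


def fura_ratio_from_conc(conc, calib: FuraCalibration):
    """Exact inverse of :func:`grynkiewicz_concentration` (forward model)."""
    conc = np.asarray(conc, dtype=float)
    u = conc / (calib.Kd * calib.beta)
    return (calib.Rmin + calib.Rmax * u) / (1.0 + u)


def fit_fura_calibration(
    known_conc,
    measured_R,
    Rmin: float,
    Rmax: float,
    beta: float,
) -> FuraCalibration:
    """Estimate Kd from a buffered-calcium calibration series.

    Regresses y = log10[(R - Rmin)/(Rmax - R) * beta] on x = log10(conc) and
    reads Kd off the x-intercept (x at y = 0).  Ratios outside the open
    interval (Rmin, Rmax) are excluded with a warning; at least 3 usable
    points are required.

    The regression is inverse-variance weighted: under multiplicative ratio
    noise the uncertainty of y blows up as R approaches either asymptote
    (sigma_y proportional to R * [1/(R-Rmin) + 1/(Rmax-R)]), so points at the
    extreme ends of the concentration range would otherwise dominate the fit
    with almost no information.  The noise CV itself cancels from the
    weights, and on noiseless data the weighting leaves the (exact) fit
    unchanged.  The returned ``r2`` is the weighted coefficient of
    determination in log-log space.
    """
    conc = np.asarray(known_conc, dtype=float)
    R = np.asarray(measured_R, dtype=float)
    if conc.size != R.size:
        raise DataError("concentration and ratio arrays must match")
    usable = (R > Rmin) & (R < Rmax) & (conc > 0)
    if np.any(~usable):
        warnings.warn(
            f"{int(np.sum(~usable))} calibration point(s) outside (Rmin, Rmax) excluded",
            stacklevel=2,
        )
    conc, R = conc[usable], R[usable]
    if conc.size < 3:
        raise DataError("need >= 3 usable calibration points")
    x = np.log10(conc)
    y = np.log10((R - Rmin) / (Rmax - R) * beta)
    # propagated sd of y per unit ratio CV; the CV cancels in the weights
    sigma_y = (1.0 / np.log(10.0)) * (1.0 / (R - Rmin) + 1.0 / (Rmax - R)) * R
    w = 1.0 / sigma_y**2
    w_sum = float(np.sum(w))
    xm = float(np.sum(w * x)) / w_sum
    ym = float(np.sum(w * y)) / w_sum
    sxx = float(np.sum(w * (x - xm) ** 2))
    if sxx == 0:
        raise DataError("degenerate calibration: no spread in concentration")
    slope = float(np.sum(w * (x - xm) * (y - ym))) / sxx
    if slope == 0:
        raise DataError("degenerate calibration: zero slope")
    intercept = ym - slope * xm
    log10_kd = -intercept / slope  # x at y = 0
    yhat = intercept + slope * x
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FuraCalibration(
        Kd=float(10.0**log10_kd),
        Rmin=Rmin,
        Rmax=Rmax,
        beta=beta,
        r2=r2,
        conc_grid=tuple(conc.tolist()),
    )


# ---------------------------------------------------------------------------
# SyGCaMP normalisation


def sygcamp_basal(roi: ROISeries, baseline_window: float = 15.0) -> float:
    """Resting signal: mean ROI fluorescence over the (>= 15 s, 1 Hz)
    non-stimulated baseline divided by the mean local background."""
    t = roi.frame_times
    mask = t < t[0] + baseline_window
    if not np.any(mask):
        raise DataError("no frames in baseline window")
    bg = float(np.mean(roi.F_background[mask]))
    if bg <= 0:
        raise DataError("background is zero: basal normalisation undefined")
    return float(np.mean(roi.F[mask])) / bg


def sygcamp_evoked(roi: ROISeries, stim_window: tuple[float, float]) -> float:
    """Evoked transient amplitude in units of baseline noise SD.

    (peak F within ``stim_window`` - mean baseline F) / SD of baseline F,
    with the baseline taken from all frames preceding the window.  Invariant
    to camera gain (both numerator and denominator scale together).
    """
    t = roi.frame_times
    pre = t < stim_window[0]
    win = (t >= stim_window[0]) & (t <= stim_window[1])
    if not np.any(win):
        raise DataError("no frames in stimulation window")
    if np.sum(pre) < 2:
        raise DataError("need >= 2 baseline frames before the stimulus")
    f = roi.F - roi.F_background
    basal = float(np.mean(f[pre]))
    noise_sd = float(np.std(f[pre], ddof=1))
    if noise_sd == 0:
        noise_sd = np.finfo(float).eps
    return (float(np.max(f[win])) - basal) / noise_sd
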