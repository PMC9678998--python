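"""Synthetic recordings with known ground truth for every analysis stage.

The generators emulate the statistical structure each estimator assumes:

* miniature traces — homogeneous Poisson events (rate optionally coupled
  linearly to resting calcium) drawn as bi-exponential inward currents with
  lognormal quantal amplitudes on white Gaussian noise;
* evoked trains — a depletion model with ``N_sites`` release sites, release
  probability ``Pr`` per stimulus (expected-value or binomial mode) and
  constant replenishment at ``replenish_rate`` sites/s, capped at the pool
  size;
* Fura-2 pairs — the exact forward Grynkiewicz model generating consistent
  340/380 channel intensities with multiplicative noise;
* sypHy traces — step exocytosis per probe, mono-exponential re-acidification
  with ``tau_endo``, and a terminal NH4Cl segment at Fmax.

All randomness flows through ``numpy.random.Generator`` seeded from the
model's ``seed`` combined with a per-generator stream tag, so every simulator
is bit-reproducible and independent of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calcium import FuraCalibration, fura_ratio_from_conc
from .io import DataError, ROISeries, StimulusProtocol, Trace, train_protocol

__all__ = [
    "SynapseModel",
    "ImagingModel",
    "simulate_mini_trace",
    "simulate_train",
    "render_train_trace",
    "simulate_fura",
    "simulate_sygcamp",
    "simulate_phluorin",
    "psc_kernel",
    "PRESETS",
    "preset",
]

# stream tags keeping the RNG of each generator independent at equal seeds
_STREAM_MINI = 101
_STREAM_TRAIN = 202
_STREAM_FURA = 303
_STREAM_GCAMP = 404
_STREAM_PHLUORIN = 505

#: resting calcium (nM) at which the spontaneous rate equals ``mini_rate``
CA_REFERENCE = 100.0


@dataclass(frozen=True)
class SynapseModel:
    """Ground-truth parameters of one simulated synapse population.

    ``q_mean`` defaults to a typical hippocampal miniature-event amplitude
    (20 pA); train analyses in tests and drivers usually pass q explicitly.

    Units: ``q_mean`` pA; ``replenish_rate`` sites/s; ``mini_rate`` Hz;
    ``mini_rate_ca_slope`` Hz/nM around the 100 nM reference;
    ``resting_ca`` nM; ``noise_sd`` pA; PSC time constants in ms.
    """

    N_sites: int = 100
    q_mean: float = 20.0
    q_cv: float = 0.3
    Pr: float = 0.35
    replenish_rate: float = 80.0
    mini_rate: float = 0.5
    mini_rate_ca_slope: float = 0.003
    resting_ca: float = 110.0
    noise_sd: float = 2.0
    psc_rise_tau: float = 0.5
    psc_decay_tau: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.Pr <= 1):
            raise DataError("Pr must be in (0, 1]")
        if self.q_mean <= 0 or self.N_sites <= 0:
            raise DataError("q_mean and N_sites must be positive")
        for name in ("replenish_rate", "mini_rate", "noise_sd", "q_cv"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @property
    def effective_mini_rate(self) -> float:
        """Spontaneous rate after the linear calcium coupling, clamped >= 0."""
        rate = self.mini_rate + self.mini_rate_ca_slope * (self.resting_ca - CA_REFERENCE)
        if rate < 0:
            warnings.warn("computed mini rate < 0 clamped to 0", stacklevel=2)
            return 0.0
        return rate


@dataclass(frozen=True)
class ImagingModel:
    """Ground truth for the imaging simulators.

    ``calib`` parameterises the Fura-2 forward model; ``gcamp_kd`` (nM)
    anchors the SyGCaMP saturation; ``f0``/``fmax`` are quenched and fully
    alkalinised sypHy fluorescence; ``tau_endo`` s; multiplicative noise CV
    ``noise_cv``.
    """

    calib: FuraCalibration = field(
        default_factory=lambda: FuraCalibration(Kd=225.0, Rmin=0.3, Rmax=6.0, beta=5.0)
    )
    gcamp_kd: float = 375.0
    f0: float = 100.0
    fmax: float = 500.0
    tau_endo: float = 12.0
    frame_rate: float = 1.0
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise DataError("frame_rate must be positive")
        if not self.fmax > self.f0 > 0:
            raise DataError("require fmax > f0 > 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def psc_kernel(dt: float, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """Unit-peak bi-exponential PSC kernel sampled at ``dt`` seconds."""
    tr, td = rise_tau_ms * 1e-3, decay_tau_ms * 1e-3
    if not td > tr > 0:
        raise DataError("require decay tau > rise tau > 0")
    t_end = td * 8
    t = np.arange(0.0, t_end, dt)
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def _lognormal_amps(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), n)


# ---------------------------------------------------------------------------
# miniature traces


def simulate_mini_trace(
    model: SynapseModel,
    duration: float,
    dt: float = 1e-4,
) -> tuple[Trace, pd.DataFrame]:
    """Spontaneous-release recording with ground-truth event schedule.

    Returns ``(trace, events)`` where ``events`` has columns ``t`` (kernel
    onset, s) and ``amplitude`` (pA, positive magnitude).  Events are
    inward (negative) on the trace.
    """
    if duration <= 0 or dt <= 0:
        raise DataError("duration and dt must be positive")
    rng = _rng(model.seed, _STREAM_MINI)
    rate = model.effective_mini_rate
    n_events = rng.poisson(rate * duration) if rate > 0 else 0
    times = np.sort(rng.uniform(0.0, duration, n_events))
    amps = _lognormal_amps(rng, n_events, model.q_mean, model.q_cv)

    n = int(round(duration / dt))
    x = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else np.zeros(n)
    kernel = psc_kernel(dt, model.psc_rise_tau, model.psc_decay_tau)
    for t_ev, a in zip(times, amps):
        i0 = int(round(t_ev / dt))
        seg = kernel[: n - i0]
        x[i0 : i0 + seg.size] -= a * seg
    trace = Trace(samples=x, dt=dt, t0=0.0, label="sim_minis", units="pA")
    events = pd.DataFrame({"t": times, "amplitude": amps})
    return trace, events


# ---------------------------------------------------------------------------
# evoked trains


def simulate_train(
    model: SynapseModel,
    protocol: StimulusProtocol,
    mode: str = "expected",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-stimulus evoked amplitudes from the depletion/replenishment model.

    Pool dynamics per stimulus k (pool ``a`` starts at ``N_sites``):
    released_k = a_k * Pr (``expected`` mode) or Binomial(round(a_k), Pr)
    (``stochastic``); a_{k+1} = a_k - released_k + replenish_rate * ISI_k,
    capped at ``N_sites``.  Amplitude_k = released_k * q_mean.

    Returns ``(amplitudes, ground_truth)`` with per-stimulus pool and
    release counts.
    """
    if mode not in ("expected", "stochastic"):
        raise DataError(f"unknown mode {mode!r}")
    rng = _rng(model.seed, _STREAM_TRAIN)
    st = protocol.stim_times
    isis = np.append(protocol.isis, protocol.isis[-1] if st.size > 1 else 0.0)
    a = float(model.N_sites)
    pools, released, amps = [], [], []
    for k in range(st.size):
        pools.append(a)
        if mode == "expected":
            rel = a * model.Pr
        else:
            rel = float(rng.binomial(int(round(a)), model.Pr))
        released.append(rel)
        amps.append(rel * model.q_mean)
        a = min(a - rel + model.replenish_rate * isis[k], float(model.N_sites))
    gt = pd.DataFrame(
        {"stim_t": st, "pool": pools, "released": released, "amplitude": amps}
    )
    return np.asarray(amps), gt


def render_train_trace(
    amplitudes: np.ndarray,
    protocol: StimulusProtocol,
    model: SynapseModel,
    dt: float = 1e-4,
    tail: float = 0.1,
    synaptic_delay: float = 0.003,
) -> Trace:
    """Render per-stimulus amplitudes as an inward-current trace with noise.

    Each response kernel starts ``synaptic_delay`` seconds after its stimulus
    (default 3 ms), so the peak falls beyond the stimulation-artifact blank
    of the amplitude measurement, as it does in real recordings.
    """
    st = protocol.stim_times
    duration = st[-1] - st[0] + tail
    t0 = st[0]
    n = int(round(duration / dt))
    rng = _rng(model.seed, _STREAM_TRAIN + 1)
    x = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else np.zeros(n)
    kernel = psc_kernel(dt, model.psc_rise_tau, model.psc_decay_tau)
    for t_s, a in zip(st, np.asarray(amplitudes)):
        i0 = int(round((t_s - t0 + synaptic_delay) / dt))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        x[i0 : i0 + seg.size] -= a * seg
    return Trace(samples=x, dt=dt, t0=t0, label="sim_train", units="pA")


# ---------------------------------------------------------------------------
# imaging


def simulate_fura(
    true_conc,
    imaging: ImagingModel,
    n_frames: int = 30,
    f380_max: float = 1000.0,
    background: float = 50.0,
) -> list[tuple[ROISeries, ROISeries]]:
    """Paired 340/380 ROI series for each true concentration (nM).

    Channel intensities are generated consistently with the forward
    Grynkiewicz model: the 380 nm signal interpolates between its 0-Ca and
    saturated levels (ratio ``beta``) with the same saturation fraction that
    sets R, and F340 = R * F380.  Multiplicative Gaussian noise of CV
    ``noise_cv`` is applied per frame, on top of an additive background.
    """
    conc = np.atleast_1d(np.asarray(true_conc, dtype=float))
    if np.any(conc < 0):
        raise DataError("concentrations must be non-negative")
    rng = _rng(imaging.seed, _STREAM_FURA)
    calib = imaging.calib
    t = np.arange(n_frames) / imaging.frame_rate
    f380_min = f380_max / calib.beta
    out = []
    for i, c in enumerate(conc):
        R = float(fura_ratio_from_conc(c, calib))
        u = c / (calib.Kd * calib.beta)
        x = u / (1.0 + u)  # saturation fraction
        f380 = f380_max + (f380_min - f380_max) * x
        f340 = R * f380
        noisy340 = f340 * (1 + imaging.noise_cv * rng.standard_normal(n_frames))
        noisy380 = f380 * (1 + imaging.noise_cv * rng.standard_normal(n_frames))
        out.append(
            (
                ROISeries(t, noisy340 + background, background, f"roi{i}", "340"),
                ROISeries(t, noisy380 + background, background, f"roi{i}", "380"),
            )
        )
    return out


def simulate_sygcamp(
    imaging: ImagingModel,
    duration: float = 30.0,
    baseline: float = 15.0,
    basal_scale: float = 1.0,
    evoked_conc: float = 0.0,
    resting_conc: float = 110.0,
    background: float = 50.0,
    stim_duration: float = 2.0,
) -> ROISeries:
    """Single-wavelength presynaptic GCaMP bouton with optional evoked step.

    Basal fluorescence follows a Hill saturation F = f0*(1 + 4*c/(c+Kd))
    scaled by ``basal_scale``; an evoked calcium step to ``evoked_conc``
    spans ``stim_duration`` s after the baseline.  Frames at
    ``imaging.frame_rate`` (1 Hz in the reference protocol).
    """
    rng = _rng(imaging.seed, _STREAM_GCAMP)
    n = int(round(duration * imaging.frame_rate))
    t = np.arange(n) / imaging.frame_rate

    def level(c):
        return imaging.f0 * (1.0 + 4.0 * c / (c + imaging.gcamp_kd)) * basal_scale

    f = np.full(n, level(resting_conc))
    if evoked_conc > 0:
        stim = (t >= baseline) & (t < baseline + stim_duration)
        f[stim] = level(evoked_conc)
    noisy = f * (1 + imaging.noise_cv * rng.standard_normal(n))
    return ROISeries(t, noisy + background, background, "sygcamp", "green")


def simulate_phluorin(
    imaging: ImagingModel,
    probe_times=(10.0, 110.0, 210.0),
    conditioning: tuple[float, float] | None = None,
    post_probe_times=(),
    nh4cl_window: tuple[float, float] | None = None,
    duration: float = 320.0,
    exo_fraction_per_probe: float = 0.25,
    conditioning_fraction: float = 0.8,
    plateau_fraction: float = 0.0,
    background: float = 20.0,
) -> tuple[ROISeries, dict]:
    """sypHy ROI trace: step exocytosis, exponential re-acidification, NH4Cl.

    The surface (dequenched) fraction ``x`` decays toward
    ``plateau_fraction`` with ``imaging.tau_endo``; each probe adds
    ``exo_fraction_per_probe`` and the optional conditioning train (start,
    duration) ramps in ``conditioning_fraction`` linearly.  Fluorescence is
    ``f0 + (fmax - f0) * x`` plus background and multiplicative noise; the
    NH4Cl window pins F at ``fmax``.  Returns the series and a ground-truth
    dict.
    """
    if not 0 <= exo_fraction_per_probe <= 1:
        raise DataError("exo fraction must be in [0, 1]")
    rng = _rng(imaging.seed, _STREAM_PHLUORIN)
    n = int(round(duration * imaging.frame_rate))
    t = np.arange(n) / imaging.frame_rate
    dt = 1.0 / imaging.frame_rate
    x = 0.0
    xs = np.empty(n)
    cond_per_frame = 0.0
    decay = np.exp(-dt / imaging.tau_endo)
    for i, ti in enumerate(t):
        # relax toward the plateau with tau_endo, then add this frame's
        # exocytosis so the probe frame samples the undecayed peak
        x = plateau_fraction + (x - plateau_fraction) * decay
        for tp in probe_times:
            if tp <= ti < tp + dt:
                x = min(x + exo_fraction_per_probe, 1.0)
        for tp in post_probe_times:
            if tp <= ti < tp + dt:
                x = min(x + exo_fraction_per_probe, 1.0)
        if conditioning is not None:
            c0, cdur = conditioning
            if c0 <= ti < c0 + cdur:
                x = min(x + conditioning_fraction * dt / cdur, 1.0)
        xs[i] = x
    f = imaging.f0 + (imaging.fmax - imaging.f0) * xs
    if nh4cl_window is not None:
        w = (t >= nh4cl_window[0]) & (t <= nh4cl_window[1])
        f[w] = imaging.fmax
    noisy = f * (1 + imaging.noise_cv * rng.standard_normal(n))
    roi = ROISeries(t, noisy + background, background, "syphy", "green")
    truth = {
        "tau_endo": imaging.tau_endo,
        "exo_fraction_per_probe": exo_fraction_per_probe,
        "probe_times": tuple(probe_times),
        "post_probe_times": tuple(post_probe_times),
        "f0": imaging.f0,
        "fmax": imaging.fmax,
    }
    return roi, truth


# ---------------------------------------------------------------------------
# presets: the study conditions each scenario emulates

PRESETS: dict[str, SynapseModel] = {
    # wild-type resting terminal: ~110 nM resting calcium
    "wt_rest": SynapseModel(resting_ca=110.0),
    # calcium-binding-deficient mutant: elevated resting calcium (~265 nM)
    # raises the spontaneous rate through the linear coupling and halves
    # activity-dependent pool replenishment
    "e373k_rest": SynapseModel(resting_ca=265.0, replenish_rate=40.0),
    # RRP estimation train: 40 Hz for 2 s, near-unity release probability
    "depletion_40hz": SynapseModel(Pr=0.8),
    # sustained depression/recovery: 30 s at 20 Hz then 0.1 Hz probing
    "recovery_20hz": SynapseModel(Pr=0.35),
}

PRESET_PROTOCOLS: dict[str, StimulusProtocol] = {
    "depletion_40hz": train_protocol(40.0, 2.0),
    "recovery_20hz": train_protocol(20.0, 30.0, probe_freq=0.1, probe_duration=60.0),
}


def preset(name: str, seed: int | None = None) -> SynapseModel:
    """Named scenario model, optionally reseeded."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    model = PRESETS[name]
    return model if seed is None else replace(model, seed=seed)
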