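"""Core data types and text-table I/O shared by every analysis stage.

All signals are carried by three light containers: :class:`Trace` for
uniformly sampled voltage-clamp current (pA, inward negative as recorded at
-70 mV) or fluorescence, :class:`ROISeries` for frame-based imaging of a
single region of interest, and :class:`StimulusProtocol` for ordered stimulus
times with train/probe metadata.  Times are always seconds on a single clock
with t0 = start of sweep; "amplitude" downstream always means the unsigned
deflection |peak - baseline|.

The canonical interchange format is a plain columnar CSV (``time_s`` plus a
signal column) with an optional JSON sidecar for provenance, so that traces
exported from any acquisition program can be analysed without vendor readers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "StimulusProtocol",
    "ROISeries",
    "SchemaError",
    "DataError",
    "read_trace_table",
    "write_trace_table",
    "read_roi_table",
    "write_roi_table",
    "write_results",
    "train_protocol",
    "paired_pulse_protocol",
]


class SchemaError(ValueError):
    """A table is missing a declared column or the config is inconsistent."""


class DataError(ValueError):
    """Table contents violate a precondition (non-monotone or non-uniform time)."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples
        Signal values (pA for current, a.u. for fluorescence).
    dt
        Sampling interval in seconds (10-20 kHz recordings give 1e-4..5e-5).
    t0
        Time of the first sample, seconds.
    label
        Free-text identifier (cell / sweep).
    units
        Unit string of ``samples``.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    label: str = ""
    units: str = "pA"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.dt > 0:
            raise DataError(f"dt must be positive, got {self.dt}")
        if samples.ndim != 1 or samples.size < 2:
            raise DataError("trace needs at least 2 samples in a 1-d array")
        if not np.all(np.isfinite(samples)):
            raise DataError("trace samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (nearest, clipped to the trace)."""
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n - 1))


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus times plus train/probe frequency metadata."""

    stim_times: np.ndarray
    train_freq: float
    train_duration: float = 0.0
    probe_freq: float = 0.0
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        st = np.asarray(self.stim_times, dtype=float)
        object.__setattr__(self, "stim_times", st)
        if st.ndim != 1 or st.size == 0:
            raise DataError("protocol needs at least one stimulus time")
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise DataError("stimulus times must be strictly increasing")
        if not self.train_freq > 0:
            raise DataError("train_freq must be positive")

    @property
    def n_stim(self) -> int:
        return self.stim_times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.stim_times)


@dataclass(frozen=True)
class ROISeries:
    """Fluorescence of one ROI over frames, with per-frame or scalar background.

    ``channel`` is "340"/"380" for Fura-2 excitation pairs or "green" for
    single-wavelength indicators (GCaMP, pHluorin).
    """

    frame_times: np.ndarray
    F: np.ndarray
    F_background: np.ndarray | float = 0.0
    roi_id: str = ""
    channel: str = "green"

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        f = np.asarray(self.F, dtype=float)
        bg = np.asarray(self.F_background, dtype=float)
        if bg.ndim == 0:
            bg = np.full_like(f, float(bg))
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "F", f)
        object.__setattr__(self, "F_background", bg)
        if t.size != f.size or bg.size != f.size:
            raise DataError("frame_times, F and background lengths must agree")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError("frame times must be increasing")
        if not np.all(np.isfinite(f)):
            raise DataError("fluorescence must be finite")
        if np.any(bg < 0):
            raise DataError("background must be non-negative")


# ---------------------------------------------------------------------------
# protocol constructors


def train_protocol(
    freq: float,
    duration: float,
    t_start: float = 0.0,
    probe_freq: float = 0.0,
    probe_duration: float = 0.0,
) -> StimulusProtocol:
    """Regular train at ``freq`` Hz for ``duration`` s, optionally followed by
    low-frequency recovery probes (e.g. 30 s @ 20 Hz then 0.1 Hz probing)."""
    n = int(round(freq * duration))
    times = t_start + np.arange(n) / freq
    if probe_freq > 0 and probe_duration > 0:
        n_probe = int(round(probe_freq * probe_duration))
        probe_t0 = t_start + duration
        probes = probe_t0 + np.arange(n_probe) / probe_freq
        times = np.concatenate([times, probes])
    return StimulusProtocol(
        stim_times=times,
        train_freq=freq,
        train_duration=duration,
        probe_freq=probe_freq,
    )


def paired_pulse_protocol(isi: float, t_start: float = 0.05) -> StimulusProtocol:
    """Two stimuli separated by ``isi`` seconds (standard ISIs 0.02-1.0 s)."""
    return StimulusProtocol(
        stim_times=np.array([t_start, t_start + isi]),
        train_freq=1.0 / isi,
        train_duration=isi,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_trace_table(
    path: str | Path,
    time_col: str = "time_s",
    value_col: str = "value",
    units: str = "pA",
    label: str = "",
    uniformity_rtol: float = 1e-6,
) -> Trace:
    """Read a two-column CSV sweep into a :class:`Trace`.

    Sampling must be uniform to within ``uniformity_rtol * dt``; duplicated or
    non-monotone timestamps raise :class:`DataError`, a missing column raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    for col in (time_col, value_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not in {path}: {list(df.columns)}")
    t = df[time_col].to_numpy(dtype=float)
    x = df[value_col].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError("trace table needs at least 2 rows")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise DataError("time column must be strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > uniformity_rtol * dt:
        raise DataError("non-uniform sampling beyond tolerance")
    return Trace(samples=x, dt=dt, t0=float(t[0]), label=label or Path(path).stem, units=units)


def write_trace_table(trace: Trace, path: str | Path, value_col: str = "value") -> None:
    # %.17g round-trips IEEE doubles exactly
    df = pd.DataFrame({"time_s": trace.times, value_col: trace.samples})
    df.to_csv(path, index=False, float_format="%.17g")


def read_roi_table(
    path: str | Path,
    time_col: str = "time_s",
    f_col: str = "F",
    bg_col: str = "F_background",
    roi_id: str = "",
    channel: str = "green",
) -> ROISeries:
    """Read a per-frame ROI fluorescence CSV (background column optional)."""
    df = pd.read_csv(path)
    for col in (time_col, f_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not in {path}: {list(df.columns)}")
    bg = df[bg_col].to_numpy(dtype=float) if bg_col in df.columns else 0.0
    return ROISeries(
        frame_times=df[time_col].to_numpy(dtype=float),
        F=df[f_col].to_numpy(dtype=float),
        F_background=bg,
        roi_id=roi_id or Path(path).stem,
        channel=channel,
    )


def write_roi_table(roi: ROISeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": roi.frame_times, "F": roi.F, "F_background": roi.F_background}
    ).to_csv(path, index=False, float_format="%.17g")


def _to_record(obj: Any) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        rec = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, np.ndarray):
                continue  # array-valued fields go to their own trace/roi table
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            rec[f.name] = v
        return rec
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"cannot serialise {type(obj)!r} as a result record")


def config_hash(config: Any) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    results: Iterable[Any] | Any,
    path: str | Path,
    provenance: dict | None = None,
) -> pd.DataFrame:
    """Write result objects to CSV with a JSON provenance sidecar.

    ``results`` is a dataclass instance, a dict, or a sequence of either; the
    sidecar ``<path>.json`` records the schema plus any provenance the caller
    supplies (config hash, seed, versions).  An empty sequence writes a file
    with a header only when the schema can be inferred, otherwise an empty file.
    """
    path = Path(path)
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = [results]
    elif isinstance(results, dict):
        results = [results]
    records = [_to_record(r) for r in results]
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "columns": list(df.columns),
        "n_rows": int(len(df)),
        "provenance": provenance or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return df
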