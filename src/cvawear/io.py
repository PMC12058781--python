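"""Multichannel waveform records: on-disk layout, resampling and band-pass filtering.

A :class:`WaveformRecord` holds named channels (``ecg``, ``scg_x/y/z``,
``ppg_ir``, ``accel_x/y/z``, ...) each with its own sampling rate, plus the
metadata the downstream stages need (subject id, clinic/home setting, dose
events, posture schedule, simulation ground truth when present).

The native on-disk layout is one directory per record: a ``<channel>.csv``
file per channel (columns ``time_s,value``) and a ``meta.json`` sidecar with
per-channel sampling rates and the metadata.  An HDF5 container with identical
content is available for bulk storage.

Filtering is zero-phase (forward-backward Butterworth) so fiducial timings
are not shifted; resampling is polyphase FIR to avoid aliasing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any

import numpy as np
from scipy import signal as sps

__all__ = [
    "Channel",
    "WaveformRecord",
    "read_record",
    "write_record",
    "resample_uniform",
    "bandpass",
    "SCG_BAND",
    "PPG_BAND",
    "TARGET_FS",
]

#: Analysis bands (Hz) for the cardiomechanical and vascular channels.
SCG_BAND = (1.0, 40.0)
PPG_BAND = (1.0, 8.0)
#: Common sampling rate (Hz) all channels are brought to before beat work.
TARGET_FS = 500.0


@dataclass
class Channel:
    """A uniformly sampled signal with its rate and start time."""

    samples: np.ndarray
    fs: float
    start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self.samples)) / self.fs


@dataclass
class WaveformRecord:
    """Named channels plus study metadata for one recording."""

    channels: dict[str, Channel]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def write_record(record: WaveformRecord, path: str | Path, fmt: str = "csv") -> Path:
    """Write a record to ``path`` (a directory for csv, a file for hdf5).

    Samples round-trip bit-exactly: CSV values are written with ``repr``-level
    precision and HDF5 stores the float64 arrays directly.
    """
    path = Path(path)
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "channels": {},
            "metadata": _jsonable(record.metadata),
        }
        for name, ch in record.channels.items():
            arr = np.column_stack([ch.times(), ch.samples])
            np.savetxt(path / f"{name}.csv", arr, delimiter=",",
                       header="time_s,value", comments="", fmt="%.17g")
            meta["channels"][name] = {"fs": ch.fs, "start": ch.start,
                                      "n": int(len(ch.samples))}
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        return path
    if fmt == "hdf5":
        import h5py

        path = path if path.suffix else path.with_suffix(".h5")
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            for name, ch in record.channels.items():
                ds = f.create_dataset(name, data=ch.samples)
                ds.attrs["fs"] = ch.fs
                ds.attrs["start"] = ch.start
            f.attrs["metadata"] = json.dumps(_jsonable(record.metadata))
        return path
    raise ValueError(f"unknown format {fmt!r}")


def read_record(path: str | Path) -> WaveformRecord:
    """Read a record written by :func:`write_record`.

    Raises :class:`ValueError` naming the offending channel when the sidecar
    is missing a sampling rate or a channel's length disagrees with it.
    """
    path = Path(path)
    if path.is_file() and path.suffix in {".h5", ".hdf5"}:
        import h5py

        channels: dict[str, Channel] = {}
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs.get("metadata", "{}"))
            for name in f:
                ds = f[name]
                channels[name] = Channel(ds[...], float(ds.attrs["fs"]),
                                         float(ds.attrs.get("start", 0.0)))
        return WaveformRecord(channels, meta)

    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    channels = {}
    for name, spec in meta.get("channels", {}).items():
        if "fs" not in spec:
            raise ValueError(f"sidecar missing 'fs' for channel {name!r}")
        data = np.loadtxt(path / f"{name}.csv", delimiter=",", skiprows=1,
                          ndmin=2)
        samples = data[:, 1]
        if "n" in spec and len(samples) != spec["n"]:
            raise ValueError(
                f"channel {name!r}: {len(samples)} samples on disk but "
                f"sidecar declares {spec['n']}")
        channels[name] = Channel(samples, float(spec["fs"]),
                                 float(spec.get("start", 0.0)))
    return WaveformRecord(channels, meta.get("metadata", {}))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Resampling and filtering
# ---------------------------------------------------------------------------

def resample_uniform(x: np.ndarray, fs_in: float, fs_out: float = TARGET_FS,
                     ) -> np.ndarray:
    """Polyphase-FIR resampling to ``fs_out``; output length = round(n*fs_out/fs_in)."""
    x = np.asarray(x, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if x.size == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    # remove the mean so FIR passband ripple cannot modulate the DC level
    mu = x.mean()
    y = sps.resample_poly(x - mu, up, down, padtype="line") + mu
    n_out = int(round(len(x) * fs_out / fs_in))
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, ``order`` per pass)."""
    x = np.asarray(x, dtype=float)
    if not (0 < lo < hi < fs / 2):
        raise ValueError(
            f"corner frequencies must satisfy 0 < lo < hi < fs/2, "
            f"got lo={lo}, hi={hi}, fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = min(len(x) - 1, 3 * int(fs))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def preprocess_record(record: WaveformRecord, fs_out: float = TARGET_FS,
                      scg_band: tuple[float, float] = SCG_BAND,
                      ppg_band: tuple[float, float] = PPG_BAND,
                      ) -> WaveformRecord:
    """Resample cardiovascular channels to a common rate and band-pass them.

    ECG is resampled but left wide-band (each R-peak detector applies its own
    filter bank); SCG and PPG get their analysis bands.  Channels the beat
    pipeline does not use (accelerometer axes, off-axis SCG) pass through
    untouched.  The applied filter specs are logged in the metadata.
    """
    out: dict[str, Channel] = {}
    specs: dict[str, Any] = {}
    for name, ch in record.channels.items():
        if name == "ecg":
            y = resample_uniform(ch.samples, ch.fs, fs_out)
            out[name] = Channel(y, fs_out, ch.start)
            specs[name] = {"resampled_to": fs_out, "band": None}
        elif name.startswith("scg"):
            y = resample_uniform(ch.samples, ch.fs, fs_out)
            y = bandpass(y, fs_out, *scg_band)
            out[name] = Channel(y, fs_out, ch.start)
            specs[name] = {"resampled_to": fs_out, "band": list(scg_band),
                           "filter": "butterworth order 4, zero-phase"}
        elif name.startswith("ppg"):
            y = resample_uniform(ch.samples, ch.fs, fs_out)
            y = bandpass(y, fs_out, *ppg_band)
            out[name] = Channel(y, fs_out, ch.start)
            specs[name] = {"resampled_to": fs_out, "band": list(ppg_band),
                           "filter": "butterworth order 4, zero-phase"}
        else:
            out[name] = Channel(ch.samples.copy(), ch.fs, ch.start)
            specs[name] = {"passthrough": True}
    meta = dict(record.metadata)
    meta["filter_specs"] = specs
    return WaveformRecord(out, meta)
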