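"""Synthetic multimodal wearable recordings with known ground truth.

Generates the signal ensemble a chest patch records — single-lead ECG,
dorsoventral seismocardiogram (SCG), infrared photoplethysmogram (PPG) and a
triaxial accelerometer — from a common train of beat times, so every
downstream estimate (R-peaks, PEP, LVET, PAT, HRV indices) can be checked
against the configured truth.

The beat train carries autonomic-like RR variability: a low-frequency (LF,
default 0.10 Hz) and a high-frequency (HF, default 0.25 Hz) sinusoidal
modulation plus white jitter.  Waveform morphology is deliberately stylised —
a narrow biphasic QRS, Gaussian-enveloped ~20 Hz oscillation packets at the
aortic-opening (AO) and aortic-closing (AC) instants of the SCG, and a
gamma-like PPG pulse whose foot sits at the configured pulse-arrival time —
the simplest shapes that expose the fiducials the pipeline extracts.

:func:`gen_dose_response` composes these into per-subject OFF/ON recording
pairs with a dose-scaled PEP increase, ON-state SCG/PPG amplitude reduction,
and RR-variability suppression in the orthostatic-hypotension (OH) subgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Channel, WaveformRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_rr_series",
    "gen_ecg",
    "gen_scg",
    "gen_ppg",
    "gen_accel",
    "gen_dose_response",
]

#: Per-channel native sampling rates (Hz) of the emulated patch.
FS_ECG = 500.0
FS_SCG = 1000.0
FS_PPG = 67.0
FS_ACCEL = 50.0


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Timing parameters are in ms, rates in Hz, dose in mg of levodopa
    equivalents.  ``delta_pep_per_100mg`` is the ON-state PEP increase per
    100 mg; ``scg_amp_ratio_on``/``ppg_amp_ratio_on`` multiply the ON-state
    waveform amplitudes; ``rmssd_on_factor_oh`` multiplies every RR
    variability source (LF, HF, jitter) of OH subjects in the ON state, so
    ground-truth RMSSD scales by exactly that factor.
    """

    n_subjects: int = 14
    oh_fraction: float = 0.5
    dose_mg: float | Sequence[float] = 150.0
    mean_hr: float = 70.0
    hr_between_sd: float = 5.0          # between-subject mean-HR spread (bpm)
    lf_amp: float = 25.0                # ms
    hf_amp: float = 20.0                # ms
    lf_freq: float = 0.10               # Hz
    hf_freq: float = 0.25               # Hz
    rr_noise_sd: float = 8.0            # ms white jitter on RR
    pep_off: float = 90.0               # ms
    pep_between_sd: float = 10.0        # between-subject PEP spread (ms)
    lvet_off: float = 300.0             # ms
    pat_off: float = 210.0              # ms
    delta_pep_per_100mg: float = 8.0    # ms per 100 mg
    delta_pep_between_sd: float = 4.0   # between-subject response spread (ms)
    scg_amp_ratio_on: float = 0.85
    ppg_amp_ratio_on: float = 0.85
    rmssd_on_factor_oh: float = 0.7
    scg_amp: float = 1.0                # AO packet amplitude (device units)
    ppg_amp: float = 1.0
    ecg_amp: float = 1.0
    noise_sd_ecg: float = 0.02
    noise_sd_scg: float = 0.05
    noise_sd_ppg: float = 0.02
    noise_sd_accel: float = 0.01        # g
    artifact_rate: float = 0.2          # motion bursts per minute
    segment_s: float = 330.0            # length of each OFF / ON segment
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.oh_fraction <= 1.0:
            raise ValueError("oh_fraction must be in [0, 1]")
        if self.mean_hr <= 0 or self.lf_freq <= 0 or self.hf_freq <= 0:
            raise ValueError("rates must be positive")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15] Hz")
        if not 0.15 <= self.hf_freq <= 0.4:
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.4] Hz")
        if self.pep_off >= self.pat_off:
            raise ValueError("pep_off must be < pat_off (PTT must be positive)")
        if self.lvet_off <= 0 or self.pep_off <= 0:
            raise ValueError("systolic timings must be positive")
        if self.segment_s < 300:
            raise ValueError("each OFF/ON segment must be >= 300 s")

    def doses(self) -> np.ndarray:
        d = np.asarray(self.dose_mg, dtype=float)
        if d.ndim == 0:
            d = np.full(self.n_subjects, float(d))
        if len(d) != self.n_subjects:
            raise ValueError("dose_mg must be scalar or length n_subjects")
        return d


@dataclass
class SimTruth:
    """Ground truth for one generated segment."""

    beat_times: np.ndarray              # s, strictly increasing
    rr_ms: np.ndarray                   # ms, len = len(beat_times) - 1
    pep_true: np.ndarray                # ms per beat
    lvet_true: np.ndarray               # ms per beat
    pat_true: np.ndarray                # ms per beat
    state: str = "OFF"                  # OFF | ON
    oh_flag: bool = False
    posture: str = "seated"

    def __post_init__(self) -> None:
        if len(self.beat_times) > 1:
            if not np.all(np.diff(self.beat_times) > 0):
                raise ValueError("beat times must be strictly increasing")
            min_rr = float(np.min(self.rr_ms))
            if np.any(self.pep_true + self.lvet_true >= min_rr):
                raise ValueError("PEP + LVET must stay below the minimum RR")
        if np.any(self.pep_true <= 0) or np.any(self.lvet_true <= 0):
            raise ValueError("per-beat timings must be positive")
        if np.any(self.pep_true >= self.pat_true):
            raise ValueError("PEP must be < PAT for every beat")


# ---------------------------------------------------------------------------
# Beat train
# ---------------------------------------------------------------------------

def gen_rr_series(duration_s: float, mean_hr: float, lf_amp: float = 0.0,
                  hf_amp: float = 0.0, noise_sd: float = 0.0,
                  seed: int | np.random.Generator = 0,
                  lf_freq: float = 0.10, hf_freq: float = 0.25,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Beat times (s) and RR intervals (ms) with LF/HF sinusoidal modulation.

    RR(t) = 60000/mean_hr + lf_amp sin(2π f_LF t) + hf_amp sin(2π f_HF t)
    + N(0, noise_sd²); beat times are the running sum starting at t = 0.
    """
    if duration_s < 300:
        raise ValueError("duration must be >= 300 s (one 5-min window)")
    if not 40 <= mean_hr <= 180:
        raise ValueError("mean_hr must be within [40, 180] bpm")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    base = 60_000.0 / mean_hr
    if lf_amp + hf_amp + 5 * noise_sd >= base:
        raise ValueError("modulation amplitudes would drive RR non-positive")
    times = [0.0]
    rrs: list[float] = []
    t = 0.0
    while True:
        rr = (base
              + lf_amp * math.sin(2 * math.pi * lf_freq * t)
              + hf_amp * math.sin(2 * math.pi * hf_freq * t)
              + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        if rr <= 0:
            raise ValueError("generated RR interval <= 0; reduce amplitudes")
        t += rr / 1000.0
        if t >= duration_s:
            break
        times.append(t)
        rrs.append(rr)
    return np.asarray(times), np.asarray(rrs)


# ---------------------------------------------------------------------------
# Channel waveforms
# ---------------------------------------------------------------------------

def _place(template: np.ndarray, centers_idx: np.ndarray, n: int) -> np.ndarray:
    """Sum copies of ``template`` (centre at len//2) at the given sample indices."""
    y = np.zeros(n)
    half = len(template) // 2
    for c in centers_idx:
        a, b = c - half, c - half + len(template)
        ta, tb = max(0, -a), len(template) - max(0, b - n)
        a, b = max(a, 0), min(b, n)
        if a < b:
            y[a:b] += template[ta:tb]
    return y


def gen_ecg(beat_times: np.ndarray, duration_s: float | None = None,
            fs: float = FS_ECG, noise_sd: float = 0.0, amp: float = 1.0,
            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Stylised ECG: one dominant biphasic QRS deflection per beat time."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    beat_times = np.asarray(beat_times, dtype=float)
    if duration_s is None:
        duration_s = (beat_times[-1] + 1.0) if len(beat_times) else 1.0
    n = int(round(duration_s * fs))
    # R wave: narrow Gaussian; small delayed negative lobe as the S wave.
    half_ms = 60.0
    tt = np.arange(-half_ms, half_ms + 1e-9, 1000.0 / fs) / 1000.0
    sigma = 0.006
    template = amp * (np.exp(-tt**2 / (2 * sigma**2))
                      - 0.25 * np.exp(-(tt - 0.025)**2 / (2 * (1.5 * sigma)**2)))
    idx = np.round(beat_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    y = _place(template, idx, n)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n)
    return y


def _packet(fs: float, amp: float, sigma_ms: float = 15.0,
            carrier_hz: float = 20.0) -> np.ndarray:
    """Gaussian-enveloped cosine packet; dominant extremum exactly at centre."""
    half = 3.5 * sigma_ms
    tt = np.arange(-half, half + 1e-9, 1000.0 / fs) / 1000.0
    return amp * np.exp(-tt**2 / (2 * (sigma_ms / 1000.0)**2)) \
        * np.cos(2 * np.pi * carrier_hz * tt)


def gen_scg(beat_times: np.ndarray, pep_true: np.ndarray | float,
            lvet_true: np.ndarray | float, amp: float = 1.0,
            duration_s: float | None = None, fs: float = FS_SCG,
            noise_sd: float = 0.0, seed: int | np.random.Generator = 0,
            ) -> np.ndarray:
    """Dorsoventral SCG: AO packet at beat+PEP, AC packet at beat+PEP+LVET."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    beat_times = np.asarray(beat_times, dtype=float)
    pep = np.broadcast_to(np.asarray(pep_true, dtype=float), beat_times.shape)
    lvet = np.broadcast_to(np.asarray(lvet_true, dtype=float), beat_times.shape)
    if len(beat_times) > 1:
        min_rr = float(np.min(np.diff(beat_times))) * 1000.0
        if np.any(pep + lvet >= min_rr):
            raise ValueError("PEP + LVET exceeds the shortest RR: packets overlap")
    if duration_s is None:
        duration_s = (beat_times[-1] + 1.0) if len(beat_times) else 1.0
    n = int(round(duration_s * fs))
    ao_tpl = _packet(fs, 1.0)
    ac_tpl = _packet(fs, 0.6)
    y = np.zeros(n)
    half_ao, half_ac = len(ao_tpl) // 2, len(ac_tpl) // 2
    for t, p, l in zip(beat_times, pep, lvet):
        for tpl, half, t_f in ((ao_tpl, half_ao, t + p / 1000.0),
                               (ac_tpl, half_ac, t + (p + l) / 1000.0)):
            c = int(round(t_f * fs))
            a, b = c - half, c - half + len(tpl)
            ta, tb = max(0, -a), len(tpl) - max(0, b - n)
            a, b = max(a, 0), min(b, n)
            if a < b:
                y[a:b] += tpl[ta:tb]
    y *= amp
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n)
    return y


def _ppg_pulse(fs: float, peak_ms: float = 150.0,
               length_ms: float = 900.0) -> np.ndarray:
    """Gamma-like pulse starting at index 0, normalised to peak 1.

    Unit shape exponent gives a non-zero upstroke slope right at the onset,
    so the foot is a well-defined kink rather than a gradual departure.
    """
    tt = np.arange(0.0, length_ms, 1000.0 / fs)
    shape = (tt / peak_ms) * np.exp(-tt / peak_ms)
    return shape / shape.max()


def gen_ppg(beat_times: np.ndarray, pat_true: np.ndarray | float,
            pulse_amp: np.ndarray | float = 1.0,
            duration_s: float | None = None, fs: float = FS_PPG,
            noise_sd: float = 0.0, seed: int | np.random.Generator = 0,
            ) -> np.ndarray:
    """Infrared PPG: gamma-like pulse whose foot sits at beat+PAT."""
    if fs < 20:
        raise ValueError("fs too low to resolve the pulse (< 20 Hz)")
    beat_times = np.asarray(beat_times, dtype=float)
    pat = np.broadcast_to(np.asarray(pat_true, dtype=float), beat_times.shape)
    amp = np.broadcast_to(np.asarray(pulse_amp, dtype=float), beat_times.shape)
    if len(beat_times) > 1:
        min_rr = float(np.min(np.diff(beat_times))) * 1000.0
        if np.any(pat >= min_rr):
            raise ValueError("PAT exceeds the shortest RR")
    if duration_s is None:
        duration_s = (beat_times[-1] + 1.5) if len(beat_times) else 1.0
    n = int(round(duration_s * fs))
    tpl = _ppg_pulse(fs)
    y = np.zeros(n)
    for t, p, a in zip(beat_times, pat, amp):
        c = int(round((t + p / 1000.0) * fs))
        b = min(c + len(tpl), n)
        if c < n and b > max(c, 0):
            a0 = max(c, 0)
            y[a0:b] += a * tpl[a0 - c:b - c]
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n)
    return y


#: Gravity direction (device frame, unit vector) per posture label.  The
#: device x axis is the torso longitudinal axis, z the dorsoventral axis.
_POSTURE_GRAVITY = {
    "standing": np.array([1.0, 0.0, 0.0]),
    "seated": np.array([math.cos(math.radians(15)), 0.0,
                        math.sin(math.radians(15))]),
    "supine": np.array([0.0, 0.0, 1.0]),
}


def gen_accel(posture_schedule: Sequence[tuple[float, float, str]],
              activity_bursts: Sequence[tuple[float, float]] = (),
              fs: float = FS_ACCEL, noise_sd: float = 0.01,
              burst_sd: float = 0.4, seed: int | np.random.Generator = 0,
              ) -> np.ndarray:
    """Triaxial accelerometer (g units), shape (n, 3).

    Gravity orientation follows the posture schedule (a list of
    ``(start_s, end_s, label)`` covering the full duration); activity bursts
    add band-limited (0.5-10 Hz) high-variance noise on all axes.
    """
    if not posture_schedule:
        raise ValueError("posture schedule must cover the recording")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    duration = max(end for _, end, _ in posture_schedule)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    y = np.full((n, 3), np.nan)
    for start, end, label in posture_schedule:
        if label not in _POSTURE_GRAVITY:
            raise ValueError(f"unknown posture label {label!r}")
        sel = (t >= start) & (t < end)
        y[sel] = _POSTURE_GRAVITY[label]
    if np.any(np.isnan(y)):
        raise ValueError("posture schedule leaves gaps in the recording")
    y += rng.normal(0.0, noise_sd, y.shape)
    if activity_bursts:
        from scipy import signal as sps

        sos = sps.butter(2, [0.5, min(10.0, 0.45 * fs)], btype="bandpass",
                         fs=fs, output="sos")
        for start, end in activity_bursts:
            sel = (t >= start) & (t < end)
            if sel.sum() > 30:
                burst = sps.sosfiltfilt(sos, rng.normal(0, burst_sd,
                                                        (sel.sum(), 3)), axis=0)
                y[sel] += burst
    return y


# ---------------------------------------------------------------------------
# Dose-response study generator
# ---------------------------------------------------------------------------

def _segment_record(cfg: SimConfig, rng: np.random.Generator, subject: str,
                    state: str, oh: bool, dose: float, mean_hr: float,
                    pep_base: float, pep_shift: float,
                    ) -> tuple[WaveformRecord, SimTruth]:
    """One >=5-min seated-rest segment for one subject in one state."""
    var_scale = cfg.rmssd_on_factor_oh if (state == "ON" and oh) else 1.0
    beat_times, rr = gen_rr_series(
        cfg.segment_s, mean_hr,
        lf_amp=cfg.lf_amp * var_scale, hf_amp=cfg.hf_amp * var_scale,
        noise_sd=cfg.rr_noise_sd * var_scale, seed=rng,
        lf_freq=cfg.lf_freq, hf_freq=cfg.hf_freq)
    nb = len(beat_times)
    pep = pep_base + (pep_shift if state == "ON" else 0.0)
    amp_scale = cfg.scg_amp_ratio_on if state == "ON" else 1.0
    ppg_scale = cfg.ppg_amp_ratio_on if state == "ON" else 1.0
    pep_arr = np.full(nb, pep)
    lvet_arr = np.full(nb, cfg.lvet_off)
    pat_arr = np.full(nb, cfg.pat_off + (pep - cfg.pep_off))
    truth = SimTruth(beat_times, rr, pep_arr, lvet_arr, pat_arr,
                     state=state, oh_flag=oh, posture="seated")

    ecg = gen_ecg(beat_times, cfg.segment_s, FS_ECG, cfg.noise_sd_ecg,
                  amp=cfg.ecg_amp, seed=rng)
    scg = gen_scg(beat_times, pep_arr, lvet_arr, amp=cfg.scg_amp * amp_scale,
                  duration_s=cfg.segment_s, fs=FS_SCG,
                  noise_sd=cfg.noise_sd_scg, seed=rng)
    ppg = gen_ppg(beat_times, pat_arr, cfg.ppg_amp * ppg_scale,
                  duration_s=cfg.segment_s, fs=FS_PPG,
                  noise_sd=cfg.noise_sd_ppg, seed=rng)
    n_bursts = rng.poisson(cfg.artifact_rate * cfg.segment_s / 60.0)
    bursts = []
    for _ in range(n_bursts):
        b0 = rng.uniform(0, cfg.segment_s - 5.0)
        bursts.append((b0, b0 + rng.uniform(1.0, 4.0)))
        sel_s = slice(int(b0 * FS_SCG), int(bursts[-1][1] * FS_SCG))
        scg[sel_s] += rng.normal(0, 3 * cfg.noise_sd_scg,
                                 scg[sel_s].shape)
        sel_p = slice(int(b0 * FS_PPG), int(bursts[-1][1] * FS_PPG))
        ppg[sel_p] += rng.normal(0, 3 * cfg.noise_sd_ppg,
                                 ppg[sel_p].shape)
    accel = gen_accel([(0.0, cfg.segment_s, "seated")], bursts,
                      fs=FS_ACCEL, noise_sd=cfg.noise_sd_accel, seed=rng)
    channels = {
        "ecg": Channel(ecg, FS_ECG),
        "scg_z": Channel(scg, FS_SCG),
        "ppg_ir": Channel(ppg, FS_PPG),
        "accel_x": Channel(accel[:, 0], FS_ACCEL),
        "accel_y": Channel(accel[:, 1], FS_ACCEL),
        "accel_z": Channel(accel[:, 2], FS_ACCEL),
    }
    meta = {
        "subject": subject, "setting": "clinic", "state": state,
        "oh_flag": bool(oh), "dose_mg": float(dose),
        "posture": "seated",
        "truth": {
            "beat_times": truth.beat_times, "rr_ms": truth.rr_ms,
            "pep_ms": pep_arr, "lvet_ms": lvet_arr, "pat_ms": pat_arr,
        },
    }
    return WaveformRecord(channels, meta), truth


def gen_dose_response(cfg: SimConfig
                      ) -> list[dict]:
    """Per-subject OFF and ON recordings plus ground truth.

    Returns one dict per subject with keys ``subject``, ``oh_flag``,
    ``dose_mg``, ``off``/``on`` (:class:`~cvawear.io.WaveformRecord`) and
    ``truth_off``/``truth_on`` (:class:`SimTruth`).  Fully deterministic for
    a given config (all randomness flows from ``cfg.seed``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    doses = cfg.doses()
    n_oh = int(round(cfg.oh_fraction * cfg.n_subjects))
    out = []
    for i in range(cfg.n_subjects):
        subject = f"S{i + 1:02d}"
        oh = i < n_oh
        mean_hr = float(np.clip(rng.normal(cfg.mean_hr, cfg.hr_between_sd),
                                45, 170))
        pep_base = max(40.0, rng.normal(cfg.pep_off, cfg.pep_between_sd))
        # dose-scaled mean response plus between-subject heterogeneity
        pep_shift = (cfg.delta_pep_per_100mg * doses[i] / 100.0
                     + (rng.normal(0.0, cfg.delta_pep_between_sd)
                        if cfg.delta_pep_between_sd > 0 else 0.0))
        rec_off, tr_off = _segment_record(cfg, rng, subject, "OFF", oh,
                                          doses[i], mean_hr, pep_base,
                                          pep_shift)
        rec_on, tr_on = _segment_record(cfg, rng, subject, "ON", oh,
                                        doses[i], mean_hr, pep_base,
                                        pep_shift)
        out.append({"subject": subject, "oh_flag": oh, "dose_mg": doses[i],
                    "off": rec_off, "on": rec_on,
                    "truth_off": tr_off, "truth_on": tr_on})
    return out
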