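"""Physiomarker extraction: HRV indices, systolic timings, amplitudes.

Thirteen markers are computed per 5-min analysis window:

* ECG / rhythm: HR, RMSSD, SDNN, LF power, HF power, LF/HF ratio.  Gaps in
  the screened NN series are filled with monotone pchip interpolation over
  beat index; spectra use an 8 Hz evenly resampled tachogram and an
  averaged periodogram (segment length covering two cycles of 0.013 Hz,
  50 % overlap) integrated over the LF [0.04-0.15 Hz] and HF [0.15-0.4 Hz]
  bands.
* SCG (cardiomechanical): aortic-opening (AO) and aortic-closing (AC)
  fiducials give PEP (R->AO), LVET (AO->AC), the HR-corrected LVETi and
  PEP/LVETi; the AO complex's peak-to-trough range is SCGamp.  Because SCG
  morphology varies between people, several prominent peaks/valleys are
  tracked across beats as fiducial candidates, candidates whose
  beat-to-beat timing series covary (pairwise r >= 0.5, majority cluster)
  are retained, and AO/AC are per-beat medians over the retained tracks.
* PPG (vasomotor): the pulse foot is the median of six classical onset
  estimators (argmax, argmin, max first and second derivative, 20 % of
  pulse height, intersecting tangents); PAT is R->foot, PPGamp the pulse
  range, and PTT = PAT - PEP by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator, interp1d

from . import beats as _beats
from . import quality as _quality
from .beats import NNSeries, RPeakSet, clean_nn, detect_rpeaks, fuse_rpeaks
from .io import WaveformRecord
from .quality import BeatMatrix, quality_pipeline

__all__ = [
    "MARKER_NAMES",
    "interpolate_nn_gaps",
    "rmssd",
    "sdnn",
    "nn_spectrum",
    "detect_ao_ac",
    "systolic_intervals",
    "scg_amplitude",
    "ppg_foot",
    "ppg_amplitude",
    "pat_from_foot",
    "ptt_from_pat_pep",
    "extract_window_markers",
    "build_marker_table",
]

MARKER_NAMES = ["HR", "RMSSD", "SDNN", "LF", "HF", "LF_HF",
                "PEP", "LVETi", "PEP_LVETi", "SCGamp", "PPGamp", "PAT", "PTT"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
#: Search windows for SCG fiducial candidates, ms after the R-peak.
AO_WINDOW_MS = (20.0, 180.0)
AC_WINDOW_MS = (250.0, 450.0)
#: Additive HR correction slope for LVET (Weissler-style), ms per bpm.
C_HR_DEFAULT = 1.7


# ---------------------------------------------------------------------------
# HRV: time domain
# ---------------------------------------------------------------------------

def interpolate_nn_gaps(nn: NNSeries) -> tuple[np.ndarray, np.ndarray]:
    """Fill masked NN intervals by monotone pchip over beat index.

    Returns ``(times, nn_filled)`` of full length; valid values untouched.
    """
    if nn.valid.sum() < 2:
        raise ValueError("need at least 2 valid NN intervals to interpolate")
    idx = np.arange(len(nn.nn_ms))
    filled = nn.nn_ms.copy()
    if not nn.valid.all():
        interp = PchipInterpolator(idx[nn.valid], nn.nn_ms[nn.valid],
                                   extrapolate=True)
        filled[~nn.valid] = interp(idx[~nn.valid])
    return nn.times, filled


def rmssd(nn_ms: np.ndarray) -> float:
    """Root mean square of successive NN differences (ms)."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if len(nn_ms) < 2:
        raise ValueError("need >= 2 intervals")
    d = np.diff(nn_ms)
    return float(np.sqrt(np.mean(d ** 2)))


def sdnn(nn_ms: np.ndarray) -> float:
    """Sample standard deviation (n-1) of NN intervals (ms)."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if len(nn_ms) < 2:
        raise ValueError("need >= 2 intervals")
    return float(np.std(nn_ms, ddof=1))


# ---------------------------------------------------------------------------
# HRV: frequency domain
# ---------------------------------------------------------------------------

def nn_spectrum(times_s: np.ndarray, nn_ms: np.ndarray, fs_interp: float = 8.0,
                min_freq: float = 0.013) -> tuple[float, float, float]:
    """LF power, HF power (ms^2) and LF/HF ratio of a gap-filled NN series.

    The tachogram is cubic-interpolated onto an evenly spaced ``fs_interp``
    grid and fed to an averaged periodogram whose segment length covers two
    cycles of ``min_freq`` (capped at the series length) with 50 % overlap.
    """
    times_s = np.asarray(times_s, dtype=float)
    nn_ms = np.asarray(nn_ms, dtype=float)
    if len(nn_ms) < 4:
        raise ValueError("series too short for spectral analysis")
    grid = np.arange(times_s[0], times_s[-1], 1.0 / fs_interp)
    kind = "cubic" if len(nn_ms) >= 4 else "linear"
    tach = interp1d(times_s, nn_ms, kind=kind)(grid)
    nperseg = int(round(2.0 / min_freq * fs_interp))
    if nperseg > len(tach):
        warnings.warn("series shorter than one spectral segment; "
                      "falling back to a single segment")
        nperseg = len(tach)
    f, pxx = sps.welch(tach, fs=fs_interp, nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")
    lf = float(np.trapezoid(pxx[(f >= LF_BAND[0]) & (f < LF_BAND[1])],
                            f[(f >= LF_BAND[0]) & (f < LF_BAND[1])]))
    hf = float(np.trapezoid(pxx[(f >= HF_BAND[0]) & (f < HF_BAND[1])],
                            f[(f >= HF_BAND[0]) & (f < HF_BAND[1])]))
    ratio = lf / hf if hf > 0 else np.nan
    return lf, hf, ratio


# ---------------------------------------------------------------------------
# SCG fiducials
# ---------------------------------------------------------------------------

def _window_extrema(beat: np.ndarray, fs: float, win_ms: tuple[float, float],
                    prominence_frac: float = 0.10) -> np.ndarray:
    """Times (ms from beat start) of salient peaks/valleys inside a window."""
    a = int(round(win_ms[0] * fs / 1000.0))
    b = int(round(win_ms[1] * fs / 1000.0))
    seg = beat[a:min(b, len(beat))]
    if len(seg) < 3 or np.ptp(seg) == 0:
        return np.array([])
    prom = prominence_frac * np.ptp(seg)
    out = []
    for sgn in (1.0, -1.0):
        pk, _ = sps.find_peaks(sgn * seg, prominence=prom)
        out.extend(pk.tolist())
    return (a + np.sort(np.array(out, dtype=float))) * 1000.0 / fs


def _track_candidates(cands: list[np.ndarray], match_tol_ms: float = 15.0,
                      min_coverage: float = 0.5) -> np.ndarray:
    """Associate per-beat candidate times into tracks by temporal proximity.

    Returns a (n_tracks, n_beats) matrix of times (ms), NaN where a track
    has no candidate on a beat; tracks present on < ``min_coverage`` of
    beats are dropped.
    """
    n = len(cands)
    tracks: list[dict[int, float]] = []
    last: list[float] = []
    for bi, ct in enumerate(cands):
        used = np.zeros(len(ct), dtype=bool)
        if tracks:
            order = sorted(
                ((abs(t - last[ti]), ti, ci)
                 for ti in range(len(tracks))
                 for ci, t in enumerate(ct)
                 if abs(t - last[ti]) <= match_tol_ms),
            )
            claimed = set()
            for _, ti, ci in order:
                if ti not in claimed and not used[ci]:
                    tracks[ti][bi] = ct[ci]
                    last[ti] = ct[ci]
                    claimed.add(ti)
                    used[ci] = True
        for ci, t in enumerate(ct):
            if not used[ci]:
                tracks.append({bi: t})
                last.append(t)
    mat = np.full((len(tracks), n), np.nan)
    for ti, tr in enumerate(tracks):
        for bi, t in tr.items():
            mat[ti, bi] = t
    cover = (~np.isnan(mat)).mean(axis=1)
    return mat[cover >= min_coverage]


def _covarying_tracks(mat: np.ndarray, r_min: float = 0.5,
                      parallel_tol_ms: float = 3.0) -> np.ndarray:
    """Retain the majority cluster of mutually covarying tracks.

    Two tracks covary when their beat-to-beat timing series correlate
    (Pearson r >= ``r_min`` on overlapping beats) or move in lockstep (the
    difference series has std below ``parallel_tol_ms`` — covering constant
    and parallel tracks, whose correlation is dominated by sample-grid
    jitter).  Edges define a graph whose largest connected component is
    kept.
    """
    k = mat.shape[0]
    if k <= 1:
        return mat
    adj = np.eye(k, dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if both.sum() < 3:
                continue
            xi, xj = mat[i, both], mat[j, both]
            if np.std(xi - xj) < parallel_tol_ms:
                edge = True
            elif xi.std() == 0 or xj.std() == 0:
                edge = False
            else:
                edge = float(np.corrcoef(xi, xj)[0, 1]) >= r_min
            adj[i, j] = adj[j, i] = edge
    # connected components by BFS
    comp = -np.ones(k, dtype=int)
    c = 0
    for s in range(k):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    sizes = np.bincount(comp)
    return mat[comp == int(np.argmax(sizes))]


def detect_ao_ac(ens: BeatMatrix,
                 ao_window_ms: tuple[float, float] = AO_WINDOW_MS,
                 ac_window_ms: tuple[float, float] = AC_WINDOW_MS,
                 ) -> pd.DataFrame:
    """Per-ensemble-beat AO and AC fiducial times (ms from the R-peak).

    Candidate extrema inside each search window are tracked across beats;
    tracks whose timing series covary with the majority cluster are
    retained, and the fiducial is the per-beat median over retained tracks.
    Beats with no extremum in a window get NaN (explicitly missing).
    """
    if len(ens) < 10:
        raise ValueError("need >= 10 ensemble beats for covariance tracking")
    out = {}
    for name, win in (("ao", ao_window_ms), ("ac", ac_window_ms)):
        cands = [_window_extrema(b, ens.fs, win) for b in ens.beats]
        mat = _track_candidates(cands)
        if mat.size == 0:
            out[name] = np.full(len(ens), np.nan)
            continue
        mat = _covarying_tracks(mat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = np.nanmedian(mat, axis=0)
    return pd.DataFrame({"time_s": ens.times, "ao": out["ao"],
                         "ac": out["ac"]})


def systolic_intervals(ao: float | np.ndarray, ac: float | np.ndarray,
                       hr: float, c_hr: float = C_HR_DEFAULT,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                  np.ndarray]:
    """PEP, LVET, HR-corrected LVETi and PEP/LVETi from AO/AC times (ms).

    PEP = AO (ms from R); LVET = AC - AO; LVETi = LVET + c_hr * HR with the
    additive correction slope ``c_hr`` (ms/bpm); ratio = PEP / LVETi.
    """
    ao = np.asarray(ao, dtype=float)
    ac = np.asarray(ac, dtype=float)
    if not 40 <= hr <= 180:
        raise ValueError("hr outside the physiological 40-180 bpm band")
    if np.any(ac <= ao):
        raise ValueError("AC must come after AO")
    pep = ao
    lvet = ac - ao
    lveti = lvet + c_hr * hr
    return pep, lvet, lveti, pep / lveti


def scg_amplitude(beat: np.ndarray, ao_ms: float, fs: float,
                  half_window_ms: float = 50.0) -> float:
    """Peak-to-trough range of the AO complex (ao +- half window)."""
    a = int(round((ao_ms - half_window_ms) * fs / 1000.0))
    b = int(round((ao_ms + half_window_ms) * fs / 1000.0))
    a = max(a, 0)
    if b <= a or a >= len(beat):
        raise ValueError("AO window falls outside the beat")
    seg = beat[a:min(b, len(beat))]
    return float(seg.max() - seg.min())


# ---------------------------------------------------------------------------
# PPG fiducials
# ---------------------------------------------------------------------------

def ppg_foot(beat: np.ndarray, fs: float,
             ) -> tuple[float, dict[str, float]] | tuple[float, dict]:
    """Pulse-foot time (ms from beat start): median of six onset estimators.

    Estimators: pulse argmax; last minimum before the peak; maximum first
    derivative on the upstroke; maximum second derivative on the upstroke;
    first crossing of 20 % of pulse height; intersection of the upstroke
    tangent with the horizontal baseline through the minimum.  Returns
    ``(nan, {})`` for a flat or monotone-degenerate beat.
    """
    x = np.asarray(beat, dtype=float)
    if np.ptp(x) == 0 or len(x) < 5:
        return float("nan"), {}
    imax = int(np.argmax(x))
    if imax < 2:
        return float("nan"), {}
    pre = x[:imax + 1]
    xmin = pre.min()
    imin = int(np.flatnonzero(pre <= xmin + 1e-12 * max(np.ptp(x), 1.0))[-1])
    ms = 1000.0 / fs
    d1 = np.gradient(x)
    d2 = np.gradient(d1)
    up = slice(imin, imax + 1)

    def first_near_max(v: np.ndarray) -> int:
        # earliest sample attaining the maximum (ties broken toward the
        # foot; plateaus of constant slope otherwise resolve by float ulps)
        vmax = v.max()
        tol = 1e-9 * max(abs(vmax), 1e-30)
        return int(np.flatnonzero(v >= vmax - tol)[0])

    i_d1 = imin + first_near_max(d1[up])
    i_d2 = imin + first_near_max(d2[up])
    # 20 % crossing, sub-sample by linear interpolation
    level = xmin + 0.2 * (x[imax] - xmin)
    above = np.flatnonzero(x[imin:imax + 1] >= level)
    if len(above) == 0:
        t20 = float(imax) * ms
    else:
        k = imin + int(above[0])
        if k == imin or x[k] == x[k - 1]:
            t20 = k * ms
        else:
            frac = (level - x[k - 1]) / (x[k] - x[k - 1])
            t20 = (k - 1 + frac) * ms
    slope = d1[i_d1]
    t_tan = (i_d1 - (x[i_d1] - xmin) / slope) * ms if slope > 0 \
        else float(imin) * ms
    est = {
        "argmax": imax * ms,
        "argmin": imin * ms,
        "d1max": i_d1 * ms,
        "d2max": i_d2 * ms,
        "p20": t20,
        "tangents": t_tan,
    }
    return float(np.median(list(est.values()))), est


def ppg_amplitude(beat: np.ndarray) -> float:
    """Pulse amplitude: max minus min of the beat."""
    beat = np.asarray(beat, dtype=float)
    if beat.size == 0:
        raise ValueError("empty beat")
    return float(beat.max() - beat.min())


def pat_from_foot(foot_ms: float) -> float:
    """Pulse arrival time: the foot time measured from the R-peak anchor."""
    return float(foot_ms)


def ptt_from_pat_pep(pat_ms: float, pep_ms: float) -> float:
    """Pulse transit time = PAT - PEP; non-positive values are implausible."""
    ptt = pat_ms - pep_ms
    if ptt <= 0:
        raise ValueError(f"implausible PTT {ptt:.1f} ms (PAT <= PEP)")
    return float(ptt)


# ---------------------------------------------------------------------------
# Window-level orchestration
# ---------------------------------------------------------------------------

def _slice_channel(rec: WaveformRecord, name: str, t0: float, t1: float,
                   ) -> tuple[np.ndarray, float]:
    ch = rec[name]
    a = int(round((t0 - ch.start) * ch.fs))
    b = int(round((t1 - ch.start) * ch.fs))
    return ch.samples[max(a, 0):b], ch.fs


def extract_window_markers(rec: WaveformRecord,
                           window: tuple[float, float] | None = None,
                           c_hr: float = C_HR_DEFAULT) -> dict[str, float]:
    """All 13 physiomarkers for one >= 5-min window of a preprocessed record.

    ``rec`` must already be resampled/filtered (see
    :func:`cvawear.io.preprocess_record`).  Markers that cannot be computed
    are returned as NaN, never silently zero.  Window-level timing markers
    are medians over the ensemble beats; PTT = PAT - PEP holds exactly.
    """
    if window is None:
        dur = rec["ecg"].duration
        window = (rec["ecg"].start, rec["ecg"].start + dur)
    t0, t1 = window
    if t1 - t0 < 300:
        raise ValueError("analysis window must be >= 5 min")
    out: dict[str, float] = {m: float("nan") for m in MARKER_NAMES}

    ecg, fs = _slice_channel(rec, "ecg", t0, t1)
    ref = detect_rpeaks(ecg, fs, _beats.REFERENCE_DETECTOR)
    others = [detect_rpeaks(ecg, fs, m) for m in _beats.DETECTORS
              if m != _beats.REFERENCE_DETECTOR]
    fused = fuse_rpeaks(ref, others)
    if len(fused) < 10:
        return out
    nn = clean_nn(fused)
    if nn.valid.sum() >= 2:
        times, filled = interpolate_nn_gaps(nn)
        out["HR"] = 60_000.0 / float(np.mean(filled))
        out["RMSSD"] = rmssd(filled)
        out["SDNN"] = sdnn(filled)
        try:
            out["LF"], out["HF"], out["LF_HF"] = nn_spectrum(times, filled)
        except ValueError:
            pass

    hr = out["HR"]
    peak_times = fused.times

    if "scg_z" in rec:
        scg, fs_s = _slice_channel(rec, "scg_z", t0, t1)
        _, ens = quality_pipeline(scg, fs_s, peak_times, "scg")
        if len(ens) >= 10:
            fid = detect_ao_ac(ens)
            ok = fid.dropna(subset=["ao", "ac"])
            ok = ok[ok["ac"] > ok["ao"]]
            if len(ok) and not np.isnan(hr):
                ao = float(np.median(ok["ao"]))
                ac = float(np.median(ok["ac"]))
                pep, lvet, lveti, ratio = systolic_intervals(ao, ac, hr, c_hr)
                out["PEP"] = float(pep)
                out["LVETi"] = float(lveti)
                out["PEP_LVETi"] = float(ratio)
                amps = []
                for i in ok.index:
                    try:
                        amps.append(scg_amplitude(ens.beats[i],
                                                  float(fid.loc[i, "ao"]),
                                                  ens.fs))
                    except ValueError:
                        pass
                if amps:
                    out["SCGamp"] = float(np.median(amps))

    if "ppg_ir" in rec:
        ppg, fs_p = _slice_channel(rec, "ppg_ir", t0, t1)
        _, ens_p = quality_pipeline(ppg, fs_p, peak_times, "ppg")
        if len(ens_p) >= 1:
            feet, amps_p = [], []
            for b in ens_p.beats:
                f, _ = ppg_foot(b, ens_p.fs)
                if np.isfinite(f):
                    feet.append(f)
                    amps_p.append(ppg_amplitude(b))
            if feet:
                out["PAT"] = float(np.median(feet))
                out["PPGamp"] = float(np.median(amps_p))

    if np.isfinite(out["PAT"]) and np.isfinite(out["PEP"]):
        ptt = out["PAT"] - out["PEP"]
        out["PTT"] = ptt if ptt > 0 else float("nan")
    return out


def build_marker_table(subjects: list[dict], setting: str = "clinic",
                       window: tuple[float, float] | None = None,
                       ) -> pd.DataFrame:
    """MarkerTable from simulated subjects (see ``simulate.gen_dose_response``).

    One row per (subject, state, window) with all 13 markers plus the keys
    the statistics layer needs (``oh`` flag, dose).  Records are
    preprocessed (resampled + band-passed) before extraction.
    """
    from .io import preprocess_record

    rows = []
    for s in subjects:
        for state in ("OFF", "ON"):
            rec = preprocess_record(s["off" if state == "OFF" else "on"])
            dur = rec["ecg"].duration
            win = window or (max(0.0, (dur - 300.0) / 2),
                             max(0.0, (dur - 300.0) / 2) + 300.0)
            m = extract_window_markers(rec, win)
            rows.append({"subject": s["subject"], "setting": setting,
                         "state": state, "window_id": 0,
                         "dose_mg": s["dose_mg"], "oh": bool(s["oh_flag"]),
                         **m})
    return pd.DataFrame(rows)
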