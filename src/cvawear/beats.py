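"""R-peak detection, multi-detector fusion and NN-interval screening.

Three independent R-peak detectors run on the 500 Hz single-lead ECG:

* ``gradient`` — smoothed absolute-gradient envelope thresholding,
* ``swt`` — stationary wavelet transform, squared detail coefficients at the
  QRS scale,
* ``pantompkins`` — the classic 5-15 Hz band-pass / differentiate / square /
  moving-window-integrate chain.

All three work on polarity-invariant envelopes, so inverted leads are
handled.  Their outputs are fused with the gradient detector as reference:
a reference peak survives only if at least one other detector placed a peak
within a lenient 150 ms tolerance (greedy one-to-one nearest-neighbour
matching).  The fused peaks form RR intervals that are screened in two
stages: a physiological band (40-180 bpm, i.e. 333.3-1500 ms, inclusive) and
a robust sliding-window outlier rule (30-beat windows, 90 % overlap, +-5
median absolute deviations from the window median).  Surviving intervals are
the normal-to-normal (NN) series used for HRV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "RPeakSet",
    "NNSeries",
    "detect_rpeaks",
    "fuse_rpeaks",
    "build_nn",
    "flag_outliers_mad",
    "clean_nn",
    "DETECTORS",
    "FUSION_TOL_S",
    "NN_BOUNDS_MS",
]

FUSION_TOL_S = 0.150
#: Inclusive physiological RR bounds, 40-180 bpm.
NN_BOUNDS_MS = (60_000.0 / 180.0, 60_000.0 / 40.0)


@dataclass
class RPeakSet:
    detector: str
    times: np.ndarray  # seconds, strictly increasing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class NNSeries:
    """RR intervals with validity mask and per-interval removal reasons.

    ``times`` holds the time of the *closing* peak of each interval, so
    ``nn_ms[i]`` spans ``(times[i] - nn_ms[i]/1000, times[i])``.
    """

    times: np.ndarray
    nn_ms: np.ndarray
    valid: np.ndarray
    reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reason is None:
            self.reason = np.where(self.valid, "", "unknown")
        for name in ("times", "nn_ms"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.times) == len(self.nn_ms) == len(self.valid)
                == len(self.reason)):
            raise ValueError("field lengths differ")
        if np.any((~self.valid) & (np.asarray(self.reason) == "")):
            raise ValueError("every masked interval needs a removal reason")

    def accepted(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times[self.valid], self.nn_ms[self.valid]


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _envelope_peaks(env: np.ndarray, fs: float, refractory_s: float = 0.25,
                    rel_height: float = 0.35) -> np.ndarray:
    """Indices of envelope peaks above ``rel_height`` x a robust maximum."""
    if env.max() <= 0:
        return np.array([], dtype=int)
    # robust ceiling: 98th percentile of the envelope's local maxima
    cand, _ = sps.find_peaks(env, distance=max(1, int(refractory_s * fs)))
    if len(cand) == 0:
        return np.array([], dtype=int)
    ceiling = np.percentile(env[cand], 98)
    if ceiling <= 0:
        return np.array([], dtype=int)
    keep = cand[env[cand] >= rel_height * ceiling]
    return keep


def _refine_to_r(ecg: np.ndarray, fs: float, idx: np.ndarray,
                 search_s: float = 0.05) -> np.ndarray:
    """Snap envelope peaks to the dominant |ECG| extremum nearby."""
    half = int(search_s * fs)
    x = ecg - np.median(ecg)
    out = []
    for i in idx:
        a, b = max(0, i - half), min(len(x), i + half + 1)
        out.append(a + int(np.argmax(np.abs(x[a:b]))))
    out = np.unique(out)
    return out


def _detect_gradient(ecg: np.ndarray, fs: float) -> np.ndarray:
    grad = np.gradient(ecg) ** 2
    win = max(1, int(0.08 * fs))
    env = np.convolve(grad, np.ones(win) / win, mode="same")
    return _envelope_peaks(env, fs)


def _detect_swt(ecg: np.ndarray, fs: float) -> np.ndarray:
    import pywt

    level = 4  # detail scale ~15-30 Hz at 500 Hz: QRS energy
    pad = (-len(ecg)) % (2 ** level)
    x = np.pad(ecg, (0, pad), mode="edge")
    coeffs = pywt.swt(x, "db3", level=level, trim_approx=True)
    d = coeffs[1]  # detail at the coarsest kept scale
    env = d[:len(ecg)] ** 2
    win = max(1, int(0.08 * fs))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    return _envelope_peaks(env, fs)


def _detect_pantompkins(ecg: np.ndarray, fs: float) -> np.ndarray:
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(y)
    sq = deriv ** 2
    win = max(1, int(0.150 * fs))
    env = np.convolve(sq, np.ones(win) / win, mode="same")
    return _envelope_peaks(env, fs)


DETECTORS = {
    "gradient": _detect_gradient,
    "swt": _detect_swt,
    "pantompkins": _detect_pantompkins,
}

#: Detector used as the fusion reference.
REFERENCE_DETECTOR = "gradient"


def detect_rpeaks(ecg: np.ndarray, fs: float, method: str = "gradient",
                  ) -> RPeakSet:
    """Locate R-peaks with one of the three detection strategies."""
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 10 * fs:
        raise ValueError("ECG shorter than 10 s")
    if method not in DETECTORS:
        raise ValueError(f"unknown method {method!r}; "
                         f"choose from {sorted(DETECTORS)}")
    if np.ptp(ecg) == 0:
        return RPeakSet(method, np.array([]))
    idx = DETECTORS[method](ecg, fs)
    # discard peaks hugging the record edges (filter / template truncation)
    edge = int(0.2 * fs)
    idx = idx[(idx >= edge) & (idx < len(ecg) - edge)]
    idx = _refine_to_r(ecg, fs, idx)
    return RPeakSet(method, idx / fs)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def _match_one_to_one(ref: np.ndarray, other: np.ndarray, tol: float,
                      ) -> np.ndarray:
    """Boolean mask over ``ref``: matched one-to-one within ``tol`` (inclusive).

    Greedy by increasing time difference; no peak from ``other`` is reused.
    """
    if len(ref) == 0 or len(other) == 0:
        return np.zeros(len(ref), dtype=bool)
    pairs = []
    for i, t in enumerate(ref):
        lo = int(np.searchsorted(other, t - tol))
        hi = int(np.searchsorted(other, t + tol, side="right"))
        for jj in range(lo, hi):
            dt = abs(other[jj] - t)
            if dt <= tol:
                pairs.append((dt, i, jj))
    matched_ref = np.zeros(len(ref), dtype=bool)
    used_other = np.zeros(len(other), dtype=bool)
    for dt, i, jj in sorted(pairs):
        if not matched_ref[i] and not used_other[jj]:
            matched_ref[i] = True
            used_other[jj] = True
    return matched_ref


def fuse_rpeaks(reference: RPeakSet, others: list[RPeakSet],
                tol: float = FUSION_TOL_S, min_confirm: int = 1) -> RPeakSet:
    """Keep reference peaks confirmed by >= ``min_confirm`` other detectors.

    Matching is greedy nearest-neighbour with a one-to-one constraint per
    detector pair; the tolerance is inclusive.  An empty reference yields an
    empty fused set.
    """
    ref = reference.times
    if len(ref) == 0:
        return RPeakSet("fused", np.array([]))
    confirms = np.zeros(len(ref), dtype=int)
    for other in others:
        confirms += _match_one_to_one(ref, other.times, tol)
    return RPeakSet("fused", ref[confirms >= min_confirm])


# ---------------------------------------------------------------------------
# NN construction and screening
# ---------------------------------------------------------------------------

def build_nn(peaks: RPeakSet | np.ndarray) -> NNSeries:
    """RR intervals with the physiological 40-180 bpm screen applied."""
    times = peaks.times if isinstance(peaks, RPeakSet) else np.asarray(peaks,
                                                                       float)
    if len(times) < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    nn = np.diff(times) * 1000.0
    lo, hi = NN_BOUNDS_MS
    eps = 1e-9  # keep the closed bounds closed under float round-off
    valid = (nn >= lo - eps) & (nn <= hi + eps)
    reason = np.where(valid, "", "physiological")
    return NNSeries(times[1:], nn, valid, reason)


def flag_outliers_mad(series: np.ndarray, window: int = 30,
                      overlap: float = 0.9, k: float = 5.0,
                      mad_floor: float = 1.0) -> np.ndarray:
    """Sliding-window robust outlier flags.

    A value is flagged iff it deviates from the median of *any* covering
    window by more than ``k`` MADs.  Windows are ``window`` beats long with
    ``overlap`` fractional overlap (30 beats / 90 % -> step 3); the last
    window is anchored to the series end so trailing beats are covered.
    When a window's MAD is zero the rule degenerates to an absolute floor
    (``mad_floor``, ms) so quantised series are not all-flagged.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return np.zeros(n, dtype=bool)
    step = max(1, int(round(window * (1.0 - overlap))))
    if n <= window:
        starts = [0]
        window = n
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] != n - window:
            starts.append(n - window)
    flags = np.zeros(n, dtype=bool)
    for s in starts:
        w = x[s:s + window]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        thresh = k * mad if mad > 0 else mad_floor
        flags[s:s + window] |= np.abs(w - med) > thresh
    return flags


def clean_nn(peaks: RPeakSet | np.ndarray, window: int = 30,
             overlap: float = 0.9, k: float = 5.0) -> NNSeries:
    """Full screening cascade: physiological bounds then MAD outlier flags.

    The MAD stage sees only intervals that passed the physiological screen,
    so a gross artifact cannot poison a window median twice.  Interval
    conservation holds: every raw interval is accepted or carries a reason.
    """
    nn = build_nn(peaks)
    phys_ok = nn.valid.copy()
    sub = nn.nn_ms[phys_ok]
    if len(sub) >= 2:
        out = flag_outliers_mad(sub, window=window, overlap=overlap, k=k)
        idx = np.flatnonzero(phys_ok)[out]
        nn.valid[idx] = False
        reason = np.asarray(nn.reason, dtype=object)
        reason[idx] = "mad_outlier"
        nn.reason = reason.astype(str)
    return nn
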