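"""Selection of 5-min OFF and ON analysis windows around each levodopa dose.

The OFF window is the nearest 5-min rest period ending at or before the
logged administration time; the ON window sits as close to dose + 60 min as
the data allow.  Both must be quiet (accelerometer activity index below a
rest threshold, including a 2-min guard band before each window) and share
the same posture class, mirroring the constraints a clinician applies when
reading seated-rest physiology.  Pairs that cannot satisfy the constraints
are rejected with a typed reason rather than silently skipped.

Posture comes from the gravity vector seen by the chest patch: the angle
between the mean acceleration and the torso longitudinal axis is small when
upright (seated and standing are not separable from a chest sensor and share
one "upright" class) and near 90 degrees when supine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "DoseEvent",
    "AnalysisWindowPair",
    "PairRejection",
    "activity_index",
    "posture_estimate",
    "select_pair",
]

WINDOW_S = 300.0
TARGET_SEPARATION_S = 3600.0
GUARD_S = 120.0
SEARCH_STEP_S = 30.0
#: Accepted separations (min) between OFF and ON windows.
SEPARATION_BOUNDS_MIN = (45.0, 90.0)


@dataclass
class DoseEvent:
    time_s: float
    dose_mg: float
    source: str = "diary"  # clinic | diary


@dataclass
class AnalysisWindowPair:
    off_window: tuple[float, float]
    on_window: tuple[float, float]
    posture: str
    off_activity: float
    on_activity: float

    @property
    def separation_min(self) -> float:
        off_c = 0.5 * (self.off_window[0] + self.off_window[1])
        on_c = 0.5 * (self.on_window[0] + self.on_window[1])
        return (on_c - off_c) / 60.0


@dataclass
class PairRejection:
    reason: str  # posture_mismatch | no_rest_window | insufficient_recording
    detail: str = ""


def activity_index(accel: np.ndarray, fs: float, epoch_s: float = 10.0,
                   ) -> np.ndarray:
    """Per-epoch movement intensity: variance of the magnitude of the
    0.5-10 Hz band-passed acceleration.  Filtering each axis before taking
    the magnitude makes the index exactly invariant to the constant
    gravity offset."""
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[1] != 3:
        raise ValueError("triaxial accelerometer (n, 3) required")
    hi = min(10.0, 0.45 * fs)
    sos = sps.butter(2, [0.5, hi], btype="bandpass", fs=fs, output="sos")
    bp = np.linalg.norm(sps.sosfiltfilt(sos, accel, axis=0), axis=1)
    n_ep = int(len(bp) // (epoch_s * fs))
    if n_ep == 0:
        raise ValueError("recording shorter than one epoch")
    per = int(epoch_s * fs)
    return np.array([np.var(bp[i * per:(i + 1) * per]) for i in range(n_ep)])


def posture_estimate(accel: np.ndarray, fs: float, epoch_s: float = 10.0,
                     activity: np.ndarray | None = None,
                     rest_threshold: float | None = None) -> np.ndarray:
    """Posture class per epoch: ``upright`` | ``supine`` | ``transitional`` |
    ``unstable`` (high-activity epochs are never classified).

    The mean gravity vector's angle to the device longitudinal (x) axis is
    <= 30 degrees when upright and >= 60 degrees when supine.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[1] != 3:
        raise ValueError("triaxial accelerometer (n, 3) required")
    if activity is None:
        activity = activity_index(accel, fs, epoch_s)
    if rest_threshold is None:
        rest_threshold = _rest_threshold(activity)
    per = int(epoch_s * fs)
    labels = []
    for i in range(len(activity)):
        if activity[i] > rest_threshold:
            labels.append("unstable")
            continue
        g = accel[i * per:(i + 1) * per].mean(axis=0)
        norm = np.linalg.norm(g)
        if norm == 0:
            labels.append("transitional")
            continue
        angle = np.degrees(np.arccos(np.clip(abs(g[0]) / norm, -1, 1)))
        if angle <= 30:
            labels.append("upright")
        elif angle >= 60:
            labels.append("supine")
        else:
            labels.append("transitional")
    return np.array(labels)


def _rest_threshold(activity: np.ndarray) -> float:
    """Rest cut-off: 3x the record's 10th-percentile activity index."""
    return 3.0 * float(np.percentile(activity, 10))


def _window_ok(start: float, activity: np.ndarray, labels: np.ndarray,
               epoch_s: float, rest_threshold: float,
               duration_s: float = WINDOW_S, guard_s: float = GUARD_S,
               ) -> str | None:
    """Posture label if the window (plus guard band) is quiet and uniform,
    else None."""
    e0 = int((start - guard_s) // epoch_s)
    e1 = int(np.ceil((start + duration_s) / epoch_s))
    if e0 < 0 or e1 > len(activity):
        return None
    if np.any(activity[e0:e1] > rest_threshold):
        return None
    w0 = int(start // epoch_s)
    lab = labels[w0:e1]
    if len(set(lab)) != 1 or lab[0] in ("unstable", "transitional"):
        return None
    return str(lab[0])


def select_pair(accel: np.ndarray, fs: float, dose: DoseEvent,
                epoch_s: float = 10.0,
                separation_bounds_min: tuple[float, float] = SEPARATION_BOUNDS_MIN,
                ) -> AnalysisWindowPair | PairRejection:
    """Best OFF/ON 5-min window pair for one dose event, or a typed rejection.

    Candidate window starts step on a 30-s grid; the accepted pair minimises
    the distance of the OFF->ON separation from 60 min subject to rest,
    guard-band and posture-uniformity constraints.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    total_s = accel.shape[0] / fs
    if not 0 <= dose.time_s <= total_s:
        raise ValueError("dose event outside the record span")
    if total_s - dose.time_s < 65 * 60:
        return PairRejection("insufficient_recording",
                             f"only {(total_s - dose.time_s) / 60:.0f} min "
                             "after the dose")
    act = activity_index(accel, fs, epoch_s)
    thr = _rest_threshold(act)
    labels = posture_estimate(accel, fs, epoch_s, activity=act,
                              rest_threshold=thr)

    def candidates(lo: float, hi: float) -> list[tuple[float, str]]:
        out = []
        start = max(GUARD_S, np.ceil(lo / SEARCH_STEP_S) * SEARCH_STEP_S)
        while start + WINDOW_S <= hi:
            lab = _window_ok(start, act, labels, epoch_s, thr)
            if lab is not None:
                out.append((start, lab))
            start += SEARCH_STEP_S
        return out

    # search only the neighbourhood that can satisfy the separation bounds
    reach_s = separation_bounds_min[1] * 60.0 + WINDOW_S + GUARD_S
    off_c = candidates(max(0.0, dose.time_s - reach_s), dose.time_s)
    on_c = candidates(dose.time_s, min(total_s, dose.time_s + reach_s))
    if not off_c and not on_c:
        return PairRejection("no_rest_window", "no quiet window on either side")
    if not off_c:
        return PairRejection("no_rest_window", "no quiet OFF window")
    if not on_c:
        return PairRejection("no_rest_window", "no quiet ON window")

    lo_min, hi_min = separation_bounds_min
    best: tuple[float, AnalysisWindowPair] | None = None
    posture_pairs_exist = False
    for off_s, off_lab in off_c:
        for on_s, on_lab in on_c:
            sep = ((on_s + WINDOW_S / 2) - (off_s + WINDOW_S / 2)) / 60.0
            if not lo_min <= sep <= hi_min:
                continue
            posture_pairs_exist = True
            if off_lab != on_lab:
                continue
            score = abs(sep - 60.0)
            if best is None or score < best[0]:
                e_off = int(off_s // epoch_s)
                e_on = int(on_s // epoch_s)
                n_ep = int(WINDOW_S // epoch_s)
                pair = AnalysisWindowPair(
                    (off_s, off_s + WINDOW_S), (on_s, on_s + WINDOW_S),
                    off_lab,
                    float(act[e_off:e_off + n_ep].mean()),
                    float(act[e_on:e_on + n_ep].mean()))
                best = (score, pair)
    if best is not None:
        return best[1]
    if posture_pairs_exist:
        return PairRejection("posture_mismatch",
                             "no OFF/ON pair shares a posture class")
    return PairRejection("no_rest_window",
                         "no quiet pair within the separation bounds")
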