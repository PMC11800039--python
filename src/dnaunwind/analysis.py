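"""Observable extraction: rupture forces, maximum forces, energies, curves.

Two forces characterize the opening of each base pair:

- the **rupture force** F_rup — the spring tension at the moment the
  pair's CM separation *ceases to decrease*, i.e. at the last local
  minimum of the (smoothed) separation series before the threshold
  crossing, after which the separation runs away;
- the **maximum force** F_max — the tension at the first sample where the
  separation reaches the threshold (8.2 Å).  F_max is an upper bound on
  F_rup, since the pair lets go before the threshold is reached.

Thermal noise makes "ceases to decrease" ill-defined on the raw series, so
the separation is smoothed with a centred moving average (default window
50 fs) before minimum detection; tensions are always read off the raw
series.  Fixtures without noise are analyzed with the window set to 0,
where the detectors are exact on the sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .trajectory import Trajectory

__all__ = [
    "RupturePoint",
    "detect_rupture",
    "detect_fmax",
    "stage_energy_change",
    "force_extension",
    "ForceExtensionCurve",
    "rupture_report",
]


@dataclass(frozen=True)
class RupturePoint:
    force: float       # pN
    t: float           # fs
    found: bool        # False if the separation never decreased


def smooth_series(y: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average with edge clamping; window <= 1 is identity."""
    if window_samples <= 1:
        return np.asarray(y, dtype=float)
    return uniform_filter1d(np.asarray(y, dtype=float),
                            size=int(window_samples), mode="nearest")


def _window_samples(times: np.ndarray, window_fs: float) -> int:
    if len(times) < 2 or window_fs <= 0:
        return 1
    dt = float(np.median(np.diff(times)))
    w = int(round(window_fs / dt))
    return max(1, w | 1)   # odd so the average is centred


def _crossing_index(cm: np.ndarray, threshold: float) -> int:
    hits = np.nonzero(np.asarray(cm) >= threshold)[0]
    if len(hits) == 0:
        raise ValueError(
            f"CM separation never reaches the {threshold} Å threshold in "
            "this window")
    return int(hits[0])


def detect_rupture(
    times: np.ndarray,
    tension: np.ndarray,
    cm: np.ndarray,
    threshold: float = 8.2,
    smooth_window_fs: float = 50.0,
) -> RupturePoint:
    """Locate the rupture point within one pair's active window.

    The rupture time is the last local minimum of the smoothed CM series
    before the threshold crossing — equivalently, the start of the final
    non-decreasing run into the crossing; within a flat minimum the later
    sample wins.  If the series never decreases at all the window start is
    returned with ``found=False``.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ValueError("empty analysis window")
    cross = _crossing_index(cm, threshold)
    s = smooth_series(cm, _window_samples(times, smooth_window_fs))[: cross + 1]
    diffs = np.diff(s)
    desc = np.nonzero(diffs < 0)[0]
    if len(desc) == 0:
        return RupturePoint(force=float(tension[0]), t=float(times[0]), found=False)
    k = int(desc[-1]) + 1          # start of the final non-decreasing run
    m = k
    while m + 1 < len(s) and s[m + 1] == s[m]:
        m += 1                     # flat minimum: tie toward the later time
    return RupturePoint(force=float(tension[m]), t=float(times[m]), found=True)


def detect_fmax(
    times: np.ndarray,
    tension: np.ndarray,
    cm: np.ndarray,
    threshold: float = 8.2,
) -> tuple[float, float]:
    """Tension and time at the first sample with CM separation ≥ threshold."""
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ValueError("empty analysis window")
    cross = _crossing_index(cm, threshold)
    return float(tension[cross]), float(times[cross])


def stage_energy_change(
    traj: Trajectory,
    window_initial: tuple[float, float],
    window_final: tuple[float, float],
) -> float:
    """ΔE = ⟨potential⟩ over the final window − ⟨potential⟩ over the initial.

    Windows are (t0, t1) in fs, inclusive; they must lie inside the
    trajectory and must not overlap.  This is the net energy change between
    the equilibrated linked duplex and the separated, re-equilibrated
    strands — computed on the surrogate potential, so its value is not
    comparable to ab initio energy differences.
    """
    (a0, a1), (b0, b1) = window_initial, window_final
    if a0 >= a1 or b0 >= b1:
        raise ValueError("windows must satisfy t0 < t1")
    # identical windows are allowed (ΔE = 0 by self-difference); partial
    # overlap indicates a bookkeeping mistake and is rejected
    if (a0, a1) != (b0, b1) and a0 < b1 and b0 < a1:
        raise ValueError("windows overlap")
    t = traj.times
    if a0 < t[0] or b1 > t[-1] or b0 < t[0] or a1 > t[-1]:
        raise ValueError("window extends beyond the trajectory")
    if traj.potential is None:
        raise ValueError("trajectory carries no potential-energy series")
    m_i = traj.pair_window(a0, a1)
    m_f = traj.pair_window(b0, b1)
    if not m_i.any() or not m_f.any():
        raise ValueError("a window contains no samples")
    return float(np.mean(traj.potential[m_f]) - np.mean(traj.potential[m_i]))


@dataclass
class ForceExtensionCurve:
    """Tension versus CM separation, ordered by time.

    ``plateau_end`` is the index ending the initial plateau (the longest
    prefix whose local tension-per-Å slope stays below ``slope_fraction``
    of the terminal slope), or ``None`` when the window is too short or no
    rising branch exists.
    """

    separation: np.ndarray
    tension: np.ndarray
    plateau_end: int | None


def force_extension(
    times: np.ndarray,
    tension: np.ndarray,
    cm: np.ndarray,
    slope_fraction: float = 0.25,
) -> ForceExtensionCurve:
    """Pair tension with CM separation for the force–extension plot."""
    times = np.asarray(times, dtype=float)
    tension = np.asarray(tension, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if not (len(times) == len(tension) == len(cm)):
        raise ValueError("series lengths (timestamps) do not match")
    if len(times) < 3:
        return ForceExtensionCurve(separation=cm, tension=tension,
                                   plateau_end=None)
    ds = np.gradient(cm)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.gradient(tension) / np.where(np.abs(ds) < 1e-12, np.nan, ds)
    tail = slope[-max(3, len(slope) // 10):]
    tail = tail[np.isfinite(tail)]
    if len(tail) == 0:
        return ForceExtensionCurve(separation=cm, tension=tension,
                                   plateau_end=None)
    terminal = float(np.median(tail))
    if terminal <= 0:
        return ForceExtensionCurve(separation=cm, tension=tension,
                                   plateau_end=None)
    below = ~(slope > slope_fraction * terminal)   # NaN slopes count as flat
    end = int(np.argmin(below)) if not below.all() else len(below)
    return ForceExtensionCurve(separation=cm, tension=tension,
                               plateau_end=end if end > 0 else None)


def rupture_report(
    pair_logs: dict[int, "PairLog"],
    labels: tuple[str, ...],
    threshold: float = 8.2,
    smooth_window_fs: float = 50.0,
) -> pd.DataFrame:
    """Per-pair rupture summary from the steering controller's logs.

    One row per pair, in sequence order, with the label convention
    ``1TA``/``3GC``/...; ``bound_ok`` records whether F_max ≥ F_rup held
    and ``rupture_found`` whether the separation ever decreased inside the
    window.
    """
    rows = []
    for idx in sorted(pair_logs):
        log = pair_logs[idx]
        t, tension, cm = log.arrays()
        rup = detect_rupture(t, tension, cm, threshold, smooth_window_fs)
        fmax, t_max = detect_fmax(t, tension, cm, threshold)
        rows.append({
            "pair": idx + 1,
            "label": labels[idx],
            "F_rup_pN": rup.force,
            "t_rup_fs": rup.t,
            "F_max_pN": fmax,
            "t_max_fs": t_max,
            "t_activate_fs": log.t_activate,
            "t_deactivate_fs": log.t_deactivate,
            "rupture_found": rup.found,
            "bound_ok": fmax >= rup.force,
        })
    return pd.DataFrame(rows)
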