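"""Work of breathing from pressure-volume records.

The headline statistic is the area on the negative-pressure side of the
p-v loop: the work the breathing muscles perform against sub-ambient
circuit pressure while drawing breath in.  Operationally,

    W = ∫ (-p) dV   over samples with p < 0 and dV > 0  (trapezoidal),

converted to joules via 1 mbar·mL = 1e-4 J exactly.  Work done against
positive pressure during exhalation is computed separately
(:func:`work_positive_side`) and reported but excluded from the headline
number.  Work per cycle times the breathing rate gives work per minute.

Breath cycles are delimited by successive local minima of the
(smoothed) volume channel — the end-expiration convention — and partial
leading/trailing cycles are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PVRecord",
    "BreathCycle",
    "SegmentationError",
    "segment_breaths",
    "work_negative_side",
    "work_positive_side",
    "work_per_minute",
    "analyze_record",
    "MBAR_ML_TO_J",
]

MBAR_ML_TO_J = 1e-4


class SegmentationError(ValueError):
    """Raised when a record does not contain at least one complete cycle."""


@dataclass(frozen=True)
class PVRecord:
    """Sampled pressure and volume channels on a common time base."""

    t: np.ndarray  # s, strictly increasing
    p: np.ndarray  # mbar
    v: np.ndarray  # mL

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if not (len(t) == len(p) == len(v)):
            raise ValueError(
                f"channel lengths differ: t={len(t)}, p={len(p)}, v={len(v)}"
            )
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("time channel must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class BreathCycle:
    """One complete breath: sample index range [start, stop] inclusive."""

    start: int
    stop: int
    work_j: float  # inspiratory negative-side work
    work_positive_j: float  # expiratory positive-side work
    peak_negative_pressure_mbar: float  # magnitude of the deepest suction


def segment_breaths(rec: PVRecord, smooth_window: int | None = None) -> list[tuple[int, int]]:
    """Index ranges of complete cycles, minimum-to-minimum.

    The volume channel is moving-average smoothed (default window: 2% of
    the record, at least 3 samples, forced odd) before locating local
    minima; partial cycles before the first and after the last minimum
    are discarded.
    """
    v = rec.v
    if smooth_window is None:
        smooth_window = max(3, len(v) // 50)
    if smooth_window % 2 == 0:
        smooth_window += 1
    pad = smooth_window // 2
    kernel = np.ones(smooth_window) / smooth_window
    vs = np.convolve(np.pad(v, pad, mode="edge"), kernel, mode="valid")
    vrange = float(vs.max() - vs.min())
    if vrange <= 0.0:
        raise SegmentationError("volume channel is constant; no breath cycles")
    # minima of volume = peaks of -volume; prominence gate rejects ripple,
    # and find_peaks resolves flat minima (trapezoid holds) to one index
    minima, _ = find_peaks(-vs, prominence=0.25 * vrange)
    if minima.size < 2:
        raise SegmentationError(
            f"found {minima.size} volume minima; need at least 2 for one complete cycle"
        )
    return [(int(a), int(b)) for a, b in zip(minima[:-1], minima[1:])]


def work_negative_side_arrays(p: np.ndarray, v: np.ndarray) -> float:
    """Trapezoidal ∫(-p)dV over the inspiratory limb where p < 0, in J."""
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    dv = np.diff(v)
    pm = 0.5 * (p[:-1] + p[1:])
    mask = (dv > 0) & (pm < 0)
    return float(np.sum(-pm[mask] * dv[mask]) * MBAR_ML_TO_J)


def work_positive_side_arrays(p: np.ndarray, v: np.ndarray) -> float:
    """Trapezoidal ∫p(-dV) over the expiratory limb where p > 0, in J."""
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    dv = np.diff(v)
    pm = 0.5 * (p[:-1] + p[1:])
    mask = (dv < 0) & (pm > 0)
    return float(np.sum(pm[mask] * -dv[mask]) * MBAR_ML_TO_J)


def work_negative_side(rec: PVRecord, cycle: tuple[int, int]) -> float:
    """Negative-side loop area of one cycle, in joules (>= 0)."""
    a, b = cycle
    return work_negative_side_arrays(rec.p[a : b + 1], rec.v[a : b + 1])


def work_positive_side(rec: PVRecord, cycle: tuple[int, int]) -> float:
    a, b = cycle
    return work_positive_side_arrays(rec.p[a : b + 1], rec.v[a : b + 1])


def work_per_minute(work_per_cycle_j: float, rate_bpm: float) -> float:
    """Work per minute = work per cycle x breathing rate."""
    if work_per_cycle_j < 0 or rate_bpm < 0:
        raise ValueError(
            f"inputs must be >= 0, got work={work_per_cycle_j!r}, rate={rate_bpm!r}"
        )
    return work_per_cycle_j * rate_bpm


def analyze_record(rec: PVRecord) -> list[BreathCycle]:
    """Segment a record and compute per-cycle work and peak suction."""
    cycles = segment_breaths(rec)
    out = []
    for a, b in cycles:
        p_seg = rec.p[a : b + 1]
        out.append(
            BreathCycle(
                start=a,
                stop=b,
                work_j=work_negative_side(rec, (a, b)),
                work_positive_j=work_positive_side(rec, (a, b)),
                peak_negative_pressure_mbar=float(max(0.0, -p_seg.min())),
            )
        )
    return out
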