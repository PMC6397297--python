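"""Time-lapse metrics: centroid tracking, migration statistics and
F-actin turnover.

Migration directionality (MD) is the ratio of net displacement to total
path length of a centroid track,

    MD = d(P_0, P_T) / sum_i d(P_i, P_{i+1}),

so MD = 1 for a perfectly directed path and 0 for a closed loop.  F-actin
interframe change is the signed percent change between successive frames,
IFC_i = 100 * (FA_{i+1} - FA_i) / FA_i, and drug-induced disassembly is the
percent drop between t = 0 and t = t_end (default 30 min),
100 * (FA_0 - FA_30) / FA_0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import morphometrics


@dataclass
class Track:
    """Centroid positions (um) of one cell over time (minutes)."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) < 2:
            raise ValueError("a track needs at least 2 positions")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class FASeries:
    """Per-frame F-actin amount (counts) over time (minutes)."""

    times: np.ndarray
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if len(self.times) != len(self.fa):
            raise ValueError("times and fa length mismatch")
        if np.any(self.fa < 0):
            raise ValueError("FA values must be >= 0")


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


def _frame_centroid(frame: np.ndarray, weighted: bool) -> Optional[np.ndarray]:
    """Centroid (row, col) of the dominant cell in one frame, or None if
    the frame has no foreground."""
    if frame.max() <= 0 or np.ptp(frame) == 0:
        return None
    mask = frame > threshold_otsu(frame)
    if not mask.any():
        return None
    mask = ndimage.binary_fill_holes(mask)
    mask = morphometrics._largest_component(mask)
    if weighted:
        w = np.where(mask, frame, 0.0)
        total = w.sum()
        rr, cc = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
        return np.array([(w * rr).sum() / total, (w * cc).sum() / total])
    return np.asarray(ndimage.center_of_mass(mask))


def track_centroids(frames: Sequence[np.ndarray], pixel_size: float,
                    dt: float = 10.0, weighted: bool = True,
                    max_gap: int = 2) -> Track:
    """Track one cell's centroid through a time-ordered frame sequence.

    Each frame is segmented independently (threshold, hole-fill, largest
    component) and reduced to its intensity-weighted centroid (set
    ``weighted=False`` for the plain mask centroid).  Frames with no
    foreground are linearly interpolated from their neighbours, up to
    ``max_gap`` consecutive missing frames; longer gaps, or missing first
    or last frames, raise ``ValueError``.
    """
    cents: List[Optional[np.ndarray]] = [
        _frame_centroid(np.asarray(f, dtype=float), weighted) for f in frames]
    if len(cents) < 2:
        raise ValueError("need at least 2 frames")
    if cents[0] is None or cents[-1] is None:
        raise ValueError("first or last frame has no foreground")

    out = np.zeros((len(cents), 2))
    i = 0
    while i < len(cents):
        if cents[i] is not None:
            out[i] = cents[i]
            i += 1
            continue
        j = i
        while cents[j] is None:
            j += 1
        if j - i > max_gap:
            raise ValueError(
                f"{j - i} consecutive empty frames at index {i} "
                f"(max_gap={max_gap})")
        a, b = out[i - 1], cents[j]
        for k in range(i, j):
            f = (k - (i - 1)) / (j - (i - 1))
            out[k] = a + f * (b - a)
        i = j
    times = np.arange(len(cents)) * dt
    return Track(times=times, positions=out * pixel_size)


# ---------------------------------------------------------------------------
# Migration statistics
# ---------------------------------------------------------------------------


def total_distance(track: Track) -> float:
    """Total path length: sum of Euclidean step lengths (um)."""
    steps = np.diff(track.positions, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def directionality(track: Track) -> float:
    """Migration directionality: net displacement / total path length.

    Returns NaN (reported missing) for a track with zero total distance.
    """
    total = total_distance(track)
    if total == 0:
        return float("nan")
    net = float(np.hypot(*(track.positions[-1] - track.positions[0])))
    return net / total


# ---------------------------------------------------------------------------
# F-actin turnover
# ---------------------------------------------------------------------------


def interframe_change(fa: FASeries) -> np.ndarray:
    """Signed percent change of F-actin between successive frames."""
    values = fa.fa
    if np.any(values[:-1] <= 0):
        raise ValueError("FA must be positive on all but the last frame")
    return 100.0 * np.diff(values) / values[:-1]


def disassembly(fa: FASeries, t_end: float = 30.0) -> float:
    """Percent F-actin lost between t=0 and t=t_end (negative = assembly)."""
    times = fa.times
    i0 = np.flatnonzero(np.isclose(times, 0.0))
    i1 = np.flatnonzero(np.isclose(times, t_end))
    if i0.size == 0 or i1.size == 0:
        raise ValueError(f"series lacks frames at t=0 and t={t_end} min")
    fa0 = fa.fa[i0[0]]
    if fa0 <= 0:
        raise ValueError("FA at t=0 must be positive")
    return float(100.0 * (fa0 - fa.fa[i1[0]]) / fa0)
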