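"""Coordinate-based gait event detection, cycle selection, time normalization.

Heel strike and toe-off are defined kinematically: heel strike is the local
maximum of the fore-aft displacement of the heel relative to the sacrum
along the direction of travel; toe-off is the local minimum of the toe's
displacement from the sacrum.  Only relative displacement matters, so the
detection is invariant to any constant offset of the whole scene.

The analysed cycle runs from one right heel strike to the next; its curves
are linearly interpolated onto 101 points (0..100 % of the cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import GapError, NoCompleteCycleError, ValidationError

__all__ = [
    "GaitEvents",
    "detect_events",
    "select_central_cycle",
    "time_normalize",
    "parse_travel_axis",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: minimum peak separation as a fraction of the estimated cycle length
MIN_SEPARATION_FRACTION = 0.4
#: required peak prominence as a fraction of the displacement range
PROMINENCE_FRACTION = 0.10


def parse_travel_axis(travel_axis: str) -> tuple[int, float]:
    """Parse 'x' / '+x' / '-y' ... into (column index, sign)."""
    s = travel_axis.strip().lower()
    sign = 1.0
    if s and s[0] in "+-":
        sign = -1.0 if s[0] == "-" else 1.0
        s = s[1:]
    if s not in _AXES:
        raise ValidationError(f"unknown travel axis {travel_axis!r}")
    return _AXES[s], sign


@dataclass
class GaitEvents:
    """Detected gait events (0-based frame indices) for one side.

    Invariants: each list strictly increasing; between consecutive heel
    strikes exactly one toe-off (alternation).
    """

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    side: str = "right"
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        for name, arr in (("heel_strikes", self.heel_strikes), ("toe_offs", self.toe_offs)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        hs = self.heel_strikes
        for a, b in zip(hs[:-1], hs[1:]):
            inside = np.sum((self.toe_offs > a) & (self.toe_offs < b))
            if inside != 1:
                raise ValidationError(
                    f"alternation violated: {inside} toe-offs between heel strikes {a} and {b}"
                )

    @property
    def cycles(self) -> list[tuple[int, int]]:
        """Complete cycles as (start, end) heel-strike frame pairs."""
        hs = self.heel_strikes
        return list(zip(hs[:-1], hs[1:]))


def _relative_displacement(
    point: np.ndarray, sacrum: np.ndarray, travel_axis: str
) -> np.ndarray:
    point = np.asarray(point, dtype=float)
    sacrum = np.asarray(sacrum, dtype=float)
    if point.shape != sacrum.shape or point.ndim != 2 or point.shape[1] != 3:
        raise ValidationError("trajectories must share an (n, 3) shape")
    col, sign = parse_travel_axis(travel_axis)
    return sign * (point[:, col] - sacrum[:, col])


def _find_extrema(disp: np.ndarray, kind: str) -> np.ndarray:
    """Two-pass peak finding: estimate the cycle length from an
    unconstrained pass, then enforce a minimum separation of
    ``MIN_SEPARATION_FRACTION`` times the median cycle estimate."""
    signal = disp if kind == "max" else -disp
    gaps = ~np.isfinite(signal)
    work = signal.copy()
    if gaps.any():
        idx = np.arange(signal.size)
        work[gaps] = np.interp(idx[gaps], idx[~gaps], signal[~gaps])
    rng = np.nanmax(work) - np.nanmin(work)
    if rng <= 0:
        return np.array([], dtype=int)
    prominence = PROMINENCE_FRACTION * rng
    peaks, _ = find_peaks(work, prominence=prominence)
    if peaks.size >= 2:
        est = np.median(np.diff(peaks))
        distance = max(1, int(round(MIN_SEPARATION_FRACTION * est)))
        peaks, _ = find_peaks(work, prominence=prominence, distance=distance)
    if gaps.any():
        if peaks.size >= 2:
            half = max(1, int(round(np.median(np.diff(peaks)) / 4)))
        else:
            half = max(1, int(0.1 * signal.size))
        gap_idx = np.flatnonzero(gaps)
        for p in peaks:
            if np.any(np.abs(gap_idx - p) <= half):
                raise GapError(
                    f"missing samples overlap a candidate {kind} near frame {p}"
                )
    return peaks


def detect_events(
    heel: np.ndarray,
    toe: np.ndarray,
    sacrum: np.ndarray,
    travel_axis: str = "+x",
    frame_rate: float | None = None,
    side: str = "right",
) -> GaitEvents:
    """Detect heel strikes and toe-offs from marker trajectories.

    Heel strikes are local maxima of heel-sacrum displacement along the
    travel axis, toe-offs local minima of toe-sacrum displacement; peaks
    must clear a prominence of 10 % of the displacement range and a minimum
    separation of 0.4 median cycle estimates.  Toe-offs outside the first
    and last heel strike are dropped; within each cycle the deepest minimum
    is kept so the alternation invariant holds.
    """
    disp_heel = _relative_displacement(heel, sacrum, travel_axis)
    disp_toe = _relative_displacement(toe, sacrum, travel_axis)

    heel_strikes = _find_extrema(disp_heel, "max")
    if heel_strikes.size < 2:
        raise NoCompleteCycleError(
            f"no complete cycle: {heel_strikes.size} heel strike(s) detected"
        )
    toe_candidates = _find_extrema(disp_toe, "min")

    toe_offs = []
    for a, b in zip(heel_strikes[:-1], heel_strikes[1:]):
        inside = toe_candidates[(toe_candidates > a) & (toe_candidates < b)]
        if inside.size == 0:
            raise NoCompleteCycleError(
                f"no toe-off detected between heel strikes {a} and {b}"
            )
        toe_offs.append(inside[int(np.argmin(disp_toe[inside]))])

    return GaitEvents(
        heel_strikes=heel_strikes,
        toe_offs=np.asarray(toe_offs, dtype=int),
        side=side,
        frame_rate=frame_rate,
    )


def select_central_cycle(
    events: GaitEvents,
    sacrum: np.ndarray | None = None,
    travel_axis: str = "+x",
    volume_bounds: tuple[float, float] | None = None,
) -> tuple[int, int]:
    """Pick the most central complete cycle.

    With volume bounds (min, max position in mm along the travel axis), the
    cycle whose mid-cycle sacrum position lies nearest the volume centre is
    chosen; without bounds (or without a sacrum trajectory) the cycle whose
    midpoint frame is closest to the temporal midpoint of the recording is
    used.  Ties break toward the earlier cycle.
    """
    cycles = events.cycles
    if not cycles:
        raise NoCompleteCycleError("no complete cycle to select from")
    if len(cycles) == 1:
        return cycles[0]
    if volume_bounds is not None and sacrum is not None:
        col, _ = parse_travel_axis(travel_axis)
        centre = 0.5 * (volume_bounds[0] + volume_bounds[1])
        pos = np.asarray(sacrum, dtype=float)[:, col]
        dist = [abs(pos[(a + b) // 2] - centre) for a, b in cycles]
    else:
        mid = (len(np.asarray(sacrum)) - 1) / 2 if sacrum is not None else None
        if mid is None:
            mid = (cycles[0][0] + cycles[-1][1]) / 2
        dist = [abs((a + b) / 2 - mid) for a, b in cycles]
    return cycles[int(np.argmin(dist))]


def time_normalize(
    series: np.ndarray, start: int, end: int, n_points: int = 101
) -> np.ndarray:
    """Linearly resample ``series[start:end]`` onto ``n_points`` cycle
    fractions 0, 1, ..., 100 %; endpoints are preserved exactly.

    ``series`` may be 1-D (frames,) or 2-D (channels, frames).  Missing
    samples (NaN) inside the window are an error — gaps are never
    interpolated silently.
    """
    series = np.asarray(series, dtype=float)
    if not end > start:
        raise ValidationError(f"cycle end ({end}) must exceed start ({start})")
    window = series[..., start : end + 1]
    if window.shape[-1] != end - start + 1:
        raise ValidationError("cycle window extends past the series")
    if not np.all(np.isfinite(window)):
        raise GapError(f"missing samples inside cycle [{start}, {end}]")
    xp = np.arange(start, end + 1, dtype=float)
    x = np.linspace(start, end, n_points)
    if window.ndim == 1:
        return np.interp(x, xp, window)
    return np.stack([np.interp(x, xp, row) for row in window])
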