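"""In-memory containers for trials, normalized gait cycles and whole studies.

Units are millimetres for positions and degrees for angles throughout the
package.  Frame indexing is 0-based; file formats that count frames from 1
are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .constants import CHANNELS, N_CYCLE_POINTS, channel_index
from .errors import ValidationError

#: (subject_id, session, condition, trial_index)
TrialKey = tuple[str, int, str, int]

_ORTHO_TOL = 1e-6


def check_rotations(poses: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    """Validate that the 3x3 blocks of an (n, 4, 4) or (n, 3, 3) pose array
    are proper rotations (orthonormal, det +1) within ``tol``."""
    R = np.asarray(poses, dtype=float)
    if R.ndim != 3 or R.shape[1:] not in ((3, 3), (4, 4)):
        raise ValidationError(f"pose array must be (n,3,3) or (n,4,4), got {R.shape}")
    R = R[:, :3, :3]
    err = np.abs(R @ np.swapaxes(R, 1, 2) - np.eye(3)).max()
    if err > tol:
        raise ValidationError(f"rotations not orthonormal: max |R R^T - I| = {err:.3g}")
    det = np.linalg.det(R)
    if np.abs(det - 1.0).max() > max(tol, 1e-6):
        raise ValidationError("rotation determinant differs from +1")


@dataclass
class TrialRecording:
    """Raw per-trial input: point trajectories and/or segment pose sequences.

    Parameters
    ----------
    frame_rate : float
        Capture rate in Hz, > 0.
    points : mapping of name -> (n, 3) float array
        Point trajectories in millimetres.  NaN marks missing samples.
    poses : mapping of segment -> (n, 4, 4) float array
        Homogeneous rigid-body poses (rotation in the upper 3x3, translation
        in mm in the last column).
    angles : mapping of (joint, plane) -> (n,) float array
        Precomputed joint-angle series in degrees (already filtered
        upstream); present when the source exported angles rather than
        poses.
    meta : dict
        Free-form metadata; the study loaders put ``subject``, ``session``,
        ``condition`` and ``trial`` here, the walking simulator adds its
        ground-truth event frames.
    """

    frame_rate: float
    points: dict[str, np.ndarray] = field(default_factory=dict)
    poses: dict[str, np.ndarray] = field(default_factory=dict)
    angles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.poses = {k: np.asarray(v, dtype=float) for k, v in self.poses.items()}
        self.angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        lengths = set()
        for name, arr in self.points.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"point series {name!r} must be (n, 3)")
            lengths.add(arr.shape[0])
        for name, arr in self.poses.items():
            check_rotations(arr)
            lengths.add(arr.shape[0])
        for key, arr in self.angles.items():
            if arr.ndim != 1:
                raise ValidationError(f"angle series {key} must be 1-D")
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise ValidationError(f"series lengths differ: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        for d in (self.points, self.poses, self.angles):
            for arr in d.values():
                return arr.shape[0]
        return 0

    def angle_matrix(self) -> np.ndarray:
        """Stack the angle series into a (12, n) matrix in channel order.

        Channels without a stored series are NaN rows.
        """
        n = self.n_frames
        out = np.full((len(CHANNELS), n), np.nan)
        for (joint, plane), series in self.angles.items():
            out[channel_index(joint, plane)] = series
        return out


@dataclass
class GaitCycleCurves:
    """One trial's time-normalized angle curves: 12 channels x 101 points."""

    values: np.ndarray
    cycle: tuple[int, int] | None = None  # source (start, end) heel-strike frames
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(CHANNELS), N_CYCLE_POINTS):
            raise ValidationError(
                f"curves must be ({len(CHANNELS)}, {N_CYCLE_POINTS}), got {self.values.shape}"
            )
        if self.cycle is not None and not self.cycle[1] > self.cycle[0]:
            raise ValidationError("cycle end must exceed cycle start")

    def get(self, joint: str, plane: str) -> np.ndarray:
        return self.values[channel_index(joint, plane)]


class StudyDataset:
    """The full study hierarchy subject -> session -> condition -> trials.

    Holds normalized :class:`GaitCycleCurves` per trial plus optional
    per-trial segment lengths (mm) and, for raw studies, the unprocessed
    :class:`TrialRecording` objects awaiting event detection.
    """

    def __init__(self) -> None:
        self.trials: dict[TrialKey, GaitCycleCurves] = {}
        self.raw: dict[TrialKey, TrialRecording] = {}
        #: (subject, session, condition, trial, segment) -> length in mm
        self.segment_lengths: dict[tuple[str, int, str, int, str], float] = {}
        self.metadata: dict = {}

    # -- construction -----------------------------------------------------
    def add_trial(self, key: TrialKey, curves: GaitCycleCurves) -> None:
        if key in self.trials:
            raise ValidationError(f"duplicate trial {key}")
        self.trials[key] = curves

    def add_raw(self, key: TrialKey, recording: TrialRecording) -> None:
        if key in self.raw:
            raise ValidationError(f"duplicate raw trial {key}")
        self.raw[key] = recording

    # -- views ------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.trials} | {k[0] for k in self.raw})

    def sessions(self) -> list[int]:
        return sorted({k[1] for k in self.trials} | {k[1] for k in self.raw})

    def conditions(self) -> list[str]:
        return sorted({k[2] for k in self.trials} | {k[2] for k in self.raw})

    def select(
        self,
        subject: str | None = None,
        sessions: Iterable[int] | None = None,
        conditions: Iterable[str] | None = None,
    ) -> list[TrialKey]:
        """Sorted trial keys matching the given coordinates (None = all)."""
        ses = set(sessions) if sessions is not None else None
        con = set(conditions) if conditions is not None else None
        keys = [
            k
            for k in self.trials
            if (subject is None or k[0] == subject)
            and (ses is None or k[1] in ses)
            and (con is None or k[2] in con)
        ]
        return sorted(keys)

    def stack(self, keys: Iterable[TrialKey]) -> np.ndarray:
        """Stack trials into an (n_trials, 12, 101) array."""
        keys = list(keys)
        if not keys:
            return np.empty((0, len(CHANNELS), N_CYCLE_POINTS))
        return np.stack([self.trials[k].values for k in keys])

    def completeness_report(
        self, design: Mapping[str, int] | None = None
    ) -> list[tuple]:
        """List missing (subject, session, condition, trial-count) cells.

        With a design mapping (``n_sessions``, ``n_conditions`` via observed
        labels, ``n_trials``) the expected grid is the Cartesian product of
        observed subjects with the designed sessions/conditions/trial count;
        without one, the observed label sets define the grid.
        """
        subjects = self.subjects()
        sessions = self.sessions()
        conditions = self.conditions()
        n_trials = max((k[3] for k in self.trials), default=-1) + 1
        if design is not None:
            sessions = list(range(1, int(design.get("n_sessions", len(sessions))) + 1))
            n_trials = int(design.get("n_trials", n_trials))
        missing = []
        for s in subjects:
            for ses in sessions:
                for c in conditions:
                    have = len(self.select(subject=s, sessions=[ses], conditions=[c]))
                    if have < n_trials:
                        missing.append((s, ses, c, have, n_trials))
        return missing
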