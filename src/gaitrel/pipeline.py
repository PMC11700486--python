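"""Raw-trial processing: events -> central cycle -> angles -> 101 points.

Turns raw recordings (marker trajectories and/or segment pose sequences)
into normalized gait-cycle curves, in place, on a study dataset.  Angle
channels the recording cannot supply are left NaN.
"""

from __future__ import annotations

import logging

import numpy as np

from .angles import joint_angles, pelvis_angles, segment_length
from .constants import CHANNELS, N_CYCLE_POINTS, channel_index
from .datasets import GaitCycleCurves, StudyDataset, TrialRecording
from .errors import GaitrelError
from .events import detect_events, select_central_cycle, time_normalize

log = logging.getLogger(__name__)

__all__ = ["trial_to_cycle_curves", "process_raw_trials", "DEFAULT_MARKERS"]

#: marker labels used for event detection (override via study metadata
#: ``marker_map``: {"heel": ..., "toe": ..., "sacrum": ...})
DEFAULT_MARKERS = {"heel": "r_heel", "toe": "r_toe", "sacrum": "sacrum"}

#: segment chain for Cardan angle extraction from pose sequences:
#: channel joint -> (proximal segment or None for lab, distal segment)
POSE_CHAIN = {
    "pelvis": (None, "pelvis"),
    "hip": ("pelvis", "thigh_R"),
    "knee": ("thigh_R", "shank_R"),
    "ankle": ("shank_R", "foot_R"),
}

#: endpoint markers defining segment lengths, when present
SEGMENT_ENDPOINTS = {
    "thigh_R": ("hip_R", "knee_R"),
    "shank_R": ("knee_R", "ankle_R"),
}


def _angle_series(rec: TrialRecording, order: str) -> np.ndarray:
    """(12, n) angle time series in degrees, NaN for unavailable channels."""
    n = rec.n_frames
    out = np.full((len(CHANNELS), n), np.nan)
    for (joint, plane), series in rec.angles.items():
        out[channel_index(joint, plane)] = series
    for joint, (prox, dist) in POSE_CHAIN.items():
        if dist not in rec.poses:
            continue
        if prox is None:
            ang, _ = pelvis_angles(rec.poses[dist], order=order)
        elif prox in rec.poses:
            ang, _ = joint_angles(rec.poses[prox], rec.poses[dist], order=order)
        else:
            continue
        for k, plane in enumerate(("sagittal", "frontal", "transverse")):
            idx = channel_index(joint, plane)
            if np.isnan(out[idx]).all():
                out[idx] = ang[:, k]
    return out


def trial_to_cycle_curves(
    rec: TrialRecording,
    travel_axis: str = "+x",
    volume_bounds: tuple[float, float] | None = None,
    order: str = "XYZ",
    markers: dict[str, str] | None = None,
) -> GaitCycleCurves:
    """Process one raw trial into normalized 101-point curves."""
    markers = {**DEFAULT_MARKERS, **(markers or {}), **(
        rec.meta.get("marker_map") or {}
    )}
    travel_axis = rec.meta.get("travel_axis", travel_axis)
    series = _angle_series(rec, order)
    if series.shape[1] == N_CYCLE_POINTS and not rec.points:
        return GaitCycleCurves(values=series)  # already normalized upstream
    missing = [m for m in markers.values() if m not in rec.points]
    if missing:
        raise GaitrelError(
            f"cannot detect events: markers {missing} absent from trial"
        )
    heel = rec.points[markers["heel"]]
    toe = rec.points[markers["toe"]]
    sacrum = rec.points[markers["sacrum"]]
    events = detect_events(
        heel, toe, sacrum, travel_axis=travel_axis, frame_rate=rec.frame_rate
    )
    start, end = select_central_cycle(
        events, sacrum, travel_axis=travel_axis, volume_bounds=volume_bounds
    )
    # channels absent from the source stay NaN; only real data is checked
    # for gaps and resampled
    values = np.full((len(CHANNELS), N_CYCLE_POINTS), np.nan)
    valid = ~np.isnan(series).all(axis=1)
    if valid.any():
        values[valid] = time_normalize(series[valid], start, end)
    return GaitCycleCurves(
        values=values,
        cycle=(int(start), int(end)),
        duration_s=(end - start) / rec.frame_rate,
    )


def process_raw_trials(
    dataset: StudyDataset,
    travel_axis: str | None = None,
    volume_bounds: tuple[float, float] | None = None,
    order: str = "XYZ",
) -> None:
    """Convert every raw trial of a dataset into cycle curves, in place.

    Defaults for the travel axis and volume bounds come from the study
    metadata written by the manifest loader.  Segment lengths are computed
    from endpoint markers when present.
    """
    study = dataset.metadata.get("study") or {}
    travel_axis = travel_axis or study.get("travel_axis", "+x")
    if volume_bounds is None and study.get("volume_bounds") is not None:
        volume_bounds = tuple(study["volume_bounds"])
    markers = study.get("marker_map") or None
    for key in sorted(dataset.raw):
        rec = dataset.raw.pop(key)
        try:
            curves = trial_to_cycle_curves(
                rec, travel_axis=travel_axis, volume_bounds=volume_bounds,
                order=order, markers=markers,
            )
        except GaitrelError as exc:
            raise GaitrelError(f"trial {key}: {exc}") from exc
        dataset.add_trial(key, curves)
        for seg, (prox, dist) in SEGMENT_ENDPOINTS.items():
            if prox in rec.points and dist in rec.points:
                dataset.segment_lengths[(*key, seg)] = segment_length(
                    rec.points[prox], rec.points[dist]
                )
        log.debug("processed raw trial %s: cycle %s", key, curves.cycle)
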