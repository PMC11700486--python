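"""Joint angles from segment poses; segment lengths and inter-session drift.

Joint angles are Cardan decompositions of the relative rotation between a
proximal and a distal segment, computed per frame as ``R_rel = R_prox^T
R_dist`` and decomposed with an intrinsic rotation sequence (default X-Y-Z,
i.e. sagittal, frontal, transverse).  Pelvis angles are computed the same
way against the lab frame (identity proximal pose).  The sequence is
configurable because upstream pose-estimation pipelines differ; the default
is the common clinical convention with flexion/anterior tilt positive about
the laterally-directed X axis.

Segment lengths are the per-frame Euclidean distance between the proximal
and distal end positions; in pose-estimation output this is constant within
a trial, so a single value per trial is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .datasets import StudyDataset, check_rotations
from .errors import ValidationError

__all__ = [
    "cardan_angles",
    "joint_angles",
    "pelvis_angles",
    "segment_length",
    "segment_length_report",
    "SegmentLengthReport",
]

#: middle-angle magnitude (deg) beyond which decomposition is flagged
GIMBAL_LIMIT_DEG = 89.9

_VALID_ORDERS = {"XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX"}


def _rotations(poses: np.ndarray) -> np.ndarray:
    """Extract (n, 3, 3) rotation blocks from (n, 3, 3) or (n, 4, 4) poses."""
    arr = np.asarray(poses, dtype=float)
    check_rotations(arr)
    return arr[:, :3, :3]


def cardan_angles(
    relative: np.ndarray, order: str = "XYZ", unwrap: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose (n, 3, 3) relative rotations into Cardan angles (degrees).

    Returns ``(angles, gimbal)`` where ``angles`` is (n, 3) in the order of
    the sequence and ``gimbal`` is a boolean mask flagging frames whose
    middle angle exceeds ``GIMBAL_LIMIT_DEG`` in magnitude (the first and
    third angles are poorly conditioned there).  Angle series are unwrapped
    so continuous motion does not jump by 360 deg.
    """
    if order.upper() not in _VALID_ORDERS:
        raise ValidationError(f"unknown Cardan order {order!r}")
    order = order.upper()  # intrinsic, body-fixed
    rel = np.asarray(relative, dtype=float)
    ang = Rotation.from_matrix(rel).as_euler(order, degrees=True)
    ang = np.atleast_2d(ang)
    gimbal = np.abs(ang[:, 1]) > GIMBAL_LIMIT_DEG
    if gimbal.any():
        warnings.warn(
            f"{int(gimbal.sum())} frame(s) near gimbal lock "
            f"(|middle angle| > {GIMBAL_LIMIT_DEG} deg)",
            RuntimeWarning,
            stacklevel=2,
        )
    if unwrap and ang.shape[0] > 1:
        ang = np.unwrap(ang, axis=0, period=360.0)
    return ang, gimbal


def joint_angles(
    proximal: np.ndarray,
    distal: np.ndarray,
    order: str = "XYZ",
) -> tuple[np.ndarray, np.ndarray]:
    """Angles of the distal segment relative to the proximal one.

    Both inputs are (n, 3, 3) or (n, 4, 4) pose sequences of equal length
    with orthonormal rotation blocks.  Returns ``(angles_deg, gimbal_mask)``
    with angles shaped (n, 3) in sequence order (X-Y-Z default: sagittal,
    frontal, transverse).
    """
    Rp = _rotations(proximal)
    Rd = _rotations(distal)
    if Rp.shape[0] != Rd.shape[0]:
        raise ValidationError("proximal and distal sequences differ in length")
    rel = np.swapaxes(Rp, 1, 2) @ Rd
    return cardan_angles(rel, order=order)


def pelvis_angles(pelvis: np.ndarray, order: str = "XYZ") -> tuple[np.ndarray, np.ndarray]:
    """Pelvis orientation relative to the lab axes (identity proximal)."""
    Rd = _rotations(pelvis)
    return cardan_angles(Rd, order=order)


def segment_length(
    proximal_end: np.ndarray,
    distal_end: np.ndarray,
    constant_tol_mm: float = 1e-6,
) -> float:
    """Length of a segment (mm) from its endpoint trajectories.

    Returns the single value when the per-frame distance is constant to
    ``constant_tol_mm``; otherwise the trial mean, with a warning about the
    variability.  A zero-length segment is an error.
    """
    p = np.atleast_2d(np.asarray(proximal_end, dtype=float))
    d = np.atleast_2d(np.asarray(distal_end, dtype=float))
    if p.shape != d.shape or p.shape[-1] != 3 or p.shape[0] == 0:
        raise ValidationError("endpoint series must be non-empty (n, 3) of equal shape")
    dist = np.linalg.norm(d - p, axis=-1)
    if np.min(dist) <= constant_tol_mm:
        raise ValidationError("zero-length segment")
    spread = float(np.max(dist) - np.min(dist))
    if spread > constant_tol_mm:
        warnings.warn(
            f"segment length varies by {spread:.3g} mm within the trial; using the mean",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.mean(dist))


@dataclass
class SegmentLengthReport:
    """Inter-session segment-length drift.

    ``per_subject``: one row per (subject, condition, segment) with the two
    session means (mm), their absolute difference (mm) and the difference
    as a percentage of the session-1 mean.  ``cohort``: mean and SD across
    subjects per (condition, segment); the SD is across subjects.
    """

    per_subject: pd.DataFrame
    cohort: pd.DataFrame


def segment_length_report(
    dataset: StudyDataset,
    sessions: tuple[int, int] = (1, 2),
) -> SegmentLengthReport:
    """Per-subject and cohort inter-session segment-length differences.

    Lengths are averaged over the trials of each session (per condition);
    the inter-session difference is reported as an absolute value in mm and
    as a percentage of the session-1 mean.  A missing session leaves NaN
    cells rather than imputing.
    """
    if not dataset.segment_lengths:
        raise ValidationError("dataset carries no segment lengths")
    rows = []
    df = pd.DataFrame(
        [
            {"subject": s, "session": ses, "condition": c, "trial": t,
             "segment": seg, "length_mm": v}
            for (s, ses, c, t, seg), v in dataset.segment_lengths.items()
        ]
    )
    grouped = df.groupby(["subject", "condition", "segment", "session"])["length_mm"].mean()
    for (subj, cond, seg), sub in grouped.groupby(level=[0, 1, 2]):
        means = sub.droplevel([0, 1, 2])
        m1 = means.get(sessions[0], np.nan)
        m2 = means.get(sessions[1], np.nan)
        diff = abs(m2 - m1) if np.isfinite(m1) and np.isfinite(m2) else np.nan
        pct = 100.0 * diff / m1 if np.isfinite(diff) and m1 > 0 else np.nan
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "segment": seg,
                "session1_mm": m1,
                "session2_mm": m2,
                "diff_mm": diff,
                "diff_pct": pct,
            }
        )
    per_subject = pd.DataFrame(rows)
    cohort = (
        per_subject.groupby(["condition", "segment"])[["session1_mm", "diff_mm", "diff_pct"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    cohort.columns = ["_".join(c).rstrip("_") for c in cohort.columns]
    return SegmentLengthReport(per_subject=per_subject, cohort=cohort)
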