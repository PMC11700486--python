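"""Plain-text trial dialect: UTF-8 CSV with a mandatory header row.

Three column vocabularies, mixable in one file:

* point trajectories: ``frame, <name>_x, <name>_y, <name>_z`` (mm);
* joint angles: ``<joint>_<plane>`` (degrees), e.g. ``knee_sagittal`` — a
  101-row angle file is a ready-made normalized gait cycle;
* pose sequences: ``<segment>_pose_r00 .. <segment>_pose_r22`` (row-major
  rotation) and ``<segment>_pose_tx/ty/tz`` (mm).

Lines starting with ``#`` are comments; ``# key: value`` comments carry
metadata (``frame_rate_hz``, ``subject``, ``session``, ``condition``,
``trial``).  The ``frame`` column is 1-based on disk and converted to the
package's 0-based indexing; it is required whenever point or pose columns
are present.  Empty cells read as NaN (missing samples).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from ..constants import JOINTS, PLANES
from ..datasets import GaitCycleCurves, TrialRecording
from ..errors import FormatError

__all__ = ["load_tabular", "write_tabular"]

_META_KEYS = {"frame_rate_hz", "subject", "session", "condition", "trial"}
_FLOAT_FMT = "%.10g"


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        key = key.strip()
        if key in _META_KEYS:
            value = value.strip()
            if key == "frame_rate_hz":
                meta[key] = float(value)
            elif key in ("session", "trial"):
                meta[key] = int(value)
            else:
                meta[key] = value
        else:
            meta.setdefault("comments", []).append(body)
    return meta


def _classify_columns(header: list[str]) -> dict:
    """Map each column to its destination (point axis, pose element or
    angle channel)."""
    plan: dict = {"frame": None, "points": {}, "poses": {}, "angles": {}}
    for idx, raw in enumerate(header):
        col = raw.strip()
        if col == "frame":
            plan["frame"] = idx
        elif "_pose_" in col:
            seg, _, element = col.partition("_pose_")
            plan["poses"].setdefault(seg, {})[element] = idx
        elif col.endswith(("_x", "_y", "_z")):
            name, axis = col[:-2], col[-1]
            plan["points"].setdefault(name, {})[axis] = idx
        elif col.split("_", 1)[0] in JOINTS:
            joint, _, plane = col.partition("_")
            if plane not in PLANES:
                raise FormatError(f"unknown plane token {plane!r} in column {col!r}")
            plan["angles"][(joint, plane)] = idx
        else:
            raise FormatError(f"unrecognised column {col!r}")
    if (plan["points"] or plan["poses"]) and plan["frame"] is None:
        raise FormatError("point/pose files require a 'frame' column")
    return plan


_POSE_ELEMENTS = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]


def load_tabular(path: str | Path, frame_rate: float | None = None) -> TrialRecording:
    """Read a trial from the tabular dialect.

    ``frame_rate`` overrides (or supplies, when absent from the file's
    metadata comments) the capture rate; normalized 101-point angle files
    default to a nominal rate of 101 samples per cycle second.
    """
    path = Path(path)
    comment_lines: list[str] = []
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, record in enumerate(csv.reader(fh), start=1):
            if not record or (record[0].lstrip().startswith("#")):
                if record:
                    comment_lines.append(",".join(record))
                continue
            if header is None:
                header = [c.strip() for c in record]
                n_cols = len(header)
                continue
            if len(record) != n_cols:
                raise FormatError(
                    f"{path.name}: line {lineno}: expected {n_cols} fields, got {len(record)}"
                )
            rows.append(record)
    if header is None:
        raise FormatError(f"{path.name}: missing header row")
    if not rows:
        raise FormatError(f"{path.name}: no data rows")

    meta = _parse_meta(comment_lines)
    plan = _classify_columns(header)
    try:
        data = np.array(
            [[float(v) if v.strip() else np.nan for v in row] for row in rows]
        )
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric value ({exc})") from exc

    n = data.shape[0]
    points = {}
    for name, axes in plan["points"].items():
        if set(axes) != {"x", "y", "z"}:
            raise FormatError(f"{path.name}: point {name!r} missing axis columns")
        points[name] = np.column_stack([data[:, axes[a]] for a in "xyz"])
    poses = {}
    for seg, elements in plan["poses"].items():
        if set(elements) != set(_POSE_ELEMENTS):
            raise FormatError(f"{path.name}: pose {seg!r} missing elements")
        mats = np.tile(np.eye(4), (n, 1, 1))
        for i in range(3):
            for j in range(3):
                mats[:, i, j] = data[:, elements[f"r{i}{j}"]]
        for axis, name in enumerate(("tx", "ty", "tz")):
            mats[:, axis, 3] = data[:, elements[name]]
        poses[seg] = mats
    angles = {key: data[:, idx] for key, idx in plan["angles"].items()}

    rate = frame_rate or meta.get("frame_rate_hz")
    if rate is None:
        rate = 101.0  # nominal for normalized-cycle angle files
    return TrialRecording(
        frame_rate=float(rate), points=points, poses=poses, angles=angles, meta=meta
    )


def write_tabular(
    trial: TrialRecording | GaitCycleCurves, path: str | Path
) -> Path:
    """Write a trial (or a normalized cycle) in the tabular dialect.

    Loss-free to the stated precision (round-trips with
    :func:`load_tabular`).
    """
    path = Path(path)
    if isinstance(trial, GaitCycleCurves):
        from ..constants import CHANNELS

        angles = {ch: trial.values[i] for i, ch in enumerate(CHANNELS)}
        trial = TrialRecording(frame_rate=101.0, angles=angles)

    n = trial.n_frames
    header: list[str] = []
    columns: list[np.ndarray] = []
    need_frame = bool(trial.points or trial.poses)
    if need_frame:
        header.append("frame")
        columns.append(np.arange(1, n + 1, dtype=float))  # 1-based on disk
    for name in sorted(trial.points):
        for axis in "xyz":
            header.append(f"{name}_{axis}")
        columns.extend(trial.points[name].T)
    for seg in sorted(trial.poses):
        mats = trial.poses[seg]
        for i in range(3):
            for j in range(3):
                header.append(f"{seg}_pose_r{i}{j}")
                columns.append(mats[:, i, j])
        for axis, tag in enumerate(("tx", "ty", "tz")):
            header.append(f"{seg}_pose_{tag}")
            columns.append(mats[:, axis, 3])
    for (joint, plane) in sorted(trial.angles):
        header.append(f"{joint}_{plane}")
        columns.append(trial.angles[(joint, plane)])

    with open(path, "w", newline="", encoding="utf-8") as fh:
        if trial.frame_rate and not (trial.angles and not need_frame):
            fh.write(f"# frame_rate_hz: {trial.frame_rate:.10g}\n")
        for key in ("subject", "session", "condition", "trial"):
            if key in trial.meta:
                fh.write(f"# {key}: {trial.meta[key]}\n")
        fh.write(",".join(header) + "\n")
        block = np.column_stack(columns)
        for row_idx in range(n):
            fields = []
            for col_idx, value in enumerate(block[row_idx]):
                if need_frame and col_idx == 0:
                    fields.append(str(int(value)))
                elif np.isnan(value):
                    fields.append("")
                else:
                    fields.append(_FLOAT_FMT % value)
            fh.write(",".join(fields) + "\n")
    return path
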