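"""Study manifests: a YAML index tying trial files to the study design.

Layout::

    study:
      name: demo
      frame_rate_hz: 180
      travel_axis: "+x"
      volume_bounds: [0, 6000]     # mm, optional
    design:
      n_subjects: 22
      n_sessions: 2
      n_conditions: 2
      n_trials: 5
    segment_lengths: segment_lengths.csv   # optional
    entries:
      - {subject: S01, session: 1, condition: tight, trial: 0,
         file: trials/S01_s1_tight_t0.csv}

(subject, session, condition, trial) tuples must be unique.  Trial indices
are 0-based; sessions are 1-based labels.  Referenced files are loaded by
extension (``.c3d`` binary, anything else via the tabular dialect).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import yaml

from ..constants import CHANNELS, N_CYCLE_POINTS
from ..datasets import GaitCycleCurves, StudyDataset, TrialKey
from ..errors import ManifestError
from .c3d import load_c3d, write_c3d
from .tabular import load_tabular, write_tabular

__all__ = ["load_study", "write_study"]

_LENGTH_COLUMNS = ["subject", "session", "condition", "trial", "segment", "length_mm"]


def _read_lengths(path: Path) -> dict:
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (
                row["subject"],
                int(row["session"]),
                row["condition"],
                int(row["trial"]),
                row["segment"],
            )
            out[key] = float(row["length_mm"])
    return out


def load_study(manifest_path: str | Path, strict: bool = True) -> StudyDataset:
    """Assemble a :class:`StudyDataset` from a manifest.

    Trials whose file provides all 12 angle channels at 101 points become
    normalized :class:`GaitCycleCurves` immediately; anything else is kept
    as a raw recording for the event/angle pipeline.  With ``strict=True``
    (default) a session or condition label outside the declared design, or
    a missing file, raises; with ``strict=False`` missing files are skipped
    and surface in the completeness report.
    """
    manifest_path = Path(manifest_path)
    try:
        doc = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ManifestError(f"cannot parse manifest: {exc}") from exc
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ManifestError("manifest must be a mapping with an 'entries' list")
    entries = doc.get("entries") or []
    if not entries:
        raise ManifestError("manifest has no entries")
    study = doc.get("study") or {}
    design = doc.get("design") or {}
    root = manifest_path.parent

    ds = StudyDataset()
    ds.metadata = {"study": study, "design": design}
    n_sessions = int(design.get("n_sessions", 0)) or None
    n_trials = int(design.get("n_trials", 0)) or None
    seen: set[TrialKey] = set()
    for i, entry in enumerate(entries):
        try:
            key: TrialKey = (
                str(entry["subject"]),
                int(entry["session"]),
                str(entry["condition"]),
                int(entry["trial"]),
            )
            rel = entry["file"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ManifestError(f"entry {i}: invalid ({exc})") from exc
        if key in seen:
            raise ManifestError(f"duplicate trial tuple {key}")
        seen.add(key)
        if strict and n_sessions is not None and not 1 <= key[1] <= n_sessions:
            raise ManifestError(
                f"entry {i}: session {key[1]} outside design (1..{n_sessions})"
            )
        if strict and n_trials is not None and not 0 <= key[3] < n_trials:
            raise ManifestError(
                f"entry {i}: trial index {key[3]} outside design (0..{n_trials - 1})"
            )
        fpath = root / rel
        if not fpath.exists():
            if strict:
                raise ManifestError(f"entry {i}: file not found: {fpath}")
            warnings.warn(f"missing trial file skipped: {fpath}", UserWarning, stacklevel=2)
            continue
        if fpath.suffix.lower() == ".c3d":
            rec = load_c3d(fpath)
        else:
            rec = load_tabular(fpath, frame_rate=study.get("frame_rate_hz"))
        rec.meta.update(
            subject=key[0], session=key[1], condition=key[2], trial=key[3]
        )
        matrix = rec.angle_matrix()
        if rec.angles and matrix.shape[1] == N_CYCLE_POINTS and not rec.points and not rec.poses:
            ds.add_trial(key, GaitCycleCurves(values=matrix))
        else:
            ds.add_raw(key, rec)

    lengths_rel = doc.get("segment_lengths")
    if lengths_rel:
        lpath = root / lengths_rel
        if lpath.exists():
            ds.segment_lengths.update(_read_lengths(lpath))
        elif strict:
            raise ManifestError(f"segment length file not found: {lpath}")
    return ds


def write_study(
    dataset: StudyDataset,
    outdir: str | Path,
    name: str = "study",
    fmt: str = "csv",
    frame_rate_hz: float = 180.0,
    travel_axis: str = "+x",
    volume_bounds: tuple[float, float] | None = None,
) -> Path:
    """Write a dataset as trial files plus a manifest; returns the manifest
    path.  ``fmt`` is 'csv' (tabular dialect) or 'c3d' (raw recordings
    only; normalized curves always go to CSV)."""
    if fmt not in ("csv", "c3d"):
        raise ManifestError(f"unknown format {fmt!r}")
    outdir = Path(outdir)
    trials_dir = outdir / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    items = [(k, ("curves", v)) for k, v in dataset.trials.items()]
    items += [(k, ("raw", v)) for k, v in dataset.raw.items()]
    for key, (kind, obj) in sorted(items, key=lambda kv: kv[0]):
        subj, session, condition, trial = key
        stem = f"{subj}_s{session}_{condition}_t{trial}"
        # C3D carries points/poses only; trials with angle series fall back
        # to the tabular dialect so nothing is lost
        if kind == "raw" and fmt == "c3d" and not obj.angles:
            fname = f"{stem}.c3d"
            write_c3d(obj, trials_dir / fname)
        else:
            fname = f"{stem}.csv"
            write_tabular(obj, trials_dir / fname)
        entries.append(
            {
                "subject": subj,
                "session": session,
                "condition": condition,
                "trial": trial,
                "file": f"trials/{fname}",
            }
        )

    doc: dict = {
        "study": {
            "name": name,
            "frame_rate_hz": frame_rate_hz,
            "travel_axis": travel_axis,
        },
        "design": dataset.metadata.get("design")
        or {
            "n_subjects": len(dataset.subjects()),
            "n_sessions": len(dataset.sessions()),
            "n_conditions": len(dataset.conditions()),
            "n_trials": max((k[3] for k in dataset.trials), default=-1) + 1,
        },
        "entries": entries,
    }
    if volume_bounds is not None:
        doc["study"]["volume_bounds"] = list(volume_bounds)

    if dataset.segment_lengths:
        lfile = outdir / "segment_lengths.csv"
        with open(lfile, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_LENGTH_COLUMNS)
            for (subj, ses, cond, trial, seg), val in sorted(
                dataset.segment_lengths.items()
            ):
                writer.writerow([subj, ses, cond, trial, seg, "%.17g" % val])
        doc["segment_lengths"] = "segment_lengths.csv"

    manifest = outdir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return manifest
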