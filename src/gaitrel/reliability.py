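"""Variance-component reliability analysis of gait waveforms.

Three nested levels of variation are computed per joint/plane channel as
pointwise standard-deviation curves over the 101 cycle points:

* **inter-trial** (intrinsic): SD across one subject's repeat trials from
  the first session, per clothing condition;
* **inter-session** (extrinsic): SD across the pooled trials of both
  sessions, per condition;
* **inter-session-clothing**: SD across all trials of both sessions and
  both conditions.

Per-subject SD curves use the sample SD (n-1 denominator) and are averaged
arithmetically across subjects to give cohort curves — the convention of
the gait-reliability literature ("average variation"); RMS pooling across
subjects is available as an option for sensitivity analysis.  No
small-sample bias correction is applied to reported outputs.

Scalar summaries per channel are the cycle average, minimum, maximum and
range of a variation curve.  The variability ratio is the cycle-averaged
pointwise quotient inter-session / inter-trial: values above 1 quantify how
much extrinsic variability a second session adds.  The clothing effect is
summarised by the RMSD between the two conditions' cohort-mean curves from
session 1.  Grand averages pool the 12 per-channel cycle averages.

The public surface follows the Model/Results pattern:
``ReliabilityModel(dataset).fit()`` returns a :class:`ReliabilityResults`
carrying all curves, tables and scalars, a text ``summary()`` and table
writers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .constants import CHANNELS, N_CYCLE_POINTS, channel_index
from .datasets import StudyDataset
from .errors import ValidationError

__all__ = [
    "pointwise_sd",
    "VariationCurve",
    "VariationCurveSet",
    "inter_trial_variation",
    "inter_session_variation",
    "inter_session_clothing_variation",
    "variability_ratio",
    "summary_metrics",
    "rmsd_conditions",
    "grand_average",
    "ReliabilityModel",
    "ReliabilityResults",
]

LEVELS = ("inter_trial", "inter_session", "inter_session_clothing")


def pointwise_sd(curves: np.ndarray) -> np.ndarray:
    """Sample SD (n-1 denominator) across the first axis, pointwise.

    ``curves`` is (n, ...) with n >= 2 stacked curves; the result drops the
    first axis.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.shape[0] < 2:
        raise ValidationError("pointwise SD needs at least 2 curves")
    return np.std(curves, axis=0, ddof=1)


@dataclass
class VariationCurve:
    """A 101-point SD curve at one level for one joint/plane channel."""

    level: str
    joint: str
    plane: str
    values: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        if self.level == "inter_session_clothing" and self.condition is not None:
            raise ValidationError("inter-session-clothing curves carry no condition tag")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CYCLE_POINTS,):
            raise ValidationError(f"variation curve must have {N_CYCLE_POINTS} points")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("variation values must be finite and non-negative")


@dataclass
class VariationCurveSet:
    """Cohort variation curves for all 12 channels at one level."""

    level: str
    values: np.ndarray  # (12, 101)
    condition: str | None = None
    n_subjects: int = 0
    excluded: list[str] = field(default_factory=list)

    def curve(self, joint: str, plane: str) -> VariationCurve:
        return VariationCurve(
            level=self.level,
            joint=joint,
            plane=plane,
            values=self.values[channel_index(joint, plane)],
            condition=self.condition,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.T, columns=[f"{j}_{p}" for j, p in CHANNELS]
        )
        df.insert(0, "cycle_pct", np.arange(N_CYCLE_POINTS))
        return df


def _per_subject_sd(
    dataset: StudyDataset,
    level: str,
    condition: str | None,
    sessions: tuple[int, ...],
    conditions: tuple[str, ...],
    min_trials: int = 2,
    pooling: str = "mean",
) -> VariationCurveSet:
    """Cohort aggregation of per-subject pointwise SD curves (arithmetic
    mean by default, quadratic/RMS pooling as an option)."""
    per_subject = []
    excluded = []
    for subj in dataset.subjects():
        keys = dataset.select(subject=subj, sessions=sessions, conditions=conditions)
        present_sessions = {k[1] for k in keys}
        present_conditions = {k[2] for k in keys}
        if (
            len(keys) < min_trials
            or present_sessions != set(sessions)
            or present_conditions != set(conditions)
        ):
            excluded.append(subj)
            continue
        per_subject.append(pointwise_sd(dataset.stack(keys)))
    if excluded:
        warnings.warn(
            f"{level}: excluded subjects without the required trials: {excluded}",
            UserWarning,
            stacklevel=3,
        )
    if not per_subject:
        raise ValidationError(f"{level}: no subject has the required trials")
    if pooling == "rms":
        values = np.sqrt(np.mean(np.square(per_subject), axis=0))
    else:
        values = np.mean(per_subject, axis=0)
    return VariationCurveSet(
        level=level,
        values=values,
        condition=condition,
        n_subjects=len(per_subject),
        excluded=excluded,
    )


def inter_trial_variation(
    dataset: StudyDataset, condition: str, session: int = 1, pooling: str = "mean"
) -> VariationCurveSet:
    """Intrinsic variation: SD over each subject's first-session trials of
    one clothing condition, averaged across subjects."""
    return _per_subject_sd(
        dataset, "inter_trial", condition, (session,), (condition,), pooling=pooling
    )


def inter_session_variation(
    dataset: StudyDataset,
    condition: str,
    sessions: tuple[int, int] = (1, 2),
    pooling: str = "mean",
) -> VariationCurveSet:
    """Extrinsic variation: SD over the pooled trials of both sessions
    (same condition), averaged across subjects.  Subjects missing a session
    are excluded with a warning."""
    return _per_subject_sd(
        dataset, "inter_session", condition, sessions, (condition,), pooling=pooling
    )


def inter_session_clothing_variation(
    dataset: StudyDataset,
    sessions: tuple[int, int] = (1, 2),
    conditions: tuple[str, ...] | None = None,
    pooling: str = "mean",
) -> VariationCurveSet:
    """SD over all trials of both sessions and both clothing conditions,
    averaged across subjects."""
    conditions = conditions or tuple(dataset.conditions())
    if len(conditions) < 2:
        raise ValidationError("inter-session-clothing variation needs >= 2 conditions")
    return _per_subject_sd(
        dataset, "inter_session_clothing", None, sessions, tuple(conditions),
        pooling=pooling,
    )


def variability_ratio(
    inter_trial: VariationCurveSet | np.ndarray,
    inter_session: VariationCurveSet | np.ndarray,
) -> np.ndarray:
    """Cycle-averaged pointwise ratio inter_session / inter_trial.

    Computed pointwise across the 101 cycle points and then averaged (not
    as a ratio of cycle averages — the two differ whenever the curves are
    not proportional).  Points where the inter-trial SD is zero are
    excluded; an all-zero inter-trial curve is an error.  Returns one
    scalar per channel, shape (12,) for curve sets or scalar for 1-D
    inputs.
    """
    it = inter_trial.values if isinstance(inter_trial, VariationCurveSet) else np.asarray(inter_trial, float)
    isv = inter_session.values if isinstance(inter_session, VariationCurveSet) else np.asarray(inter_session, float)
    if it.shape != isv.shape:
        raise ValidationError("variation curves must share a shape")
    it2 = np.atleast_2d(it)
    isv2 = np.atleast_2d(isv)
    out = np.empty(it2.shape[0])
    for i in range(it2.shape[0]):
        mask = it2[i] > 0
        if not mask.any():
            raise ValidationError("all-zero inter-trial curve: ratio undefined")
        out[i] = np.mean(isv2[i, mask] / it2[i, mask])
    return out if it.ndim > 1 else float(out[0])


class SummaryMetrics(NamedTuple):
    average: float | np.ndarray
    min: float | np.ndarray
    max: float | np.ndarray
    range: float | np.ndarray


def summary_metrics(curve: np.ndarray | VariationCurve) -> SummaryMetrics:
    """Cycle average, minimum, maximum and range of a variation curve.

    Accepts a single 101-point curve or an (..., 101) stack; metrics are
    taken over the last axis.
    """
    values = curve.values if isinstance(curve, VariationCurve) else np.asarray(curve, float)
    avg = np.mean(values, axis=-1)
    lo = np.min(values, axis=-1)
    hi = np.max(values, axis=-1)
    return SummaryMetrics(average=avg, min=lo, max=hi, range=hi - lo)


def _cohort_mean_curves(
    dataset: StudyDataset, condition: str, session: int
) -> tuple[np.ndarray, list[str]]:
    """Cohort mean curve per channel: mean across subjects of per-subject
    session trial means.  Returns ((12, 101), subjects used)."""
    per_subject = []
    subjects = []
    for subj in dataset.subjects():
        keys = dataset.select(subject=subj, sessions=(session,), conditions=(condition,))
        if not keys:
            continue
        per_subject.append(dataset.stack(keys).mean(axis=0))
        subjects.append(subj)
    if not per_subject:
        raise ValidationError(f"no session-{session} trials for condition {condition!r}")
    return np.mean(per_subject, axis=0), subjects


def rmsd_conditions(
    dataset: StudyDataset,
    conditions: tuple[str, str] | None = None,
    session: int = 1,
    per_subject: bool = False,
) -> np.ndarray:
    """RMSD between the two clothing conditions' curves, per channel.

    Default (cohort-level): build each condition's cohort mean curve from
    session-1 trials, then take the root of the mean squared pointwise
    difference over the cycle.  With ``per_subject=True`` the RMSD is
    computed between each subject's own condition means and then averaged
    across subjects.
    """
    conditions = conditions or tuple(dataset.conditions())
    if len(conditions) != 2:
        raise ValidationError("RMSD compares exactly two conditions")
    for cond in conditions:
        if cond not in dataset.conditions():
            raise ValidationError(f"condition {cond!r} missing from dataset")
    if per_subject:
        diffs = []
        for subj in dataset.subjects():
            means = []
            for cond in conditions:
                keys = dataset.select(subject=subj, sessions=(session,), conditions=(cond,))
                if not keys:
                    break
                means.append(dataset.stack(keys).mean(axis=0))
            if len(means) == 2:
                diffs.append(np.sqrt(np.mean((means[0] - means[1]) ** 2, axis=-1)))
        if not diffs:
            raise ValidationError("no subject has both conditions in that session")
        return np.mean(diffs, axis=0)
    a, _ = _cohort_mean_curves(dataset, conditions[0], session)
    b, _ = _cohort_mean_curves(dataset, conditions[1], session)
    return np.sqrt(np.mean((a - b) ** 2, axis=-1))


def grand_average(cells: np.ndarray) -> tuple[float, float]:
    """Mean and across-cell SD of the 12 per-channel cycle averages.

    ``cells`` must supply all 12 joint/plane values; a missing (NaN) cell
    is an error, not silently dropped.
    """
    cells = np.asarray(cells, dtype=float).ravel()
    if cells.size != len(CHANNELS):
        raise ValidationError(f"grand average needs {len(CHANNELS)} cells, got {cells.size}")
    if not np.all(np.isfinite(cells)):
        raise ValidationError("grand average: missing cell")
    return float(np.mean(cells)), float(np.std(cells, ddof=1))


# -- Model / Results -------------------------------------------------------


class ReliabilityModel:
    """Gait-waveform reliability model over a study dataset.

    Parameters
    ----------
    dataset : StudyDataset
        Normalized gait-cycle curves (and optionally segment lengths) for
        subjects x sessions x conditions x trials.
    conditions : pair of str, optional
        The two clothing conditions to analyse (defaults to the dataset's).
    sessions : pair of int
        The two capture sessions (default ``(1, 2)``).
    rmsd_per_subject : bool
        Use the per-subject-then-averaged RMSD variant.
    subject_pooling : {'mean', 'rms'}
        How per-subject SD curves are pooled into cohort curves.
    """

    def __init__(
        self,
        dataset: StudyDataset,
        conditions: tuple[str, str] | None = None,
        sessions: tuple[int, int] = (1, 2),
        rmsd_per_subject: bool = False,
        subject_pooling: str = "mean",
    ) -> None:
        if subject_pooling not in ("mean", "rms"):
            raise ValidationError("subject_pooling must be 'mean' or 'rms'")
        self.dataset = dataset
        conds = conditions or tuple(dataset.conditions())
        if len(conds) != 2:
            raise ValidationError(
                f"reliability analysis needs exactly 2 conditions, found {conds}"
            )
        self.conditions = conds
        self.sessions = sessions
        self.rmsd_per_subject = rmsd_per_subject
        self.subject_pooling = subject_pooling

    @classmethod
    def from_manifest(cls, path, **kwargs) -> "ReliabilityModel":
        """Build a model from a study manifest on disk (raw trials are run
        through event detection / angle extraction / normalization)."""
        from .io.manifest import load_study
        from .pipeline import process_raw_trials

        dataset = load_study(path)
        process_raw_trials(dataset)
        return cls(dataset, **kwargs)

    def fit(self) -> "ReliabilityResults":
        ds = self.dataset
        if ds.raw:
            from .pipeline import process_raw_trials

            process_raw_trials(ds)
        pool = self.subject_pooling
        inter_trial = {
            c: inter_trial_variation(ds, c, session=self.sessions[0], pooling=pool)
            for c in self.conditions
        }
        inter_session = {
            c: inter_session_variation(ds, c, self.sessions, pooling=pool)
            for c in self.conditions
        }
        isc = inter_session_clothing_variation(
            ds, self.sessions, self.conditions, pooling=pool
        )
        ratios = {
            c: variability_ratio(inter_trial[c], inter_session[c])
            for c in self.conditions
        }
        rmsd = rmsd_conditions(
            ds, self.conditions, session=self.sessions[0],
            per_subject=self.rmsd_per_subject,
        )
        seg_report = None
        if ds.segment_lengths:
            from .angles import segment_length_report

            seg_report = segment_length_report(ds, sessions=self.sessions)
        return ReliabilityResults(
            model=self,
            inter_trial=inter_trial,
            inter_session=inter_session,
            inter_session_clothing=isc,
            ratios=ratios,
            rmsd=rmsd,
            segment_report=seg_report,
        )


class ReliabilityResults:
    """Fitted reliability estimates: variation curves, tables and scalars."""

    def __init__(
        self,
        model: ReliabilityModel,
        inter_trial: dict[str, VariationCurveSet],
        inter_session: dict[str, VariationCurveSet],
        inter_session_clothing: VariationCurveSet,
        ratios: dict[str, np.ndarray],
        rmsd: np.ndarray,
        segment_report=None,
    ) -> None:
        self.model = model
        self.inter_trial = inter_trial
        self.inter_session = inter_session
        self.inter_session_clothing = inter_session_clothing
        self.ratios = ratios
        self.rmsd = rmsd
        self.segment_report = segment_report

    # -- scalar accessors --------------------------------------------------
    def curve_sets(self) -> list[VariationCurveSet]:
        return (
            [self.inter_trial[c] for c in self.model.conditions]
            + [self.inter_session[c] for c in self.model.conditions]
            + [self.inter_session_clothing]
        )

    def cycle_averages(self, level: str, condition: str | None = None) -> np.ndarray:
        """The 12 per-channel cycle-average variations for one level."""
        cs = self._curve_set(level, condition)
        return summary_metrics(cs.values).average

    def grand_averages(self) -> dict[str, tuple[float, float]]:
        """Grand average (mean, across-cell SD) per level/condition."""
        out: dict[str, tuple[float, float]] = {}
        for c in self.model.conditions:
            out[f"inter_trial_{c}"] = grand_average(self.cycle_averages("inter_trial", c))
            out[f"inter_session_{c}"] = grand_average(
                self.cycle_averages("inter_session", c)
            )
        out["inter_session_clothing"] = grand_average(
            self.cycle_averages("inter_session_clothing")
        )
        return out

    def _curve_set(self, level: str, condition: str | None) -> VariationCurveSet:
        if level == "inter_trial":
            return self.inter_trial[condition]
        if level == "inter_session":
            return self.inter_session[condition]
        if level == "inter_session_clothing":
            return self.inter_session_clothing
        raise ValidationError(f"unknown level {level!r}")

    # -- tabular views -----------------------------------------------------
    def averages_table(self) -> pd.DataFrame:
        """Long-format table of cycle average/min/max/range per level,
        joint, plane and condition."""
        rows = []
        for cs in self.curve_sets():
            m = summary_metrics(cs.values)
            for i, (joint, plane) in enumerate(CHANNELS):
                rows.append(
                    {
                        "level": cs.level,
                        "condition": cs.condition,
                        "joint": joint,
                        "plane": plane,
                        "average": m.average[i],
                        "min": m.min[i],
                        "max": m.max[i],
                        "range": m.range[i],
                    }
                )
        return pd.DataFrame(rows)

    def ratio_table(self) -> pd.DataFrame:
        rows = []
        for c in self.model.conditions:
            for i, (joint, plane) in enumerate(CHANNELS):
                rows.append(
                    {"condition": c, "joint": joint, "plane": plane,
                     "ratio": self.ratios[c][i]}
                )
        return pd.DataFrame(rows)

    def rmsd_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"joint": joint, "plane": plane, "rmsd": self.rmsd[i]}
                for i, (joint, plane) in enumerate(CHANNELS)
            ]
        )

    # -- serialisation -----------------------------------------------------
    def to_summary_dict(self) -> dict:
        """All summary scalars at full precision (machine-readable)."""
        ga = self.grand_averages()
        d = {
            "conditions": list(self.model.conditions),
            "sessions": list(self.model.sessions),
            "n_trials": self.model.dataset.n_trials,
            "grand_averages": {
                k: {"mean": v[0], "sd": v[1]} for k, v in ga.items()
            },
            "averages": self.averages_table().to_dict(orient="records"),
            "ratios": self.ratio_table().to_dict(orient="records"),
            "ratio_means": {
                c: float(np.mean(self.ratios[c])) for c in self.model.conditions
            },
            "rmsd": self.rmsd_table().to_dict(orient="records"),
            "rmsd_mean": float(np.mean(self.rmsd)),
            "excluded": {
                f"{cs.level}" + (f"_{cs.condition}" if cs.condition else ""):
                    list(cs.excluded)
                for cs in self.curve_sets()
            },
        }
        if self.segment_report is not None:
            d["segment_lengths"] = {
                "per_subject": self.segment_report.per_subject.to_dict(orient="records"),
                "cohort": self.segment_report.cohort.to_dict(orient="records"),
            }
        return d

    def save_tables(self, outdir: str | Path) -> dict[str, Path]:
        """Write summary.json plus CSV tables and per-point variation
        curves.  Every CSV number is rendered from the JSON dictionary, so
        tables and JSON cannot disagree."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary = self.to_summary_dict()
        paths: dict[str, Path] = {}
        paths["summary.json"] = outdir / "summary.json"
        paths["summary.json"].write_text(json.dumps(summary, indent=2, sort_keys=True))

        avg = pd.DataFrame(summary["averages"])
        avg["condition"] = avg["condition"].fillna("")
        t1 = avg.pivot_table(
            index=["level", "condition", "joint"], columns="plane",
            values="average", sort=False,
        ).round(2)
        paths["table1.csv"] = outdir / "table1.csv"
        t1.to_csv(paths["table1.csv"])

        t2 = avg.copy()
        t2["min"] = t2["min"].round(2)
        t2["max"] = t2["max"].round(2)
        t2["range_str"] = t2["min"].map("{:.2f}".format) + "-" + t2["max"].map("{:.2f}".format)
        t2 = t2.pivot_table(
            index=["level", "condition", "joint"], columns="plane",
            values="range_str", aggfunc="first", sort=False,
        )
        paths["table2.csv"] = outdir / "table2.csv"
        t2.to_csv(paths["table2.csv"])

        t3 = pd.DataFrame(summary["ratios"]).pivot_table(
            index=["condition", "joint"], columns="plane", values="ratio",
            sort=False,
        ).round(2)
        paths["table3.csv"] = outdir / "table3.csv"
        t3.to_csv(paths["table3.csv"])

        paths["rmsd.csv"] = outdir / "rmsd.csv"
        pd.DataFrame(summary["rmsd"]).round(2).to_csv(paths["rmsd.csv"], index=False)

        if "segment_lengths" in summary:
            paths["table4.csv"] = outdir / "table4.csv"
            pd.DataFrame(summary["segment_lengths"]["cohort"]).round(2).to_csv(
                paths["table4.csv"], index=False
            )

        for cs in self.curve_sets():
            tag = cs.level + (f"_{cs.condition}" if cs.condition else "")
            p = outdir / f"curves_{tag}.csv"
            cs.to_frame().to_csv(p, index=False, float_format="%.6f")
            paths[p.name] = p
        return paths

    def summary(self) -> str:
        """Human-readable summary of the fitted reliability estimates."""
        ga = self.grand_averages()
        lines = [
            "Gait waveform reliability summary",
            "=" * 49,
            f"conditions: {', '.join(self.model.conditions)}; "
            f"sessions: {self.model.sessions}; trials: {self.model.dataset.n_trials}",
            "",
            "Grand averages across the 12 joint/plane channels (deg):",
        ]
        for key, (mean, sd) in ga.items():
            lines.append(f"  {key:<28s} {mean:5.2f} +/- {sd:.2f}")
        lines.append("")
        for c in self.model.conditions:
            lines.append(
                f"  variability ratio ({c}): {float(np.mean(self.ratios[c])):.2f}"
            )
        lines.append(f"  mean clothing RMSD: {float(np.mean(self.rmsd)):.2f} deg")
        lines.append("")
        lines.append("Cycle-average variation per channel (deg):")
        avg = self.averages_table()
        avg["condition"] = avg["condition"].fillna("")
        pivot = avg.pivot_table(
            index=["level", "condition", "joint"], columns="plane",
            values="average", sort=False,
        ).round(2)
        lines.append(pivot.to_string())
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_variation(self, **kwargs):
        from .plotting import plot_variation_curves

        return plot_variation_curves(self, **kwargs)

    def plot_condition_means(self, **kwargs):
        from .plotting import plot_condition_means

        return plot_condition_means(self.model.dataset, self.rmsd, **kwargs)
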