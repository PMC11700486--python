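"""Synthetic gait studies with a known hierarchical variance structure.

The reliability analysis decomposes kinematic variability into intrinsic
(inter-trial) and extrinsic (inter-session, inter-session-clothing) parts.
To validate it we need data whose true variance components are known.  A
simulated angle curve for subject *i*, session *s*, condition *c*, trial *t*
is

    y(t) = template + subject_i + session_is + condition_c + noise_ist

where ``template`` is a deterministic cohort-mean waveform and the random
terms are independent band-limited Fourier curves whose pointwise standard
deviation equals the requested sigma at every cycle point: a series
``sum_k a_k cos(2*pi*k*u) + b_k sin(2*pi*k*u)`` with i.i.d. Gaussian
coefficients of variance ``sigma^2 / K`` has pointwise variance exactly
``sigma^2`` and is periodic over the cycle.  The session curve is drawn per
(subject, session) and shared across clothing conditions and trials — it
models the extrinsic effect of repeating the whole capture setup on another
day.  The condition effect is a deterministic constant offset (+/- half the
effect between the two conditions), identical for every subject.

Random streams are derived from one root seed by hierarchical counters
(:class:`numpy.random.SeedSequence`), so any subject's data is reproducible
independently of how many other subjects are generated.

The module also provides :func:`simulate_walk_markers`, a kinematic walking
fixture (heel, toe and sacrum trajectories with known ground-truth gait
events) for testing coordinate-based event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CHANNELS, CONDITIONS, N_CYCLE_POINTS
from .datasets import GaitCycleCurves, StudyDataset, TrialRecording
from .errors import ValidationError

__all__ = [
    "WaveformTemplate",
    "VarianceSpec",
    "StudyDesign",
    "default_templates",
    "simulate_study",
    "simulate_walk_markers",
]


@dataclass(frozen=True)
class WaveformTemplate:
    """Deterministic cohort-mean waveform for one joint/plane channel.

    ``harmonics`` is a sequence of (amplitude_deg, phase_rad) pairs for
    harmonics 1, 2, ... of the gait cycle; the curve is

        offset + sum_k A_k * cos(2*pi*k*u + phi_k),   u in [0, 1],

    hence periodic by construction.
    """

    joint: str
    plane: str
    harmonics: tuple[tuple[float, float], ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.harmonics) < 1:
            raise ValidationError("a template needs at least one harmonic")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.full_like(u, self.offset)
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            out = out + amp * np.cos(2 * np.pi * k * u + phase)
        return out


@dataclass(frozen=True)
class VarianceSpec:
    """Variance components of the generative model, all in degrees.

    Defaults encode the study conditions the package targets: trial-level
    (intrinsic) SD 1.3 deg and session-level (extrinsic) SD 1.5 deg, close
    to the inter-trial variation and session increment observed in
    two-session markerless gait studies of healthy adults; a 1.4 deg
    deterministic clothing offset, matching reported average between-clothing
    RMSD; a 4 deg between-subject SD, since subjects differ far more than
    repeat trials; smooth curves with 6 harmonics.
    """

    sigma_subject: float = 4.0
    sigma_session: float = 1.5
    sigma_trial: float = 1.3
    condition_effect: float = 1.4
    smoothness: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_subject", "sigma_session", "sigma_trial"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.smoothness < 1:
            raise ValidationError("smoothness must be >= 1")


@dataclass(frozen=True)
class StudyDesign:
    """Study dimensions; defaults mirror a 22-subject, two-session,
    two-clothing-condition, five-trial gait reliability protocol."""

    n_subjects: int = 22
    n_sessions: int = 2
    n_conditions: int = 2
    n_trials: int = 5
    n_points: int = N_CYCLE_POINTS

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_conditions", "n_trials"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        if self.n_conditions == 2:
            return CONDITIONS
        return tuple(f"cond{i + 1}" for i in range(self.n_conditions))

    @property
    def subject_labels(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_subjects))


def default_templates() -> dict[tuple[str, str], WaveformTemplate]:
    """Textbook-range gait waveforms for all 12 joint/plane channels.

    Amplitudes follow typical adult walking ranges (knee flexion peaking
    near 60 deg, hip flexion-extension ~ +/-25 deg, ankle ~ +/-15 deg,
    pelvis excursions of a few degrees); exact values are illustrative and
    user-overridable, nothing asserts them.
    """
    spec: dict[tuple[str, str], tuple[float, tuple[tuple[float, float], ...]]] = {
        ("pelvis", "sagittal"): (8.0, ((1.5, 0.3), (0.8, 1.1))),
        ("pelvis", "frontal"): (0.0, ((4.0, -0.5), (1.0, 0.8))),
        ("pelvis", "transverse"): (0.0, ((5.0, 2.1), (1.2, -0.4))),
        ("hip", "sagittal"): (10.0, ((25.0, 0.4), (5.0, 1.9), (1.5, 0.2))),
        ("hip", "frontal"): (2.0, ((6.0, -0.9), (2.0, 1.4))),
        ("hip", "transverse"): (-3.0, ((6.0, 1.2), (1.5, -1.0))),
        ("knee", "sagittal"): (30.0, ((22.0, 2.6), (14.0, -0.8), (4.0, 1.5))),
        ("knee", "frontal"): (-1.0, ((3.0, 0.7), (1.0, -1.2))),
        ("knee", "transverse"): (4.0, ((7.0, -2.0), (2.0, 0.5))),
        ("ankle", "sagittal"): (2.0, ((10.0, -1.2), (6.0, 2.2), (2.0, 0.1))),
        ("ankle", "frontal"): (0.0, ((5.0, 1.6), (1.5, -0.7))),
        ("ankle", "transverse"): (-5.0, ((6.0, 0.9), (2.0, 2.4))),
    }
    return {
        (joint, plane): WaveformTemplate(joint, plane, harms, offset)
        for (joint, plane), (offset, harms) in spec.items()
    }


# -- random curve machinery ------------------------------------------------


def _stream(seed: int, *path: int) -> np.random.Generator:
    """Deterministic per-entity random stream from a root seed and a
    counter path, independent of sibling entities."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))


def _fourier_basis(n_points: int, n_harmonics: int) -> tuple[np.ndarray, np.ndarray]:
    u = np.linspace(0.0, 1.0, n_points)
    k = np.arange(1, n_harmonics + 1)[:, None]
    ang = 2 * np.pi * k * u[None, :]
    return np.cos(ang), np.sin(ang)


def random_curves(
    rng: np.random.Generator,
    sigma: float,
    n_harmonics: int,
    n_points: int = N_CYCLE_POINTS,
    n_channels: int = len(CHANNELS),
) -> np.ndarray:
    """Draw (n_channels, n_points) periodic curves whose pointwise SD is
    exactly ``sigma`` at every point (Gaussian-coefficient Fourier series).

    The random draw happens even when sigma == 0 so that stream positions
    do not depend on the variance values.
    """
    cosb, sinb = _fourier_basis(n_points, n_harmonics)
    coeffs = rng.standard_normal((2, n_channels, n_harmonics))
    scale = sigma / np.sqrt(n_harmonics)
    return scale * (coeffs[0] @ cosb + coeffs[1] @ sinb)


# -- study generation ------------------------------------------------------

#: default segment-length model (mm): per-subject base ~ N(mean, sd_subject),
#: plus per-(subject, session, condition) jitter and per-trial jitter.
_SEGMENT_BASES = {"shank_R": 400.0, "thigh_R": 420.0}
_SEGMENT_SD_SUBJECT = 20.0


def simulate_study(
    design: StudyDesign | None = None,
    templates: dict[tuple[str, str], WaveformTemplate] | None = None,
    var: VarianceSpec | None = None,
    *,
    include_segment_lengths: bool = True,
    sigma_length_session: float = 5.0,
    sigma_length_trial: float = 1.0,
) -> StudyDataset:
    """Generate a complete synthetic study of normalized gait-cycle curves.

    See the module docstring for the generative model.  Segment lengths
    (right shank and thigh, mm, constant within a trial) are generated with
    their own session- and trial-level jitter unless disabled.
    """
    design = design or StudyDesign()
    var = var or VarianceSpec()
    templates = templates if templates is not None else default_templates()
    missing = [ch for ch in CHANNELS if ch not in templates]
    if missing:
        raise ValidationError(f"templates missing for channels: {missing}")
    if sigma_length_session < 0 or sigma_length_trial < 0:
        raise ValidationError("segment-length sigmas must be >= 0")

    u = np.linspace(0.0, 1.0, design.n_points)
    base = np.stack([templates[ch](u) for ch in CHANNELS])  # (12, P)
    cond_labels = design.condition_labels
    cond_offsets = var.condition_effect * (
        np.arange(design.n_conditions) - (design.n_conditions - 1) / 2.0
    )

    ds = StudyDataset()
    ds.metadata = {
        "design": {
            "n_subjects": design.n_subjects,
            "n_sessions": design.n_sessions,
            "n_conditions": design.n_conditions,
            "n_trials": design.n_trials,
            "n_points": design.n_points,
        },
        "variance": {
            "sigma_subject": var.sigma_subject,
            "sigma_session": var.sigma_session,
            "sigma_trial": var.sigma_trial,
            "condition_effect": var.condition_effect,
            "smoothness": var.smoothness,
            "seed": var.seed,
        },
    }

    K = var.smoothness
    P = design.n_points
    for i, subj in enumerate(design.subject_labels):
        subj_curve = random_curves(
            _stream(var.seed, 1, i), var.sigma_subject, K, P
        )
        seg_rng = _stream(var.seed, 4, i)
        seg_base = {
            seg: mean + _SEGMENT_SD_SUBJECT * seg_rng.standard_normal()
            for seg, mean in _SEGMENT_BASES.items()
        }
        for s in range(design.n_sessions):
            sess_curve = random_curves(
                _stream(var.seed, 2, i, s), var.sigma_session, K, P
            )
            for c, cond in enumerate(cond_labels):
                sess_len_rng = _stream(var.seed, 5, i, s, c)
                seg_session = {
                    seg: base_len + sigma_length_session * sess_len_rng.standard_normal()
                    for seg, base_len in seg_base.items()
                }
                for t in range(design.n_trials):
                    noise = random_curves(
                        _stream(var.seed, 3, i, s, c, t), var.sigma_trial, K, P
                    )
                    values = base + subj_curve + sess_curve + cond_offsets[c] + noise
                    ds.add_trial(
                        (subj, s + 1, cond, t),
                        GaitCycleCurves(values=values),
                    )
                    if include_segment_lengths:
                        tr_rng = _stream(var.seed, 6, i, s, c, t)
                        for seg, length in seg_session.items():
                            ds.segment_lengths[(subj, s + 1, cond, t, seg)] = (
                                length + sigma_length_trial * tr_rng.standard_normal()
                            )
    return ds


# -- walking-marker fixture ------------------------------------------------


def _smooth_noise(
    rng: np.random.Generator, n: int, sd: float, n_harmonics: int
) -> np.ndarray:
    """Band-limited noise over the whole recording, pointwise SD ``sd``."""
    if sd == 0 or n_harmonics < 1:
        return np.zeros(n)
    u = np.linspace(0.0, 1.0, n)
    k = np.arange(1, n_harmonics + 1)[:, None]
    ang = 2 * np.pi * k * u[None, :]
    a, b = rng.standard_normal((2, n_harmonics))
    return (sd / np.sqrt(n_harmonics)) * (a @ np.cos(ang) + b @ np.sin(ang))


def simulate_walk_markers(
    n_steps: int,
    cadence: float = 110.0,
    frame_rate: float = 180.0,
    seed: int = 0,
    *,
    direction: int = 1,
    noise_mm: float = 1.5,
    stride_length_mm: float = 1250.0,
    start_x_mm: float = 0.0,
) -> TrialRecording:
    """Simulate heel, toe and sacrum trajectories of forward walking.

    ``n_steps`` counts heel strikes of the tracked (right) foot; ``cadence``
    is in strikes of that foot per minute.  The fore-aft heel-sacrum and
    toe-sacrum displacements are smooth periodic curves with maxima at heel
    strike and minima at toe-off respectively; ground-truth event frames —
    the per-cycle argmax/argmin of the *sampled, noisy* displacement — are
    attached in ``meta['heel_strikes']`` / ``meta['toe_offs']`` together
    with the declared travel axis ('+x' or '-x').
    """
    if cadence <= 0:
        raise ValidationError("cadence must be > 0")
    if n_steps < 2:
        raise ValidationError("need at least 2 steps for one complete cycle")
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be > 0")
    if direction not in (1, -1):
        raise ValidationError("direction must be +1 or -1")

    stride = 60.0 / cadence  # s between successive tracked-foot strikes
    t0 = 0.8 * stride
    duration = t0 + (n_steps - 1) * stride + 0.8 * stride
    n = int(np.floor(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    f = 1.0 / stride
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))

    phase = 2 * np.pi * f * (t - t0)
    heel_rel = 330.0 * (np.cos(phase) + 0.22 * np.cos(2 * phase + 0.9))
    toe_rel = 280.0 * (
        np.cos(phase - 2 * np.pi * 0.12) + 0.18 * np.cos(2 * phase + 0.4)
    )

    v = stride_length_mm / stride
    nharm = max(3, 3 * n_steps)
    sac_x = start_x_mm + v * t + _smooth_noise(rng, n, noise_mm, nharm)
    sac_y = 10.0 * np.sin(phase) + _smooth_noise(rng, n, noise_mm, nharm)
    sac_z = 950.0 + 15.0 * np.cos(2 * phase) + _smooth_noise(rng, n, noise_mm, nharm)
    sacrum = np.column_stack([sac_x, sac_y, sac_z])

    heel = np.column_stack(
        [
            sac_x + heel_rel + _smooth_noise(rng, n, noise_mm, nharm),
            sac_y - 120.0 + _smooth_noise(rng, n, noise_mm, nharm),
            60.0 + 40.0 * (1 - np.cos(phase)) + _smooth_noise(rng, n, noise_mm, nharm),
        ]
    )
    toe = np.column_stack(
        [
            sac_x + toe_rel + 180.0 + _smooth_noise(rng, n, noise_mm, nharm),
            sac_y - 130.0 + _smooth_noise(rng, n, noise_mm, nharm),
            30.0 + 30.0 * (1 - np.cos(phase - 0.6)) + _smooth_noise(rng, n, noise_mm, nharm),
        ]
    )

    # ground truth: per-cycle extremum of the sampled displacement
    disp_heel = heel[:, 0] - sacrum[:, 0]
    disp_toe = toe[:, 0] - sacrum[:, 0]
    heel_strikes = []
    for k in range(n_steps):
        lo = int(np.ceil((t0 + (k - 0.5) * stride) * frame_rate))
        hi = int(np.floor((t0 + (k + 0.5) * stride) * frame_rate))
        lo, hi = max(lo, 0), min(hi, n - 1)
        heel_strikes.append(lo + int(np.argmax(disp_heel[lo : hi + 1])))
    toe_offs = []
    for k in range(n_steps - 1):
        centre = t0 + (k + 0.62) * stride
        lo = int(np.ceil((centre - 0.4 * stride) * frame_rate))
        hi = int(np.floor((centre + 0.4 * stride) * frame_rate))
        lo, hi = max(lo, 0), min(hi, n - 1)
        toe_offs.append(lo + int(np.argmin(disp_toe[lo : hi + 1])))

    if direction == -1:
        for arr in (sacrum, heel, toe):
            arr[:, 0] *= -1.0

    return TrialRecording(
        frame_rate=frame_rate,
        points={"r_heel": heel, "r_toe": toe, "sacrum": sacrum},
        meta={
            "heel_strikes": np.asarray(heel_strikes, dtype=int),
            "toe_offs": np.asarray(toe_offs, dtype=int),
            "travel_axis": "+x" if direction == 1 else "-x",
            "cadence": cadence,
        },
    )
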