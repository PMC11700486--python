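"""Synthetic study generator: variance structure, determinism, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose, assert_array_equal
from scipy.special import gammaln

import gaitrel as g
from gaitrel.constants import CHANNELS
from gaitrel.errors import ValidationError
from gaitrel.simulate import random_curves


def c4(n: int) -> float:
    """Small-sample bias factor: E[sample SD] = c4(n) * sigma under normality."""
    return float(np.exp(0.5 * np.log(2.0 / (n - 1)) + gammaln(n / 2) - gammaln((n - 1) / 2)))


def test_zero_variance_reproduces_templates(templates):
    var = g.VarianceSpec(
        sigma_subject=0, sigma_session=0, sigma_trial=0, condition_effect=0, seed=3
    )
    ds = g.simulate_study(g.StudyDesign(n_subjects=2, n_trials=2), templates, var)
    u = np.linspace(0, 1, 101)
    base = np.stack([templates[ch](u) for ch in CHANNELS])
    for curves in ds.trials.values():
        assert_allclose(curves.values, base, atol=1e-12)


def test_same_seed_gives_bit_identical_datasets():
    design = g.StudyDesign(n_subjects=2, n_trials=2)
    a = g.simulate_study(design, var=g.VarianceSpec(seed=7))
    b = g.simulate_study(design, var=g.VarianceSpec(seed=7))
    assert set(a.trials) == set(b.trials)
    for key in a.trials:
        assert_array_equal(a.trials[key].values, b.trials[key].values)
    assert a.segment_lengths == b.segment_lengths


def test_subject_streams_independent_of_cohort_size():
    # per-entity counter seeding: subject S01 is identical whether the
    # study has 2 or 5 subjects
    small = g.simulate_study(g.StudyDesign(n_subjects=2, n_trials=2), var=g.VarianceSpec(seed=5))
    large = g.simulate_study(g.StudyDesign(n_subjects=5, n_trials=2), var=g.VarianceSpec(seed=5))
    for key in small.select(subject="S01"):
        assert_array_equal(small.trials[key].values, large.trials[key].values)


@given(
    harmonics=st.lists(
        st.tuples(
            st.floats(-30, 30, allow_nan=False), st.floats(-np.pi, np.pi, allow_nan=False)
        ),
        min_size=1,
        max_size=6,
    ),
    offset=st.floats(-40, 40, allow_nan=False),
)
@settings(max_examples=50, deadline=None)
def test_template_periodicity(harmonics, offset):
    tpl = g.WaveformTemplate("knee", "sagittal", tuple(harmonics), offset)
    assert np.isclose(tpl(np.array(0.0)), tpl(np.array(1.0)), atol=1e-9)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(sigma_trial=-0.1),
        dict(sigma_session=-1.0),
        dict(sigma_subject=-2.0),
        dict(smoothness=0),
    ],
)
def test_invalid_variance_spec_rejected(kwargs):
    with pytest.raises(ValidationError):
        g.VarianceSpec(**kwargs)


def test_missing_template_rejected(templates):
    incomplete = dict(templates)
    incomplete.pop(("knee", "sagittal"))
    with pytest.raises(ValidationError, match="missing"):
        g.simulate_study(g.StudyDesign(n_subjects=1), incomplete)


def test_empty_template_harmonics_rejected():
    with pytest.raises(ValidationError):
        g.WaveformTemplate("hip", "frontal", ())


@pytest.mark.parametrize("bad", [dict(n_subjects=0), dict(n_trials=0), dict(n_points=1)])
def test_design_validation(bad):
    with pytest.raises(ValidationError):
        g.StudyDesign(**bad)


def test_noise_curves_pointwise_sd_matches_sigma():
    # pointwise sample SD of many band-limited noise curves converges to
    # sigma at every one of the 101 points
    sigma = 1.3
    rng = np.random.default_rng(0)
    draws = np.concatenate([random_curves(rng, sigma, 6) for _ in range(500)])
    sd = draws.std(axis=0, ddof=1)  # (101,) pooled over 6000 curves
    assert sd.shape == (101,)
    assert_allclose(sd, sigma, rtol=0.05)


def test_inter_trial_recovery_matches_c4_corrected_sigma():
    # Monte-Carlo oracle: cohort inter-trial variation estimates
    # c4(n_trials) * sigma_trial
    sigma_trial = 1.3
    design = g.StudyDesign(n_subjects=4, n_sessions=1, n_trials=5)
    means = []
    for rep in range(40):
        ds = g.simulate_study(
            design,
            var=g.VarianceSpec(sigma_trial=sigma_trial, sigma_session=0.7, seed=100 + rep),
        )
        cs = g.inter_trial_variation(ds, "tight")
        means.append(cs.values.mean())
    assert_allclose(np.mean(means), c4(5) * sigma_trial, rtol=0.04)


def test_intersession_converges_to_intertrial_without_session_effect():
    # with sigma_session = 0 and no condition effect, pooled two-session
    # variation estimates the same sigma as inter-trial variation
    ds = g.simulate_study(
        g.StudyDesign(n_subjects=4, n_trials=50),
        var=g.VarianceSpec(sigma_session=0, condition_effect=0, seed=21),
    )
    it = g.inter_trial_variation(ds, "tight").values.mean()
    isv = g.inter_session_variation(ds, "tight").values.mean()
    assert abs(isv - it) / it < 0.05


def test_pooled_two_level_variance_closed_form():
    # one-way random effects, k=2 sessions of n=5 trials sharing a session
    # offset: E[pooled sample variance] = sigma_t^2 + (5/9) sigma_s^2
    st_, ss = 1.3, 1.5
    design = g.StudyDesign(n_subjects=6, n_trials=5)
    variances = []
    for rep in range(60):
        ds = g.simulate_study(
            design,
            var=g.VarianceSpec(sigma_trial=st_, sigma_session=ss, seed=500 + rep),
        )
        for subj in ds.subjects():
            keys = ds.select(subject=subj, sessions=(1, 2), conditions=("tight",))
            variances.append(np.var(ds.stack(keys), axis=0, ddof=1).mean())
    expected = st_**2 + (5.0 / 9.0) * ss**2
    assert_allclose(np.mean(variances), expected, rtol=0.05)


# -- walking-marker fixture -------------------------------------------------


def test_walk_ground_truth_counts_and_monotonicity():
    rec = g.simulate_walk_markers(6, cadence=110, frame_rate=180, seed=1)
    hs = rec.meta["heel_strikes"]
    assert len(hs) == 6
    assert np.all(np.diff(hs) > 0)
    assert len(rec.meta["toe_offs"]) == 5


def test_walk_ground_truth_is_per_cycle_argmax():
    # brute-force oracle: displacement at each ground-truth heel strike is
    # the maximum within half a stride on either side
    rec = g.simulate_walk_markers(5, cadence=100, frame_rate=180, seed=3)
    disp = rec.points["r_heel"][:, 0] - rec.points["sacrum"][:, 0]
    stride_frames = int(round(60.0 / 100.0 * 180))
    for f in rec.meta["heel_strikes"]:
        lo = max(0, f - stride_frames // 2)
        hi = min(len(disp), f + stride_frames // 2)
        assert disp[f] == np.max(disp[lo:hi])


def test_walk_direction_flip_keeps_events():
    fwd = g.simulate_walk_markers(5, seed=4, direction=1)
    bwd = g.simulate_walk_markers(5, seed=4, direction=-1)
    assert_array_equal(fwd.meta["heel_strikes"], bwd.meta["heel_strikes"])
    assert_allclose(fwd.points["sacrum"][:, 0], -bwd.points["sacrum"][:, 0])


@pytest.mark.parametrize(
    "kwargs", [dict(cadence=0), dict(cadence=-5), dict(n_steps=1), dict(frame_rate=0)]
)
def test_walk_invalid_args_rejected(kwargs):
    args = dict(n_steps=4, cadence=110, frame_rate=180)
    args.update(kwargs)
    with pytest.raises(ValidationError):
        g.simulate_walk_markers(args.pop("n_steps"), **args)
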