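"""Gait event detection, central-cycle selection and time normalization."""

import numpy as np
import pytest
from numpy.testing import assert_allclose, assert_array_equal

import gaitrel as g
from gaitrel.errors import GapError, NoCompleteCycleError, ValidationError
from gaitrel.events import GaitEvents, select_central_cycle, time_normalize


def _sinusoid_trial(period=180, n_periods=5, amplitude=300.0):
    n = period * n_periods
    t = np.arange(n)
    rel = amplitude * np.sin(2 * np.pi * t / period)
    sacrum = np.column_stack([5.0 * t, np.zeros(n), np.full(n, 950.0)])
    heel = sacrum.copy()
    heel[:, 0] += rel
    toe = sacrum.copy()
    toe[:, 0] += rel  # same phase: minima fall mid-cycle between maxima
    return heel, toe, sacrum, period


def test_sinusoid_maxima_at_analytic_argmax():
    heel, toe, sacrum, period = _sinusoid_trial()
    ev = g.detect_events(heel, toe, sacrum, travel_axis="+x")
    expected = period // 4 + period * np.arange(5)
    assert_array_equal(ev.heel_strikes, expected)
    assert_array_equal(ev.toe_offs, 3 * period // 4 + period * np.arange(4))


@pytest.mark.parametrize("cadence", [80, 95, 110, 125, 140])
def test_simulator_events_recovered_within_one_frame(cadence):
    rec = g.simulate_walk_markers(6, cadence=cadence, frame_rate=180, seed=13)
    ev = g.detect_events(
        rec.points["r_heel"], rec.points["r_toe"], rec.points["sacrum"],
        travel_axis=rec.meta["travel_axis"],
    )
    assert len(ev.heel_strikes) == 6
    assert len(ev.cycles) == 6 - 1  # cycles = steps - 1
    assert np.max(np.abs(ev.heel_strikes - rec.meta["heel_strikes"])) <= 1


def test_stationary_subject_has_no_complete_cycle():
    still = np.zeros((500, 3))
    with pytest.raises(NoCompleteCycleError, match="no complete cycle"):
        g.detect_events(still, still, still)


def test_detection_invariant_to_constant_offset():
    heel, toe, sacrum, _ = _sinusoid_trial()
    ev1 = g.detect_events(heel, toe, sacrum)
    shift = np.array([1234.5, -90.0, 41.0])
    ev2 = g.detect_events(heel + shift, toe + shift, sacrum + shift)
    assert_array_equal(ev1.heel_strikes, ev2.heel_strikes)
    assert_array_equal(ev1.toe_offs, ev2.toe_offs)


def test_gap_overlapping_peak_rejected():
    heel, toe, sacrum, period = _sinusoid_trial()
    heel[period // 4 - 2 : period // 4 + 2, 0] = np.nan
    with pytest.raises(GapError):
        g.detect_events(heel, toe, sacrum)


def test_events_invariants_enforced():
    with pytest.raises(ValidationError, match="increasing"):
        GaitEvents(heel_strikes=[10, 5], toe_offs=[7])
    with pytest.raises(ValidationError, match="alternation"):
        GaitEvents(heel_strikes=[0, 100], toe_offs=[40, 60])
    ok = GaitEvents(heel_strikes=[0, 100, 200], toe_offs=[60, 160])
    assert ok.cycles == [(0, 100), (100, 200)]


# -- central cycle selection ------------------------------------------------


def _events_with_positions(midpoints_mm):
    # cycles (0,100), (100,200), ... with the sacrum placed so that each
    # mid-cycle position is as requested
    n_cycles = len(midpoints_mm)
    hs = 100 * np.arange(n_cycles + 1)
    events = GaitEvents(heel_strikes=hs, toe_offs=hs[:-1] + 50)
    pos = np.zeros((hs[-1] + 1, 3))
    for i, m in enumerate(midpoints_mm):
        pos[(hs[i] + hs[i + 1]) // 2, 0] = m
    return events, pos


def test_central_cycle_nearest_volume_centre():
    events, pos = _events_with_positions([1000.0, 3100.0, 5000.0])
    assert select_central_cycle(events, pos, volume_bounds=(0, 6000)) == (100, 200)


def test_central_cycle_single_cycle_returned():
    events = GaitEvents(heel_strikes=[10, 110], toe_offs=[70])
    assert select_central_cycle(events, np.zeros((200, 3))) == (10, 110)


def test_central_cycle_tie_breaks_earlier():
    events, pos = _events_with_positions([2900.0, 3100.0])
    assert select_central_cycle(events, pos, volume_bounds=(0, 6000)) == (0, 100)


def test_central_cycle_temporal_fallback_without_bounds():
    events, pos = _events_with_positions([1000.0, 3100.0, 5000.0])
    # recording midpoint is frame 150 -> middle cycle
    assert select_central_cycle(events, pos, volume_bounds=None) == (100, 200)


# -- time normalization -----------------------------------------------------


def test_normalize_linear_ramp():
    series = np.linspace(0.0, 10.0, 201)  # ramp over frames 0..200
    out = time_normalize(series, 0, 200)
    assert out.shape == (101,)
    assert_allclose(out, np.arange(101) * 0.1, atol=1e-12)
    assert out[50] == pytest.approx(5.0)


def test_normalize_constant_series():
    out = time_normalize(np.full(300, 7.25), 10, 260)
    assert_allclose(out, 7.25)


def test_normalize_sine_interpolation_error_below_hundredth_degree():
    frames = np.arange(301)
    series = 10.0 * np.sin(2 * np.pi * frames / 300)  # degrees
    out = time_normalize(series, 0, 300)
    exact = 10.0 * np.sin(2 * np.pi * np.linspace(0, 300, 101) / 300)
    assert np.max(np.abs(out - exact)) < 0.01


def test_normalize_idempotent_on_normalized_cycle():
    rng = np.random.default_rng(5)
    curve = rng.normal(size=101)
    assert_allclose(time_normalize(curve, 0, 100), curve, atol=1e-12)


def test_normalize_preserves_endpoints_and_rejects_gaps():
    series = np.random.default_rng(0).normal(size=400)
    out = time_normalize(series, 20, 330)
    assert out[0] == series[20] and out[-1] == series[330]
    series[100] = np.nan
    with pytest.raises(GapError):
        time_normalize(series, 20, 330)
    with pytest.raises(ValidationError):
        time_normalize(series, 50, 50)
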