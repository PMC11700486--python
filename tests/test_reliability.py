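"""Variation curves, ratios, RMSD, grand averages and the Model/Results API."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from numpy.testing import assert_allclose, assert_array_equal

import gaitrel as g
from gaitrel.constants import CHANNELS
from gaitrel.errors import ValidationError
from gaitrel.reliability import VariationCurve

from conftest import build_dataset, constant_curves


# -- pointwise SD -----------------------------------------------------------


def test_pointwise_sd_of_constant_curves_123():
    curves = np.stack([constant_curves(v) for v in (1.0, 2.0, 3.0)])
    assert_allclose(g.pointwise_sd(curves), 1.0)  # sample SD of {1,2,3}


def test_pointwise_sd_identical_curves_zero():
    curves = np.stack([constant_curves(4.2)] * 5)
    assert_allclose(g.pointwise_sd(curves), 0.0)


def test_pointwise_sd_two_curves_closed_form():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=(2, 12, 101))
    assert_allclose(g.pointwise_sd(np.stack([a, b])), np.abs(a - b) / np.sqrt(2))


def test_pointwise_sd_requires_two_curves():
    with pytest.raises(ValidationError):
        g.pointwise_sd(np.zeros((1, 12, 101)))


# -- variation levels -------------------------------------------------------


def test_inter_trial_zero_for_identical_trials():
    ds = build_dataset(
        {("S01", 1, "tight", t): 5.0 for t in range(5)}
        | {("S02", 1, "tight", t): 9.0 for t in range(5)}
    )
    assert_allclose(g.inter_trial_variation(ds, "tight").values, 0.0)


def test_inter_trial_two_subject_hand_example():
    # subject A: trials at 1 and 3 -> SD sqrt(2); subject B: identical -> 0
    ds = build_dataset(
        {
            ("A", 1, "tight", 0): 1.0,
            ("A", 1, "tight", 1): 3.0,
            ("B", 1, "tight", 0): 2.0,
            ("B", 1, "tight", 1): 2.0,
        }
    )
    expected = (np.abs(3.0 - 1.0) / np.sqrt(2) + 0.0) / 2
    assert_allclose(g.inter_trial_variation(ds, "tight").values, expected)


def test_inter_trial_excludes_single_trial_subject_with_warning():
    ds = build_dataset(
        {
            ("A", 1, "tight", 0): 1.0,
            ("A", 1, "tight", 1): 3.0,
            ("B", 1, "tight", 0): 2.0,
        }
    )
    with pytest.warns(UserWarning, match="excluded"):
        cs = g.inter_trial_variation(ds, "tight")
    assert cs.excluded == ["B"] and cs.n_subjects == 1


def test_inter_session_matches_brute_force_pooled_sd():
    # session 2 = session 1 + per-subject constant offset
    rng = np.random.default_rng(3)
    cells = {}
    pooled = []
    for subj, delta in (("A", 2.0), ("B", -1.0)):
        base = [rng.normal(0, 1, (12, 101)) for _ in range(3)]
        for t, b in enumerate(base):
            cells[(subj, 1, "loose", t)] = b
            cells[(subj, 2, "loose", t)] = b + delta
        stack = np.stack(base + [b + delta for b in base])
        pooled.append(stack.std(axis=0, ddof=1))
    ds = build_dataset(cells)
    assert_allclose(
        g.inter_session_variation(ds, "loose").values, np.mean(pooled, axis=0), atol=1e-12
    )


def test_inter_session_excludes_single_session_subject():
    ds = build_dataset(
        {("A", s, "tight", t): float(s + t) for s in (1, 2) for t in range(2)}
        | {("B", 1, "tight", t): 1.0 for t in range(2)}
    )
    with pytest.warns(UserWarning, match="excluded"):
        cs = g.inter_session_variation(ds, "tight")
    assert cs.excluded == ["B"]


def test_inter_session_clothing_constant_offset_closed_form():
    # ten trials at +1 and ten at -1 about the mean: SD = sqrt(20/19)
    cells = {}
    for ses in (1, 2):
        for t in range(5):
            cells[("A", ses, "tight", t)] = -1.0
            cells[("A", ses, "loose", t)] = 1.0
    ds = build_dataset(cells)
    assert_allclose(
        g.inter_session_clothing_variation(ds).values, np.sqrt(20.0 / 19.0), atol=1e-12
    )


def test_inter_session_clothing_identical_everything_zero():
    ds = build_dataset(
        {("A", s, c, t): 3.0 for s in (1, 2) for c in ("tight", "loose") for t in range(2)}
    )
    assert_allclose(g.inter_session_clothing_variation(ds).values, 0.0)


def test_variation_curve_invariants():
    with pytest.raises(ValidationError):
        VariationCurve("inter_trial", "knee", "sagittal", -np.ones(101))
    with pytest.raises(ValidationError):
        VariationCurve("inter_session_clothing", "knee", "sagittal", np.ones(101), condition="tight")
    with pytest.raises(ValidationError):
        VariationCurve("inter_trial", "knee", "sagittal", np.ones(100))


# -- ratios -----------------------------------------------------------------


def test_ratio_identical_curves_is_one():
    c = np.abs(np.random.default_rng(1).normal(1, 0.2, (12, 101))) + 0.1
    assert_allclose(g.variability_ratio(c, c), 1.0)


def test_ratio_proportional_curves():
    c = np.abs(np.random.default_rng(2).normal(1, 0.2, (12, 101))) + 0.1
    assert_allclose(g.variability_ratio(c, 1.5 * c), 1.5)


def test_ratio_pointwise_then_average_differs_from_ratio_of_means():
    # curves (1,2) and (2,2): pointwise mean (2/1 + 2/2)/2 = 1.5, whereas
    # the ratio of cycle means would be 2/1.5 ~= 1.33 - the documented
    # definition is pointwise-then-average
    ratio = g.variability_ratio(np.array([1.0, 2.0]), np.array([2.0, 2.0]))
    assert ratio == pytest.approx(1.5)
    assert ratio != pytest.approx(2.0 / 1.5)


def test_ratio_excludes_zero_points_and_rejects_all_zero():
    it = np.array([0.0, 1.0, 2.0])
    isv = np.array([5.0, 2.0, 2.0])
    assert g.variability_ratio(it, isv) == pytest.approx((2.0 / 1.0 + 2.0 / 2.0) / 2)
    with pytest.raises(ValidationError, match="all-zero"):
        g.variability_ratio(np.zeros(101), np.ones(101))


def test_simulated_session_effect_raises_ratio_above_one():
    ds = g.simulate_study(
        g.StudyDesign(n_subjects=8), var=g.VarianceSpec(sigma_session=1.5, seed=2)
    )
    res = g.ReliabilityModel(ds).fit()
    for cond in res.model.conditions:
        assert np.all(res.ratios[cond] > 1.0)


# -- summary metrics --------------------------------------------------------


def test_summary_metrics_constant_and_linear():
    avg, lo, hi, rng_ = g.summary_metrics(np.full(101, 2.0))
    assert (avg, lo, hi, rng_) == (2.0, 2.0, 2.0, 0.0)
    avg, lo, hi, rng_ = g.summary_metrics(np.arange(101) / 100.0)
    assert avg == pytest.approx(0.5)
    assert (lo, hi, rng_) == (0.0, 1.0, 1.0)


@given(arrays(float, 101, elements=st.floats(0, 50, allow_nan=False)))
@settings(max_examples=50, deadline=None)
def test_summary_metrics_ordering_property(curve):
    m = g.summary_metrics(curve)
    assert m.min - 1e-9 <= m.average <= m.max + 1e-9
    assert m.range == m.max - m.min


# -- RMSD -------------------------------------------------------------------


def _two_condition_dataset(tight_curve, loose_curve):
    return build_dataset(
        {("A", 1, "tight", 0): tight_curve, ("A", 1, "loose", 0): loose_curve}
    )


def test_rmsd_identical_condition_means_zero():
    c = np.random.default_rng(0).normal(size=(12, 101))
    assert_allclose(g.rmsd_conditions(_two_condition_dataset(c, c)), 0.0, atol=1e-12)


def test_rmsd_constant_offset():
    c = np.random.default_rng(1).normal(size=(12, 101))
    assert_allclose(g.rmsd_conditions(_two_condition_dataset(c, c + 2.0)), 2.0)


def test_rmsd_sinusoidal_difference_matches_discrete_rms():
    x = np.linspace(0, 2 * np.pi, 101)
    diff = 2.0 * np.sin(x)
    ds = _two_condition_dataset(constant_curves(0.0), constant_curves(diff))
    expected = np.sqrt(np.mean(diff**2))  # ~ 2/sqrt(2) up to discretization
    assert_allclose(g.rmsd_conditions(ds), expected)
    assert expected == pytest.approx(np.sqrt(2.0), abs=0.02)


def test_rmsd_missing_condition_rejected():
    ds = build_dataset({("A", 1, "tight", 0): 1.0})
    with pytest.raises(ValidationError):
        g.rmsd_conditions(ds, conditions=("tight", "loose"))


def test_rmsd_per_subject_variant_on_heterogeneous_subjects():
    # subject A differs by +2, subject B by -2: cohort means cancel but the
    # per-subject variant sees 2 for each
    cells = {
        ("A", 1, "tight", 0): 0.0, ("A", 1, "loose", 0): 2.0,
        ("B", 1, "tight", 0): 0.0, ("B", 1, "loose", 0): -2.0,
    }
    ds = build_dataset(cells)
    assert_allclose(g.rmsd_conditions(ds), 0.0, atol=1e-12)
    assert_allclose(g.rmsd_conditions(ds, per_subject=True), 2.0)


# -- grand average ----------------------------------------------------------


def test_grand_average_identical_cells():
    mean, sd = g.grand_average(np.full(12, 1.7))
    assert mean == pytest.approx(1.7) and sd == 0.0


def test_grand_average_brute_force_equivalence():
    rng = np.random.default_rng(5)
    for _ in range(20):
        cells = rng.uniform(0.2, 4.0, 12)
        mean, sd = g.grand_average(cells)
        assert mean == pytest.approx(sum(cells) / 12, abs=1e-12)
        assert sd == pytest.approx(
            np.sqrt(sum((c - mean) ** 2 for c in cells) / 11), abs=1e-12
        )


def test_grand_average_missing_cell_rejected():
    cells = np.full(12, 1.0)
    cells[3] = np.nan
    with pytest.raises(ValidationError):
        g.grand_average(cells)
    with pytest.raises(ValidationError):
        g.grand_average(np.ones(11))


# -- invariances ------------------------------------------------------------


def test_trial_order_permutation_changes_nothing(small_study):
    permuted = g.StudyDataset()
    rng = np.random.default_rng(0)
    for subj in small_study.subjects():
        for ses in small_study.sessions():
            for cond in small_study.conditions():
                keys = small_study.select(subject=subj, sessions=[ses], conditions=[cond])
                for new_t, key in enumerate(rng.permutation(len(keys))):
                    permuted.add_trial(
                        (subj, ses, cond, new_t), small_study.trials[keys[key]]
                    )
    res_a = g.ReliabilityModel(small_study).fit()
    res_b = g.ReliabilityModel(permuted).fit()
    for cond in res_a.model.conditions:
        assert_allclose(
            res_a.inter_trial[cond].values, res_b.inter_trial[cond].values, rtol=1e-12
        )
        assert_allclose(res_a.ratios[cond], res_b.ratios[cond], rtol=1e-12)
    assert_allclose(res_a.rmsd, res_b.rmsd, rtol=1e-12)


def test_variation_curves_non_negative(small_study):
    res = g.ReliabilityModel(small_study).fit()
    for cs in res.curve_sets():
        assert np.all(cs.values >= 0)


def test_session_effect_increases_intersession_over_intertrial():
    ds = g.simulate_study(
        g.StudyDesign(n_subjects=8), var=g.VarianceSpec(sigma_session=1.5, seed=17)
    )
    res = g.ReliabilityModel(ds).fit()
    ga = res.grand_averages()
    for cond in res.model.conditions:
        assert ga[f"inter_session_{cond}"][0] > ga[f"inter_trial_{cond}"][0]


# -- Model / Results surface ------------------------------------------------


def test_model_requires_two_conditions():
    ds = build_dataset({("A", 1, "tight", t): float(t) for t in range(2)})
    with pytest.raises(ValidationError, match="2 conditions"):
        g.ReliabilityModel(ds)


def test_results_summary_and_tables(small_study, tmp_path):
    res = g.ReliabilityModel(small_study).fit()
    text = res.summary()
    assert "Grand averages" in text and "variability ratio" in text
    paths = res.save_tables(tmp_path)
    for name in ("summary.json", "table1.csv", "table2.csv", "table3.csv", "rmsd.csv"):
        assert paths[name].exists()
    # every rendered table value is reproducible from summary.json
    summary = json.loads(paths["summary.json"].read_text())
    import pandas as pd

    t1 = pd.read_csv(paths["table1.csv"])
    for rec in summary["averages"]:
        row = t1[
            (t1["level"] == rec["level"])
            & (t1["condition"].fillna("") == (rec["condition"] or ""))
            & (t1["joint"] == rec["joint"])
        ]
        assert row[rec["plane"]].iloc[0] == pytest.approx(round(rec["average"], 2))


def test_results_deterministic_summary_json(small_study, tmp_path):
    (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
    g.ReliabilityModel(small_study).fit().save_tables(tmp_path / "a")
    g.ReliabilityModel(small_study).fit().save_tables(tmp_path / "b")
    assert (tmp_path / "a" / "summary.json").read_bytes() == (
        tmp_path / "b" / "summary.json"
    ).read_bytes()


def test_rms_pooling_at_least_mean_pooling(small_study):
    mean_fit = g.ReliabilityModel(small_study, subject_pooling="mean").fit()
    rms_fit = g.ReliabilityModel(small_study, subject_pooling="rms").fit()
    for cond in mean_fit.model.conditions:
        assert np.all(
            rms_fit.inter_trial[cond].values >= mean_fit.inter_trial[cond].values - 1e-12
        )
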