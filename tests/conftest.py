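import numpy as np
import pytest

import gaitrel as g
from gaitrel.constants import CHANNELS, N_CYCLE_POINTS


def constant_curves(value) -> np.ndarray:
    """A (12, 101) curve block, constant at `value` (scalar or per-point)."""
    return np.broadcast_to(
        np.asarray(value, dtype=float), (len(CHANNELS), N_CYCLE_POINTS)
    ).copy()


def build_dataset(cells: dict) -> g.StudyDataset:
    """Dataset from {(subject, session, condition, trial): curve-like}."""
    ds = g.StudyDataset()
    for key, value in cells.items():
        value = np.asarray(value, dtype=float)
        if value.shape != (len(CHANNELS), N_CYCLE_POINTS):
            value = constant_curves(value)
        ds.add_trial(key, g.GaitCycleCurves(values=value))
    return ds


@pytest.fixture(scope="session")
def small_study() -> g.StudyDataset:
    """3 subjects x 2 sessions x 2 conditions x 3 trials, default variances."""
    return g.simulate_study(
        g.StudyDesign(n_subjects=3, n_trials=3), var=g.VarianceSpec(seed=11)
    )


@pytest.fixture(scope="session")
def templates():
    return g.default_templates()
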