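import numpy as np
import pytest

from sparserules.optimizer import FitConfig, fit
from sparserules.rulespace import Dataset
from sparserules.synthdata import SyntheticSpec, generate
from sparserules.rulespace import ConjunctionRule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_rule_spec():
    """Noise-free cohort labelled by one planted order-2 rule."""
    rule = ConjunctionRule.from_dict({0: (0.5, np.inf), 1: (-np.inf, 0.5)})
    return SyntheticSpec(
        n=200,
        p=4,
        planted_rules=[rule],
        rule_weights=[2.0],
        intercept=-1.0,
        label_noise=0.0,
        seed=7,
    )


@pytest.fixture
def separable_data():
    """Noise-free cohort whose planted boundary sits exactly on the B=6 grid,
    so a fitted rule can reproduce the labels with zero training error."""
    from sparserules.rulespace import build_cutpoints
    from sparserules.synthdata import GroundTruth

    rng = np.random.default_rng(7)
    X = rng.random((200, 4))
    cuts = build_cutpoints(X, 6)
    t0 = float(cuts.cuts[0][np.argmin(np.abs(cuts.cuts[0] - 0.5))])
    t1 = float(cuts.cuts[1][np.argmin(np.abs(cuts.cuts[1] - 0.5))])
    rule = ConjunctionRule.from_dict({0: (t0, np.inf), 1: (-np.inf, t1)})
    y = np.where(rule.activations(X) == 1, 1, -1)
    truth = GroundTruth(
        rules=[rule], weights=[2.0], intercept=-1.0,
        clean_y=y, flipped=np.zeros(200, dtype=bool),
    )
    return Dataset(X, y), truth


@pytest.fixture
def fitted_separable(separable_data):
    data, truth = separable_data
    cfg = FitConfig(C=2.0, d=0.5, bins=6, max_rule_order=2, max_iterations=30, seed=0)
    return fit(data, cfg), data, truth


@pytest.fixture
def random_dataset(rng):
    n, p = 40, 3
    X = rng.random((n, p))
    y = rng.choice([-1, 1], n)
    y[0], y[1] = 1, -1
    return Dataset(X, y)
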