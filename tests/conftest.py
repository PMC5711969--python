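import numpy as np
import pytest

from alseg.lattice import PM1, ZERO_ONE, AutologisticModel
from alseg.simulate import EllipseParams, GmrfSpec, generate_suite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_model(rng, r, coding, centred, lam_scale=0.6):
    return AutologisticModel(
        rng.normal(scale=0.7, size=r), float(rng.uniform(0, lam_scale)), coding, centred
    )


ALL_VARIANTS = [
    (PM1, False),
    (PM1, True),
    (ZERO_ONE, False),
    (ZERO_ONE, True),
]


@pytest.fixture(scope="session")
def tiny_suite():
    """Small 40x40 suite with strong spatial structure, 4/3/3 split."""
    return generate_suite(
        40,
        10,
        (4, 3, 3),
        EllipseParams(n_ellipses=10, max_focus_sep=0.25, axis_slack=(0.05, 0.25)),
        GmrfSpec(means=(0.75, 0.65, 0.55), sd=1.0, dependence=0.95),
        GmrfSpec(means=(0.6, 0.5, 0.7), sd=1.0, dependence=0.95),
        master_seed=7,
    )


def enumeration_conditional(probs, i, state_index, n):
    """Conditional P(z_i = high | rest) straight from the enumerated PMF.

    State k encodes pixel i's class in bit i of k, so flipping bit i moves
    between the two states that share pixel i's neighbourhood.
    """
    k_high = state_index | (1 << i)
    k_low = k_high & ~(1 << i)
    return probs[k_high] / (probs[k_high] + probs[k_low])
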