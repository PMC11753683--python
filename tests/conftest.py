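import numpy as np
import pytest

from prepost import PrePostDataset, make_fixture


@pytest.fixture
def worked_example() -> PrePostDataset:
    """The hand-checkable 4-subject dataset used throughout the suite."""
    return make_fixture("worked_example")


def random_dataset(rng: np.random.Generator, min_per_arm: int = 3) -> PrePostDataset:
    """A random two-arm dataset with a genuine pretest-posttest relation.

    Arm sizes, location/scale of the pretest, the pretest slope and the
    treatment effect all vary draw to draw, so identity tests cover
    unbalanced and badly scaled designs too.
    """
    nc = int(rng.integers(min_per_arm, 30))
    nt = int(rng.integers(min_per_arm, 30))
    treatment = np.concatenate([np.zeros(nc), np.ones(nt)])
    pre = rng.normal(rng.uniform(-50.0, 150.0), rng.uniform(0.5, 20.0), nc + nt)
    post = (
        rng.uniform(-10.0, 10.0)
        + rng.uniform(-1.5, 1.5) * pre
        + rng.uniform(-5.0, 5.0) * treatment
        + rng.normal(0.0, rng.uniform(0.1, 10.0), nc + nt)
    )
    return PrePostDataset(treatment=treatment, pretest=pre, posttest=post)
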