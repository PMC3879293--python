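import warnings

import numpy as np
import pytest

from evicomb.ds_core import Frame, MassFunction
from evicomb.synthetic_data import TriangleSpec, make_triangle_views

# MLP training emits "no validation set" warnings in a few fixtures; keep
# test output clean without hiding unexpected warnings in assertions
warnings.filterwarnings("ignore", message="no validation set")


@pytest.fixture(scope="session")
def frame_ab():
    return Frame(("a", "b"))


@pytest.fixture(scope="session")
def frame_abc():
    return Frame(("a", "b", "c"))


@pytest.fixture(scope="session")
def triangle_d10():
    """Well-separated (side 10) three-class views: negligible Bayes error."""
    return make_triangle_views(TriangleSpec(side=10.0, seed=42))


@pytest.fixture(scope="session")
def triangle_d1():
    """Heavily overlapping (side 1) three-class views: high uncertainty."""
    return make_triangle_views(TriangleSpec(side=1.0, seed=42))


def random_mass_function(rng: np.random.Generator, frame: Frame,
                         max_focals: int = 6) -> MassFunction:
    """Random normal BBA in the package representation."""
    n_sub = (1 << len(frame)) - 1
    n = int(rng.integers(1, min(max_focals, n_sub) + 1))
    masks = 1 + rng.choice(n_sub, size=n, replace=False)
    masses = rng.dirichlet(np.ones(n))
    return MassFunction(frame, {int(m): float(v) for m, v in zip(masks, masses)})
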