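import numpy as np
import pytest

from phylomorph.io_formats import FeedingType
from phylomorph.procrustes import gpa
from phylomorph.synthetic_data import GroupModel, sample_groups, template_shapes


@pytest.fixture(scope="session")
def templates():
    return template_shapes()


@pytest.fixture(scope="session")
def small_study():
    """3 x 10 specimens over 2 terminals per group, superimposed."""
    model = GroupModel(n_per_group=10, terminals_per_group=2, seed=7)
    configs, meta = sample_groups(model)
    sample = gpa(configs)
    labels = [m.feeding_type for m in meta]
    return sample, meta, labels


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_similarity(rng):
    """Random rotation + scale + translation as a function of (k,2) coords."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    scale = rng.uniform(0.2, 5.0)
    shift = rng.uniform(-50, 50, size=2)
    return lambda coords: scale * (coords @ rot.T) + shift
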