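import numpy as np
import pytest

from cgatnet import ClassSpec, PointPattern, generate_pattern


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_pattern():
    """Three collinear cells, one of each phenotype."""
    return PointPattern(
        sample_id="tiny",
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]),
        labels=("Epithelial", "CTL", "Treg"),
    )


@pytest.fixture
def clustered_pattern():
    """A mid-sized clustered sample for pipeline-level tests."""
    return generate_pattern(ClassSpec(), seed=7, sample_id="clustered")


def random_pattern(rng, n, labels=("Epithelial", "CTL", "Treg"), extent=100.0):
    """Uniform random pattern helper shared across test modules."""
    coords = rng.uniform(0.0, extent, size=(n, 2))
    labs = tuple(rng.choice(labels, size=n))
    return PointPattern(sample_id="rand", coords=coords, labels=labs)
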