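import numpy as np
import pytest

from cellnorm.data import CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 cells with one spike-in row."""
    return CountMatrix(
        np.array([[1, 2], [3, 4], [5, 6]]),
        ["geneA", "geneB", "ERCC-00001"],
        ["cell1", "cell2"],
        is_spikein=[False, False, True],
    )


@pytest.fixture
def random_counts() -> CountMatrix:
    """A modest Poisson matrix with varying depth, no spike-ins."""
    rng = np.random.default_rng(7)
    mu = rng.lognormal(1.5, 1.0, 120)
    depth = rng.uniform(0.5, 2.0, 30)
    counts = rng.poisson(mu[:, None] * depth[None, :])
    return CountMatrix(
        counts,
        [f"g{i:03d}" for i in range(120)],
        [f"c{j:02d}" for j in range(30)],
    )
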