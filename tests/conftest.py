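import numpy as np
import pytest

from omicsnmf.io import OmicsMatrix, align_samples


def make_matrix(n, p, seed=0, prefix="S", feat_prefix="f"):
    rng = np.random.default_rng(seed)
    return OmicsMatrix(
        [f"{prefix}{i}" for i in range(n)],
        [f"{feat_prefix}{j}" for j in range(p)],
        rng.uniform(0.0, 3.0, size=(n, p)),
    )


@pytest.fixture
def small_pair():
    """Source with 12 samples, target with the first 9 (3 missing)."""
    source = make_matrix(12, 5, seed=1)
    rng = np.random.default_rng(2)
    target = OmicsMatrix(
        source.sample_ids[:9],
        [f"g{j}" for j in range(4)],
        rng.uniform(0.0, 2.0, size=(9, 4)),
    )
    return align_samples(source, target)
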