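import numpy as np
import pytest

from mtkernel.kernels import MarkerMatrix, scale_markers


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def raw_markers(rng):
    """Small unscaled biallelic marker panel (J=12, p=30)."""
    codes = rng.binomial(2, rng.uniform(0.2, 0.8, size=30), size=(12, 30)).astype(float)
    return MarkerMatrix(values=codes, line_ids=[f"L{i}" for i in range(12)])


@pytest.fixture
def scaled_markers(raw_markers):
    return scale_markers(raw_markers)
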