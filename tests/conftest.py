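import numpy as np
import pytest

from cobbkit import PipelineConfig, fixture_suite


@pytest.fixture(scope="session")
def suite():
    """The deterministic 15-phantom battery (seed 0)."""
    return fixture_suite(0)


@pytest.fixture(scope="session")
def clean_cosine(suite):
    """The 12 clean C-curve recovery fixtures."""
    return [
        (spec, mask, truth)
        for spec, mask, truth in suite
        if spec.curve_form == "cosine_C" and spec.noise_sd == 0
    ]


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def strip_mask():
    """Vertical strip: rows 0-399, cols 40-59."""
    m = np.zeros((400, 100), dtype=np.uint8)
    m[:, 40:60] = 1
    return m
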