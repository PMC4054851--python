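import numpy as np
import pytest

from notimeth import datasets


@pytest.fixture(scope="session")
def hf_sites():
    return datasets.high_frequency_sites()


@pytest.fixture(scope="session")
def printed_freqs():
    return datasets.site_frequencies()


@pytest.fixture(scope="session")
def ref_matrix():
    return datasets.reference_call_matrix()


@pytest.fixture(scope="session")
def six_panel():
    return datasets.six_marker_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240522)
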