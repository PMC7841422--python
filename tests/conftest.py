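import warnings

import pytest

from vdist import load_physiology
from vdist.errors import VdistWarning


@pytest.fixture(scope="session")
def phys():
    return load_physiology("human_70kg")


@pytest.fixture(autouse=True)
def _silence_floor_warnings():
    # floor/clip warnings are expected behaviour in many sweeps; individual
    # tests that assert on warnings re-enable them locally
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", VdistWarning)
        yield
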