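import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from spiscan.serpin_annotation import load_packaged_reference
from spiscan.synthetic_data import generate_proteome


@pytest.fixture(scope="session")
def proteome():
    """Default synthetic proteome (records, truth), fixed seed."""
    return generate_proteome(seed=1)


@pytest.fixture(scope="session")
def serpin_reference():
    return load_packaged_reference()
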