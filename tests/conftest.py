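import pytest

from pacmass import build_default_database


@pytest.fixture(scope="session")
def default_db():
    """The DP 2-10 four-monomer database (996 entries), built once."""
    return build_default_database()
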