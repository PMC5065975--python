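import pytest

from hedkit import fixtures


@pytest.fixture(scope="session")
def schema():
    """The bundled mini-vocabulary."""
    return fixtures.fixture_schema()


@pytest.fixture(scope="session")
def examples():
    """The worked example annotation strings."""
    return fixtures.example_annotations()
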