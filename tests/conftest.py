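import pytest

from modori import assign_sequences, build_reference, synthetic_scaffold


@pytest.fixture(scope="session")
def scaffold():
    return synthetic_scaffold(seed=2017)


@pytest.fixture(scope="session")
def reference(scaffold):
    """Sequenced straight reference design (shared, never mutated)."""
    return assign_sequences(build_reference(), scaffold)
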