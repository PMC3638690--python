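import pytest

from uniqoligo import EstDatabase, generate_db


@pytest.fixture
def tiny_db() -> EstDatabase:
    """Two short hand-written ESTs."""
    return EstDatabase(records=[("s1", "ACGTACGT"), ("s2", "TTTTCCCC")])


@pytest.fixture
def random_db() -> EstDatabase:
    """Seeded medium database for engine-level tests."""
    return generate_db(8, (80, 150), seed=42)
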