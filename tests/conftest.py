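import pytest

from pin_architect.domains import delineate
from pin_architect.synthetic import GeneratorConfig, generate_family


@pytest.fixture(scope="session")
def family_complete():
    """Synthetic family with truncation disabled (every sequence complete)."""
    return generate_family(GeneratorConfig(seed=11, truncate=False))


@pytest.fixture(scope="session")
def family_default():
    """Synthetic family under the default (EST-truncated) conditions."""
    return generate_family(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def partitions_complete(family_complete):
    return {r.id: delineate(r) for r in family_complete.records}


@pytest.fixture(scope="session")
def partitions_default(family_default):
    return {r.id: delineate(r) for r in family_default.records}
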