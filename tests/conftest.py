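import pytest

from mcnemar import builtin_fixtures


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {f.name: f for f in builtin_fixtures()}


@pytest.fixture(scope="session")
def bentur(fixtures_by_name):
    """AHR before/after stem cell transplantation in 21 children."""
    return fixtures_by_name["bentur"].table


@pytest.fixture(scope="session")
def cavo(fixtures_by_name):
    """Complete response before/after consolidation in 161 myeloma patients."""
    return fixtures_by_name["cavo"].table
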