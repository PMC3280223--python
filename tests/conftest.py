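import pytest

from recapture.fixtures import table1_registries
from recapture.linkage import link_records


@pytest.fixture(scope="session")
def table1():
    """(hospital, police, true_links) emulating the published study counts."""
    return table1_registries()


@pytest.fixture(scope="session")
def table1_link(table1):
    hospital, police, _ = table1
    return link_records(hospital, police)
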