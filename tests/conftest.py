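import pytest

from slrpev import cluster_evolution as ce


@pytest.fixture
def history():
    return ce.default_2r_tree()


@pytest.fixture
def slrp_family():
    """The four gnathostome cluster compositions plus timing constraints."""
    return ce.canonical_slrp_family()
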