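import pytest

from dendripk import DoseSpec, make_table2_defaults


@pytest.fixture(scope="session")
def table2():
    """Reference mouse parameter set and the six conjugates, keyed by label."""
    disp, rel, linkers = make_table2_defaults()
    return disp, rel, {l.label: l for l in linkers}


@pytest.fixture()
def dose():
    return DoseSpec(10.0)
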