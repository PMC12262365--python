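import pytest

from rnatriage.simulate import ResidueParams, make_screen_fixture


@pytest.fixture(scope="session")
def screen_fixture():
    """The deterministic 40-compound synthetic screen bundle (default seed)."""
    return make_screen_fixture(seed=0)


@pytest.fixture()
def two_residues():
    return [
        ResidueParams(40, "A", "C2-H2", 7.50, 141.0, delta_h=0.08, delta_c=0.50, v0=1.0e6),
        ResidueParams(42, "C", "C6-H6", 7.62, 139.4, delta_h=0.05, delta_c=0.30, v0=8.0e5),
    ]
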