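import pytest

from soubakit import structlib
from soubakit.synthetic import (
    BUNDLE_SEED,
    SolenoidSpec,
    make_solenoid,
    make_template_complex,
    make_ub_like_domain,
)

SEED = BUNDLE_SEED


@pytest.fixture(scope="session")
def solenoid():
    """Default 7-helix synthetic solenoid with its construction truth."""
    return make_solenoid(SolenoidSpec(seed=SEED))


@pytest.fixture(scope="session")
def ub_decoy():
    return make_ub_like_domain(SEED)


@pytest.fixture(scope="session")
def template():
    return make_template_complex(SEED)


@pytest.fixture(scope="session")
def docked_model(solenoid, template):
    from soubakit.docking import dock_ubiquitins

    structure, _ = solenoid
    helices = structlib.assign_helices(structure, chain="A")
    units = structlib.decompose_overlapping_ubas(helices)
    return dock_ubiquitins(structure, units, template)
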