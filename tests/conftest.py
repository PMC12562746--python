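import numpy as np
import pytest

from tammsensor.materials import Material, default_library
from tammsensor.resonances import characterize
from tammsensor.stack import StackSpec, build_baseline


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def baseline_ag():
    return build_baseline(1.335, "Ag")


@pytest.fixture(scope="session")
def baseline_modes(baseline_ag):
    """Classified resonances of the baseline silver structure (expensive)."""
    return characterize(baseline_ag)


@pytest.fixture(scope="session")
def metal_modes():
    """Classified baseline resonances for each of the three metals."""
    return {
        metal: characterize(build_baseline(1.335, metal))
        for metal in ("Ag", "Au", "Cu")
    }


@pytest.fixture
def single_interface(lib):
    """Semi-infinite air | semi-infinite glass (n = 1.5), no finite layers."""
    return StackSpec(lib["air"], (), Material("glass15", 1.5 + 0j))


def mode_by_label(modes, label):
    found = [m for m in modes if m.label == label]
    assert found, f"no mode labelled {label}"
    return found[0]
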