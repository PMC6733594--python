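import numpy as np
import pytest

from phresh.synthetic_embryo import (PerturbationSpec, PhaseSchedule,
                                     SpinalCordGeometry, build_embryo)


@pytest.fixture(scope="session")
def geometry():
    return SpinalCordGeometry()


@pytest.fixture(scope="session")
def schedule():
    return PhaseSchedule()


@pytest.fixture(scope="session")
def small_population(geometry):
    """A coarse cell population shared by read-only tests."""
    return build_embryo(geometry, cell_spacing=5.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ly_treatment():
    return PerturbationSpec(drug="LY411575", drug_start=20.0)
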