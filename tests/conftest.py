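import numpy as np
import pytest
from hypothesis import settings

from slabdiff import DiffusionScenario, Geometry1D

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DAY = 86400.0


@pytest.fixture
def cuvette_34mm() -> Geometry1D:
    """Long cuvette gel (34 mm) used for the inward-loading experiment."""
    return Geometry1D.from_mm(34.0)


@pytest.fixture
def cuvette_20mm() -> Geometry1D:
    """Short cuvette gel (20 mm) used for the outward/internal experiments."""
    return Geometry1D.from_mm(20.0)


@pytest.fixture
def inward_scenario(cuvette_34mm) -> DiffusionScenario:
    """Inward loading at the experimentally fitted parameter point."""
    return DiffusionScenario(cuvette_34mm, "inward", 2.93e-10, n0=9.50)


@pytest.fixture
def outward_scenario(cuvette_20mm) -> DiffusionScenario:
    """Outward release at the experimentally fitted parameter point."""
    return DiffusionScenario(cuvette_20mm, "outward", 4.25e-10, C0=3.56)


@pytest.fixture
def interior_grid(cuvette_34mm) -> np.ndarray:
    return np.linspace(0.001, cuvette_34mm.length_m - 0.001, 25)
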