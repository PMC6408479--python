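import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retmech import synthgen
from retmech.grids import ImageGrid
from retmech.model import CellMask, PhotoelasticModel, SubstrateModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid128() -> ImageGrid:
    return ImageGrid(128, 128, 0.2)


@pytest.fixture(scope="session")
def optics() -> PhotoelasticModel:
    return PhotoelasticModel()


@pytest.fixture(scope="session")
def substrate() -> SubstrateModel:
    return SubstrateModel()


@pytest.fixture(scope="session")
def contractile_model(grid128):
    return synthgen.generate_cell_model(grid128, "contractile", seed=3)


@pytest.fixture(scope="session")
def contractile_mask(contractile_model, grid128):
    return CellMask(
        mask=contractile_model.mask, grid=grid128, provenance="ground_truth"
    )


@pytest.fixture(scope="session")
def clean_retardation(contractile_model, optics):
    stress = synthgen.intracellular_stress(contractile_model)
    return synthgen.forward_retardation(stress, optics)


def rel_l2(ax, ay, bx, by, where=None):
    """Relative L2 error of (ax, ay) against reference (bx, by)."""
    if where is None:
        where = np.ones(ax.shape, dtype=bool)
    num = np.sqrt(((ax - bx) ** 2 + (ay - by) ** 2)[where].sum())
    den = np.sqrt((bx**2 + by**2)[where].sum())
    return num / den
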