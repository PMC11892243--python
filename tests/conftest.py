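import numpy as np
import pytest
from hypothesis import settings

from itilscore import LayoutSpec, PlantSpec, generate_layout, plant_tils

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TSN_MAP = {"other": 0, "tumour": 1, "stroma": 2, "necrosis": 3}


@pytest.fixture(scope="session")
def small_layout():
    """A 1.5 x 1.5 mm layout with all three TSN compartments present."""
    return generate_layout(LayoutSpec(extent_um=(1536, 1536), cancer_fraction=0.6,
                                      tsn_fractions=(0.6, 0.35, 0.05), seed=42))


@pytest.fixture(scope="session")
def small_points(small_layout):
    return plant_tils(small_layout.tsn, PlantSpec(lambda_tumour=60, lambda_stroma=20, seed=43))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
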