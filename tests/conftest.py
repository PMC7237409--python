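import warnings

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import molarmorph as mm

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_small_site_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*below minimum.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def molar_template():
    """A single synthetic taxon template (no offset)."""
    return mm.make_templates(1, 0.0, seed=0)[0]


@pytest.fixture(scope="session")
def molar_outlines(molar_template):
    """Fifteen noisy specimens of one taxon."""
    gen = np.random.default_rng(11)
    return [
        mm.simulate_specimen(molar_template, 0.01, 0.001, gen, specimen_id=f"s{i}")
        for i in range(15)
    ]


@pytest.fixture(scope="session")
def training_study():
    """A 30/30/20 three-taxon training panel."""
    return mm.simulate_study(mm.training_design(seed=5))


def random_polygon(gen: np.random.Generator, n: int = 12) -> np.ndarray:
    """Simple star-shaped polygon: random radii on sorted angles."""
    th = np.sort(gen.uniform(0, 2 * np.pi, n))
    r = gen.uniform(0.5, 1.5, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])
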