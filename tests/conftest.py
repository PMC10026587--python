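import numpy as np
import pytest
from hypothesis import settings

from pimidetect import SceneSpec, VirusPlacement

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

# placements used by the end-to-end scenes: 6 interior units, mixed sides
SIX_PLACEMENTS = (
    VirusPlacement(2, 3, "top", 0.5, 0.02),
    VirusPlacement(3, 8, "bottom", 0.5, 0.02),
    VirusPlacement(4, 6, "bottom", 0.5, 0.02),
    VirusPlacement(5, 2, "top", 0.5, 0.02),
    VirusPlacement(6, 7, "bottom", 0.5, 0.02),
    VirusPlacement(7, 4, "top", 0.5, 0.02),
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def default_scene_spec():
    """10x10 array, 6 planted viruses, default noise."""
    return SceneSpec(virus_placements=SIX_PLACEMENTS, seed=7)


@pytest.fixture(scope="session")
def small_scene_spec():
    """Fast 5x5 scene with one planted virus for unit-level tests."""
    return SceneSpec(
        rows=5, cols=5, unit_px=32, pixel_size_nm=31.25, lobe_sigma_px=3.0,
        lobe_offset_px=7.0,
        virus_placements=(VirusPlacement(2, 2, "top", 0.5, 0.02),),
        seed=11,
    )
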