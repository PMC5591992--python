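import numpy as np
import pytest

from iqm_sense.iqm_chamber import ChamberModel
from iqm_sense.mlc_segments import Segment, build_library, square_segment


@pytest.fixture(scope="session")
def library() -> list[Segment]:
    return build_library()


@pytest.fixture
def square3() -> Segment:
    return square_segment(3.0, "square3")


@pytest.fixture
def square1() -> Segment:
    return square_segment(1.0, "square1")


@pytest.fixture
def chamber() -> ChamberModel:
    return ChamberModel()


@pytest.fixture
def flat_chamber() -> ChamberModel:
    """Spatially uniform response: signal must equal w0 x area exactly."""
    return ChamberModel(w0=2.0, gradient_per_cm=0.0, plateau_fraction=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_segment(rng: np.random.Generator, max_pairs: int = 12) -> Segment:
    """Small random valid segment for oracle-style comparisons."""
    n = int(rng.integers(1, max_pairs + 1))
    centers = rng.uniform(-5, 5, size=n)
    gaps = rng.uniform(0.0, 6.0, size=n)
    pairs = tuple((c - g / 2, c + g / 2) for c, g in zip(centers, gaps))
    return Segment(
        leaf_pairs=pairs,
        first_pair_offset_cm=float(-n * 0.25),
        label=f"random_{n}",
    )
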