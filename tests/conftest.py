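import numpy as np
import pytest

from fish3d.config import RunConfig
from fish3d.spots import Spot


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_spot(
    x_um: float,
    y_um: float,
    z_um: float,
    channel: str = "FITC",
    spot_id: int = 0,
    nucleus_id: int = 1,
    intensity: float = 100.0,
) -> Spot:
    """Spot at an arbitrary μm position (pixel indices are not used by
    pairing)."""
    return Spot(
        nucleus_id=nucleus_id,
        channel=channel,
        x_px=0,
        y_px=0,
        layer=0,
        position_um=(x_um, y_um, z_um),
        intensity=intensity,
        id=spot_id,
    )
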