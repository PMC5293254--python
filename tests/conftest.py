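import numpy as np
import pytest

from platescreen.plate_model import PlateFormat, PlateRead, build_primary_layout


@pytest.fixture(scope="session")
def fmt384() -> PlateFormat:
    return PlateFormat()


@pytest.fixture(scope="session")
def primary_layout(fmt384):
    return build_primary_layout(fmt384)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_plate(primary_layout) -> PlateRead:
    """Deterministic 384-well read: controls at 20000/2000 with mild spread,
    compound wells on a known gradient."""
    rng = np.random.default_rng(7)
    signals = np.empty((16, 24))
    signals[:, :2] = 20000 + rng.normal(0, 800, size=(16, 2))
    signals[:, -2:] = 2000 + rng.normal(0, 100, size=(16, 2))
    signals[:, 2:-2] = np.linspace(2000, 20000, 16 * 20).reshape(16, 20)
    return PlateRead(barcode="TOY1", signals=np.abs(signals))
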