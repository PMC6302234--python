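import numpy as np
import pytest

from pixelplex.core import MarkerMask


@pytest.fixture
def mask_factory():
    """Build a MarkerMask from explicit positive-pixel coordinates."""

    def _make(coords, shape=(8, 8), pixel_size_um=0.3, label="m"):
        px = np.zeros(shape, dtype=bool)
        for r, c in coords:
            px[r, c] = True
        return MarkerMask(pixels=px, pixel_size_um=pixel_size_um, label=label)

    return _make


@pytest.fixture
def random_mask_factory():
    """Seeded random binary masks with a given foreground density."""

    def _make(rng, shape=(64, 64), density=0.1, pixel_size_um=0.3, label="m"):
        return MarkerMask(
            pixels=rng.random(shape) < density,
            pixel_size_um=pixel_size_um,
            label=label,
        )

    return _make
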