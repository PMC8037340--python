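"""Shared phantom fixtures.  Heavy phantoms are session-scoped."""

import numpy as np
import pytest

from marginrad import PhantomSpec, ROIMask, make_phantom


@pytest.fixture(scope="session")
def sphere20():
    """Digitized r=20 sphere with noise texture on a 48^3 grid."""
    return make_phantom(
        PhantomSpec(kind="sphere", radius=20, texture="gaussian_noise", seed=11),
        grid_shape=(48, 48, 48),
    )


@pytest.fixture(scope="session")
def sphere12():
    return make_phantom(PhantomSpec(kind="sphere", radius=12, seed=0), grid_shape=(48,) * 3)


@pytest.fixture(scope="session")
def cuboid():
    """20 x 10 x 10 cuboid on a 32^3 grid."""
    return make_phantom(PhantomSpec(kind="cuboid", edges=(20, 10, 10)), grid_shape=(32,) * 3)


@pytest.fixture(scope="session")
def spiculated_set():
    """Five seeded spiculated phantoms (r=12, 8 spikes, length 6)."""
    return [
        make_phantom(
            PhantomSpec(kind="spiculated", radius=12, n_spikes=8, spike_length=6,
                        texture="gaussian_noise", seed=s),
            grid_shape=(48,) * 3,
        )
        for s in range(5)
    ]


def _slice_mask(img2d: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> ROIMask:
    """Embed a 2D binary image as the middle axial slice of a thin 3D mask."""
    data = np.zeros(img2d.shape + (3,), dtype=bool)
    data[:, :, 1] = img2d
    return ROIMask(data=data, spacing=spacing)


@pytest.fixture(scope="session")
def slice_mask():
    """Factory embedding a 2D binary image as a thin axial ROI."""
    return _slice_mask
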