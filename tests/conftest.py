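import numpy as np
import pytest

from uristrip import default_layout, render_card_template


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def card_template(layout):
    return render_card_template(layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def textured_background(rng, shape=(560, 680)):
    """Reproducible non-uniform background with plenty of texture."""
    img = rng.uniform(0.2, 0.8, size=shape + (3,))
    from scipy.ndimage import gaussian_filter
    for c in range(3):
        img[..., c] = gaussian_filter(img[..., c], 2)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)
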