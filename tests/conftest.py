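import numpy as np
import pytest

from lpbrain.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def smooth_phantom():
    """A noise-free benign phantom: smooth enough for interpolation checks."""
    img, _ = make_phantom(PhantomSpec(cls="benign", noise_sigma=0.0, seed=1))
    return img


@pytest.fixture(scope="session")
def ring_image():
    """Radially symmetric image with a smooth wide annulus profile."""
    H = W = 256
    y, x = np.mgrid[0:H, 0:W].astype(float)
    r = np.hypot(y - (H - 1) / 2, x - (W - 1) / 2)
    return 0.2 + 0.6 * np.exp(-((r - 60.0) / 30.0) ** 2)


@pytest.fixture(scope="session")
def benign_malignant_pairs():
    """Matched-seed (benign, malignant) phantom pairs for contrast checks."""
    pairs = []
    for s in range(30):
        b, _ = make_phantom(PhantomSpec(cls="benign", seed=s))
        m, _ = make_phantom(PhantomSpec(
            cls="malignant", boundary_irregularity=0.7,
            texture_heterogeneity=0.7, seed=s))
        pairs.append((b, m))
    return pairs
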