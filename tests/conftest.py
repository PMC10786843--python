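import numpy as np
import pytest

from crowdcell.synthetic import reference_tables


@pytest.fixture(scope="session")
def tables():
    """Packaged summary counts of the crowdsourced labeling experiment."""
    return reference_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disc_image(shape=(64, 64), center=(32, 32), radius=15, fg=0.2, bg=0.9):
    """Noiseless dark disc on a light background, plus its mask."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.where(mask, fg, bg).astype(float), mask


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
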