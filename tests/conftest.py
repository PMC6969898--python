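import numpy as np
import pytest

from chromablind.features import ImagePair


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def uniform_image(colour, height=8, width=8):
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.asarray(colour, dtype=np.uint8)
    return img


@pytest.fixture
def single_pixel_pair():
    """8x8 pair differing only at pixel (3, 7)."""
    a = uniform_image((120, 130, 140))
    b = a.copy()
    b[3, 7] = (200, 60, 50)
    return ImagePair(a, b, pair_id="single")


def random_pair(rng, height=8, width=8):
    a = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    b = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    return ImagePair(a, b, pair_id="random")


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)
# ---------------------------------------------------------------------------

def dct2_bruteforce(x: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II from the defining double cosine sum."""
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    out = np.zeros((n, m))
    for k in range(n):
        ak = np.sqrt(1.0 / n) if k == 0 else np.sqrt(2.0 / n)
        for l in range(m):
            al = np.sqrt(1.0 / m) if l == 0 else np.sqrt(2.0 / m)
            s = 0.0
            for i in range(n):
                for j in range(m):
                    s += (x[i, j]
                          * np.cos(np.pi * (2 * i + 1) * k / (2 * n))
                          * np.cos(np.pi * (2 * j + 1) * l / (2 * m)))
            out[k, l] = ak * al * s
    return out


def salience_imbalance_bruteforce(pair: ImagePair, mode="lab2000hl") -> float:
    """Naive count of unequal DCT-coefficient signs over the three channels."""
    from chromablind.colour import srgb_to_lab2000hl

    a = srgb_to_lab2000hl(pair.original, mode=mode)
    b = srgb_to_lab2000hl(pair.changed, mode=mode)
    n = a.shape[0] * a.shape[1]

    def signs(coef):
        # same numerical-zero rule as the implementation documents:
        # coefficients within 1e-12 (relative) of zero carry no sign
        s = np.sign(coef)
        s[np.abs(coef) <= 1e-12 * np.abs(coef).max()] = 0
        return s

    unequal = 0
    for k in range(3):
        sa = signs(dct2_bruteforce(a[:, :, k]))
        sb = signs(dct2_bruteforce(b[:, :, k]))
        unequal += int(np.sum(sa != sb))
    return unequal / (3.0 * n)
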