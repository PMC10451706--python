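import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def sobel_oracle(image: np.ndarray) -> np.ndarray:
    """Brute-force double-loop Sobel magnitude with reflect padding.

    Independent of the package's vectorised implementation: explicit loops
    over pixels and kernel taps.
    """
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    ky = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    h, w = image.shape
    out = np.zeros((h, w), dtype=float)

    def reflect(i, n):  # numpy 'reflect' (no edge repeat)
        if i < 0:
            return -i
        if i >= n:
            return 2 * n - 2 - i
        return i

    for y in range(h):
        for x in range(w):
            gx = gy = 0.0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    v = image[reflect(y + dy, h), reflect(x + dx, w)]
                    gx += kx[dy + 1][dx + 1] * v
                    gy += ky[dy + 1][dx + 1] * v
            out[y, x] = (gx**2 + gy**2) ** 0.5
    return out
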