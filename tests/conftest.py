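import numpy as np
import pytest

from orchardtrack.synthesis import GenerationParams, generate_fixture_assets


@pytest.fixture(scope="session")
def small_assets():
    """Small sprite set with a 256x256 background: fast to composite."""
    return generate_fixture_assets(seed=11, n_fruit=4, n_leaf=6, background_size=(256, 256))


@pytest.fixture
def small_params():
    """Scene parameters scaled down for unit tests."""
    return GenerationParams(
        canvas_size=(256, 256),
        fruit_size_range=(40, 60),
        leaf_size_range=(18, 28),
        n_fruits_range=(2, 4),
        n_foreground_leaves=8,
        n_background_leaves=8,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_even_odd(vertices, image_size):
    """Exhaustive point-in-polygon scan (even-odd rule, pixel centers)."""
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    n = len(vertices)
    for r in range(h):
        for c in range(w):
            px, py = c + 0.5, r + 0.5
            crossings = 0
            for i in range(n):
                x1, y1 = vertices[i]
                x2, y2 = vertices[(i + 1) % n]
                if (y1 <= py) != (y2 <= py):
                    x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < x_int:
                        crossings += 1
            mask[r, c] = crossings % 2 == 1
    return mask
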