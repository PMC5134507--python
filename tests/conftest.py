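import numpy as np
import pytest

from modicovi import pipeline, synthetic_scenes


@pytest.fixture(scope="session")
def sprite_bank():
    return synthetic_scenes.sprite_bank(rng_seed=999)


@pytest.fixture(scope="session")
def trained_model():
    """One weed model trained at the standard experiment size.

    Session-scoped: the end-to-end recovery check and the trial
    simulation share it, so the expensive training runs once.
    """
    model, _ = pipeline.train_weed_model(seed=1, n_scenes=200, iterations=2000)
    return model


def random_mosaic(rng, h=16, w=16, layout="RGGB", bit_depth=8):
    from modicovi.segmentation import BayerMosaic

    values = rng.integers(0, 2**bit_depth, size=(h, w)).astype(float)
    return BayerMosaic(values=values, layout=layout, bit_depth=bit_depth)


def exg_loop_oracle(mosaic):
    """Scalar double-loop recomputation of the mosaic excess-green index."""
    from modicovi.segmentation import _LAYOUT_GRID

    v = mosaic.values
    grid = _LAYOUT_GRID[mosaic.layout]
    h, w = v.shape
    out = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    for r in range(1, h):
        for c in range(1, w):
            greens, reds, blues = [], [], []
            for rr in (r - 1, r):
                for cc in (c - 1, c):
                    letter = grid[rr % 2][cc % 2]
                    {"G": greens, "R": reds, "B": blues}[letter].append(v[rr, cc])
            g1, g2 = greens
            (red,), (blue,) = reds, blues
            den = red + g1 / 2 + g2 / 2 + blue
            if den > 0:
                out[r, c] = (g1 + g2 - red - blue) / den
                valid[r, c] = True
    return out, valid
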