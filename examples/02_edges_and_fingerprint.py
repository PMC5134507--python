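"""Edge-pair fingerprints of monocot vs. dicot leaves.

Extracts oriented edge segments from a ribbon leaf and a lobed leaf,
enumerates nearby segment pairs and compares the fraction of
near-parallel pairs (|dtheta| < 0.2 rad) — the signature that long
straight monocot edges leave in the relative-coordinate distribution.
"""

import numpy as np

from modicovi.density_model import scene_pairs
from modicovi.pair_geometry import fingerprint
from modicovi.synthetic_scenes import compose, make_dicot, make_monocot

for name, sprites in (
    ("monocot", [make_monocot(rng_seed=i) for i in range(3)]),
    ("dicot", [make_dicot(rng_seed=i) for i in range(3)]),
):
    scene = compose(sprites, canvas_shape=(384, 384), rng_seed=5)
    pairs = scene_pairs(scene.veg_mask)
    parallel = float(np.mean(np.abs(pairs[:, 2]) < 0.2))
    fp = fingerprint(pairs, axes=("dx", "dtheta"), bins=32)
    print(f"{name:8s}: {len(pairs):6d} pairs, near-parallel fraction {parallel:.3f}, "
          f"fingerprint mass {int(fp.counts.sum())}")
# A clearly larger near-parallel fraction for the monocot scene is what
# lets the density features separate grass-like crop from broadleaf weeds.
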