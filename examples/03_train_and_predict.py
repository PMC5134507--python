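"""Train a small weed model and predict on held-out scenes.

Composes labeled training scenes from sprites, selects Gaussian density
features by random-swap search, and compares predicted vs. true weed
pixel counts on fresh scenes.  Sizes are kept small so the example runs
in well under a minute; the package defaults (450-feature pool, 20
selected) are used for real training.
"""

import numpy as np
from scipy.stats import spearmanr

from modicovi.density_model import (
    compose_training_scenes,
    predict,
    sample_feature_pool,
    select_features,
)
from modicovi.synthetic_scenes import sprite_bank

bank = sprite_bank(rng_seed=0, n_monocot=4, n_dicot=4)
train = compose_training_scenes(bank, n_scenes=40, canvas_shape=(256, 256), rng_seed=1)
pool = sample_feature_pool(n=100, rng_seed=2)
model = select_features(pool, train, k=8, iterations=800, rng_seed=3)
print(f"training MSE: {model.mse_trace[0]:.3g} -> {model.mse_trace[-1]:.3g} "
      f"over {len(model.mse_trace) - 1} accepted swaps")

test = compose_training_scenes(bank, n_scenes=12, canvas_shape=(256, 256), rng_seed=4)
preds = [predict(s.pairs, model) for s in test]
truths = [s.true_weed_pixels for s in test]
rho = spearmanr(preds, truths).statistic
for p, t in zip(preds, truths):
    print(f"  predicted {p:9.0f}   true {t:6d}")
print(f"rank correlation (predicted vs true weed pixels): {rho:.3f}")
# High rank correlation means the selected pair-density features carry
# enough information to order scenes by their dicot weed load.
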