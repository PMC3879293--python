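"""Diversity-driven feature-subspace selection.

Draws a repository of directed random feature subsets over an
8-channel x 12-bin PSD layout, trains a classifier per subset, prunes to
the top 30% by validation accuracy, and forward-selects a committee that
minimizes the inter-rater agreement kappa (lower kappa = more diversity).
"""

import numpy as np

from evicomb import MLPConfig
from evicomb.feature_selection import (block_layout, build_pool,
                                       build_repository, forward_search,
                                       interrater_agreement, prune_pool)
from evicomb.views import FeatureSpaceView

rng = np.random.default_rng(0)
# synthetic 96-dimensional features: 3 classes, informative in a few bins
n, d = 240, 96
y = np.repeat([1, 2, 3], n // 3)
X = rng.standard_normal((n, d))
for c in (1, 2, 3):
    X[y == c, (c * 17) % d] += 2.0
    X[y == c, (c * 31) % d] += 2.0
train = FeatureSpaceView(X[::2], y[::2])
val = FeatureSpaceView(X[1::2], y[1::2])

repo = build_repository(block_layout(8, 12), k_per_channel=6, n_subsets=20,
                        seed=0)
pool = build_pool(repo, train, val, MLPConfig(max_epochs=150, seed=0))
pruned = prune_pool(pool, keep_fraction=0.3)
committee = forward_search(pruned, target_size=3)

print(f"repository: {len(repo.subsets)} subsets of 48 of {d} features")
print("pool accuracies:", [f"{e.accuracy:.2f}" for e in pool.entries])
print(f"pruned to {len(pruned)}; committee (pruned-pool ids): {committee}")
kappa = interrater_agreement(pruned.correctness_matrix()[committee])
print(f"committee inter-rater kappa: {kappa:.3f}")
# The committee starts from the most accurate classifier and adds the
# candidates that disagree with it most, trading a little individual
# accuracy for complementary errors.
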