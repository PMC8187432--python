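"""Preprocess one omics view: variance filter, ANOVA preselection, scaling.

The pipeline drops near-constant features, ranks the rest by a per-feature
one-way ANOVA F statistic with Benjamini-Hochberg FDR control, keeps the
top panel, and min-max scales everything to [0, 1].  All statistics are
fitted on training rows only; `apply_preprocess` replays the fitted map on
held-out samples (with clipping to [0, 1]).
"""

import mogonet as mg
from mogonet.preprocess import apply_preprocess, fit_preprocess

data, _ = mg.generate_complementary_trio(
    n=150, c=3, seed=0, n_features=60, n_informative=8
)
view = data.views[0]
labels = data.labels

train_ids = data.sample_ids[:100]
test_ids = data.sample_ids[100:]

processed, spec = fit_preprocess(
    view.subset_samples(train_ids), labels.subset(train_ids),
    variance_threshold=0.001, n_keep=20,
)
print(f"kept {processed.n_features} of {view.n_features} features")
print(f"training values in [{processed.values.min():.2f}, "
      f"{processed.values.max():.2f}]")

held_out = apply_preprocess(view.subset_samples(test_ids), spec)
print(f"held-out panel matches: {held_out.feature_names == spec.feature_names}")

# choose_feature_count picks a preselection size from a grid, enlarging the
# panel until its first principal component explains < 50% of the variance
count = mg.choose_feature_count(view.subset_samples(train_ids),
                                labels.subset(train_ids), [10, 20, 40])
print(f"chosen panel size: {count}")
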