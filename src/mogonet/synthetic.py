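"""Synthetic multi-omics data with planted class signal.

The generator emulates the data regime the classifier targets: m omics
views measured on the same samples, a handful of informative features per
view whose class-conditional means are shifted, the rest pure noise, and
optional class imbalance.  Class-conditional Gaussians are used so the
Bayes-optimal error of the generative model is computable, which makes the
generator usable as an oracle in tests.

View complementarity is controlled by a per-view set of "marked" classes:
a view's informative features are shifted only for the classes that view
separates, so no single view need suffice for all classes.  The
``generate_complementary_trio`` fixture marks one class per view, the
regime where integrating all three views is provably better than any
single view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .datatypes import LabelVector, MultiOmicsDataset, OmicsView

__all__ = ["SyntheticSpec", "generate", "generate_complementary_trio"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic multi-omics dataset."""

    n_samples: int = 300
    n_classes: int = 3
    proportions: list[float] | None = None  # None -> balanced
    n_views: int = 3
    n_features: list[int] | int = 200  # per view, or one value for all
    n_informative: list[int] | int = 10
    effect_size: float = 1.0  # class-mean shift in units of noise sd
    noise_sd: float = 1.0
    view_classes: list[list[int]] | None = None  # classes each view separates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportions is None:
            self.proportions = [1.0 / self.n_classes] * self.n_classes
        if len(self.proportions) != self.n_classes:
            raise ValueError("proportions length must equal n_classes")
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("proportions must sum to 1")
        if any(p <= 0 for p in self.proportions):
            raise ValueError("proportions must be positive")
        if isinstance(self.n_features, int):
            self.n_features = [self.n_features] * self.n_views
        if isinstance(self.n_informative, int):
            self.n_informative = [self.n_informative] * self.n_views
        for d, ni in zip(self.n_features, self.n_informative):
            if ni > d:
                raise ValueError("n_informative exceeds n_features")
        if self.view_classes is None:
            self.view_classes = [list(range(self.n_classes))] * self.n_views


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Labels with counts matching the proportions as closely as possible."""
    counts = np.floor(np.asarray(spec.proportions) * spec.n_samples).astype(int)
    counts[counts == 0] = 1
    remainder = spec.n_samples - counts.sum()
    if remainder > 0:
        frac = np.asarray(spec.proportions) * spec.n_samples - counts
        for cls in np.argsort(-frac)[:remainder]:
            counts[cls] += 1
    elif remainder < 0:
        for cls in np.argsort(-counts)[: -remainder]:
            counts[cls] -= 1
    labels = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels)
    return labels


def _minmax01(X: np.ndarray) -> np.ndarray:
    mins = X.min(axis=0)
    span = X.max(axis=0) - mins
    span[span == 0] = 1.0
    return (X - mins) / span


def generate(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, dict[str, list[str]]]:
    """Generate a dataset and the ground-truth planted features per view.

    Informative features occupy the first columns of each view; each marked
    class gets its own random sign pattern over them, scaled by
    ``effect_size * noise_sd``.  All values are min-max mapped to [0, 1].
    Fully determined by ``spec.seed``.
    """
    labels = _draw_labels(spec, substream(spec.seed, "synthetic/labels"))
    sample_ids = [f"s{i:04d}" for i in range(spec.n_samples)]
    views: list[OmicsView] = []
    truth: dict[str, list[str]] = {}
    for v in range(spec.n_views):
        d = spec.n_features[v]
        ni = spec.n_informative[v]
        name = f"view{v}"
        rng = substream(spec.seed, f"synthetic/{name}")
        X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, d))
        shift = np.zeros((spec.n_classes, ni))
        for cls in spec.view_classes[v]:
            pattern = rng.choice([-1.0, 1.0], size=ni)
            shift[cls] = spec.effect_size * spec.noise_sd * pattern
        X[:, :ni] += shift[labels]
        X = _minmax01(X)
        feature_names = [f"{name}_f{j:04d}" for j in range(d)]
        views.append(OmicsView(name, sample_ids, feature_names, X))
        truth[name] = feature_names[:ni]
    lv = LabelVector(sample_ids, labels, n_classes=spec.n_classes)
    return MultiOmicsDataset(views, lv), truth


def generate_complementary_trio(
    n: int = 300,
    c: int = 3,
    seed: int = 0,
    n_features: int = 200,
    n_informative: int = 10,
    effect_size: float = 1.0,
) -> tuple[MultiOmicsDataset, dict[str, list[str]]]:
    """Three views, view i informative only for class i (vs the rest).

    No single view can distinguish the unmarked classes, so any single-view
    classifier's accuracy is bounded away from 1 while the three views
    jointly identify every class — the regime where multi-omics integration
    pays off.  Requires c >= 3 (one marked class per view).
    """
    if c < 3:
        raise ValueError("the complementary trio needs at least 3 classes")
    spec = SyntheticSpec(
        n_samples=n,
        n_classes=c,
        n_views=3,
        n_features=n_features,
        n_informative=n_informative,
        effect_size=effect_size,
        view_classes=[[i] for i in range(3)],
        seed=seed,
    )
    return generate(spec)
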