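"""Core data containers shared across the pipeline.

An :class:`OmicsView` is one data modality (e.g. mRNA expression, DNA
methylation, miRNA expression) measured on a common set of samples; a
:class:`MultiOmicsDataset` bundles several views aligned to one canonical
sample order together with the class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OmicsView", "LabelVector", "MultiOmicsDataset"]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class OmicsView:
    """One omics data type: an n-samples x d-features real matrix with names."""

    name: str
    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_names, "feature")
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.feature_names):
            raise ValueError(
                f"view {self.name!r}: matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if n < 2:
            raise ValueError(f"view {self.name!r}: need at least 2 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"view {self.name!r}: non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids: list[str]) -> "OmicsView":
        """Restrict to the given sample IDs, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return OmicsView(self.name, list(ids), list(self.feature_names), self.values[idx])

    def subset_features(self, index: np.ndarray) -> "OmicsView":
        """Restrict to the feature columns selected by ``index`` (order kept)."""
        index = np.asarray(index)
        names = [self.feature_names[i] for i in index]
        return OmicsView(self.name, list(self.sample_ids), names, self.values[:, index])

    def with_values(self, values: np.ndarray) -> "OmicsView":
        return OmicsView(self.name, list(self.sample_ids), list(self.feature_names), values)


@dataclass
class LabelVector:
    """Integer class labels in [0, c) for an ordered set of samples.

    Arbitrary original labels (e.g. subtype names) are mapped to contiguous
    integers via ``classes_``, which persists the mapping so that predictions
    can be reported in the original vocabulary.
    """

    sample_ids: list[str]
    labels: np.ndarray
    n_classes: int
    classes_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != self.labels.shape[0]:
            raise ValueError("sample_ids and labels length mismatch")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError(f"labels must lie in [0, {self.n_classes})")
        if not self.classes_:
            self.classes_ = [str(i) for i in range(self.n_classes)]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def one_hot(self) -> np.ndarray:
        out = np.zeros((self.n_samples, self.n_classes))
        out[np.arange(self.n_samples), self.labels] = 1.0
        return out

    def subset(self, ids: list[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return LabelVector(list(ids), self.labels[idx], self.n_classes, list(self.classes_))

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class MultiOmicsDataset:
    """Several omics views aligned to one canonical sample order, plus labels."""

    views: list[OmicsView]
    labels: LabelVector

    def __post_init__(self) -> None:
        ids = self.labels.sample_ids
        for v in self.views:
            if v.sample_ids != ids:
                raise ValueError(f"view {v.name!r} sample order differs from labels")

    @property
    def m(self) -> int:
        return len(self.views)

    @property
    def n_samples(self) -> int:
        return self.labels.n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    def subset(self, ids: list[str]) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            [v.subset_samples(ids) for v in self.views], self.labels.subset(ids)
        )
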