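"""Per-omics preprocessing, fitted on training samples only.

Three stages, applied independently per omics view:

1. noise filtering — features with zero mean (no signal) or population
   variance below a view-specific threshold are dropped (e.g. 0.1 for
   mRNA-like data, 0.001 for methylation-like beta values, 0 for small
   miRNA panels);
2. supervised preselection — a one-way ANOVA F statistic per feature across
   classes, Benjamini-Hochberg adjusted; the strongest features with
   adjusted p below alpha are kept, the count either fixed or chosen as the
   smallest candidate for which the first principal component of the
   selected training submatrix explains less than half the variance (too
   few features tend to be mutually correlated, which the PC1 rule detects);
3. linear scaling of every surviving feature to [0, 1] using training
   min/max; test values are transformed with the same map and clipped.

The [0,1] range matters downstream: zeroing a scaled feature removes its
signal, which is what the ablation-based biomarker ranking relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import f_classif
from statsmodels.stats.multitest import multipletests

from .datatypes import LabelVector, OmicsView

__all__ = [
    "variance_filter",
    "anova_preselect",
    "choose_feature_count",
    "minmax_scale",
    "PreprocessSpec",
    "fit_preprocess",
    "apply_preprocess",
]


def variance_filter(view: OmicsView, threshold: float) -> OmicsView:
    """Drop features with zero mean or population variance below threshold."""
    if threshold < 0:
        raise ValueError("variance threshold must be nonnegative")
    mean = view.values.mean(axis=0)
    var = view.values.var(axis=0)  # population variance (divide by n)
    # threshold 0 still removes constant (zero-variance) features
    keep = (mean != 0) & (var >= threshold) & (var > 0)
    if not keep.any():
        raise ValueError(
            f"view {view.name!r}: variance filter at {threshold} removed every "
            "feature; lower the threshold"
        )
    return view.subset_features(np.where(keep)[0])


def _anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(labels)
    if counts.size < 2 or (counts > 0).sum() < 2:
        raise ValueError("ANOVA preselection needs at least 2 classes")
    if np.any(counts[counts > 0] < 2):
        raise ValueError("every class needs at least 2 samples for ANOVA")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features emit invalid-value noise
        F, p = f_classif(values, labels)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    p = np.where(np.isnan(p), 1.0, p)
    return F, p


def anova_preselect(
    view: OmicsView,
    labels: LabelVector,
    n_keep: int,
    fdr_alpha: float = 0.05,
) -> tuple[OmicsView, np.ndarray, np.ndarray]:
    """Keep the n_keep features with largest ANOVA F among FDR-significant ones.

    Returns the reduced view plus the per-feature F statistics and
    Benjamini-Hochberg adjusted p-values (for all input features).  If fewer
    than n_keep features reach adjusted p < alpha, all significant ones are
    kept with a warning.
    """
    if n_keep > view.n_features:
        raise ValueError(
            f"n_keep={n_keep} exceeds available features ({view.n_features})"
        )
    F, p = _anova_f(view.values, labels.labels)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    significant = np.where(p_adj < fdr_alpha)[0]
    if len(significant) < n_keep:
        warnings.warn(
            f"view {view.name!r}: only {len(significant)} features pass "
            f"FDR<{fdr_alpha}; keeping those instead of {n_keep}",
            stacklevel=2,
        )
        chosen = significant
    else:
        order = significant[np.argsort(-F[significant], kind="stable")]
        chosen = order[:n_keep]
    if chosen.size == 0:
        raise ValueError(f"view {view.name!r}: no feature passes FDR<{fdr_alpha}")
    chosen = np.sort(chosen)  # preserve original feature order
    return view.subset_features(chosen), F, p_adj


def _pc1_fraction(values: np.ndarray) -> float:
    centered = values - values.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    total = (s**2).sum()
    return float(s[0] ** 2 / total) if total > 0 else 1.0


def choose_feature_count(
    view: OmicsView,
    labels: LabelVector,
    candidates: list[int],
    fdr_alpha: float = 0.05,
    pc1_max_fraction: float = 0.5,
) -> int:
    """Smallest candidate count whose selected submatrix has a diffuse PC1.

    Evaluates candidates in ascending order and returns the first for which
    the first principal component of the preselected (mean-centered,
    unscaled) training submatrix explains less than ``pc1_max_fraction`` of
    the variance; falls back to the largest candidate with a warning.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    usable = sorted(c for c in candidates if c <= view.n_features)
    if not usable:
        usable = [view.n_features]
    for count in usable:
        selected, _, _ = anova_preselect(view, labels, count, fdr_alpha)
        if _pc1_fraction(selected.values) < pc1_max_fraction:
            return count
    warnings.warn(
        f"view {view.name!r}: PC1 explains >= {pc1_max_fraction:.0%} of variance "
        "at every candidate count; using the largest",
        stacklevel=2,
    )
    return usable[-1]


@dataclass
class PreprocessSpec:
    """Fitted preprocessing state for one view: kept features and scaling."""

    view_name: str
    feature_names: list[str] = field(default_factory=list)
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    variance_threshold: float = 0.0
    n_preselected: int = 0


def minmax_scale(
    view: OmicsView, fitted: PreprocessSpec | None = None
) -> tuple[OmicsView, PreprocessSpec]:
    """Scale each feature linearly to [0, 1].

    Without a fitted spec, min/max are taken from this (training) view and
    constant features map to 0.  With a fitted spec the training transform
    is reused and outputs are clipped to [0, 1].
    """
    if fitted is None:
        mins = view.values.min(axis=0)
        maxs = view.values.max(axis=0)
        fitted = PreprocessSpec(
            view_name=view.name,
            feature_names=list(view.feature_names),
            mins=mins,
            maxs=maxs,
        )
        clip = False
    else:
        if fitted.feature_names != view.feature_names:
            raise ValueError(
                f"view {view.name!r}: feature set differs from the fitted spec"
            )
        mins, maxs = fitted.mins, fitted.maxs
        clip = True
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (view.values - mins) / safe
    scaled[:, span == 0] = 0.0
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return view.with_values(scaled), fitted


def fit_preprocess(
    view: OmicsView,
    labels: LabelVector,
    variance_threshold: float = 0.0,
    n_keep: int | str = "auto",
    candidates: list[int] | None = None,
    fdr_alpha: float = 0.05,
    pc1_max_fraction: float = 0.5,
    whitelist: set[str] | None = None,
) -> tuple[OmicsView, PreprocessSpec]:
    """Fit the full pipeline on training data and return the processed view.

    ``whitelist`` optionally restricts the view to a fixed feature panel
    (e.g. an assay's probe set) before any statistics are computed.
    """
    if whitelist is not None:
        idx = [i for i, f in enumerate(view.feature_names) if f in whitelist]
        if not idx:
            raise ValueError(f"view {view.name!r}: whitelist removed every feature")
        view = view.subset_features(np.array(idx))
    filtered = variance_filter(view, variance_threshold)
    if n_keep == "all":
        selected = filtered  # keep every variance-surviving feature
    else:
        if n_keep == "auto":
            grid = candidates or [200, 1000, 2000]
            n_keep = choose_feature_count(
                filtered, labels, grid, fdr_alpha, pc1_max_fraction
            )
        n_keep = min(int(n_keep), filtered.n_features)
        selected, _, _ = anova_preselect(filtered, labels, n_keep, fdr_alpha)
    scaled, spec = minmax_scale(selected)
    spec.variance_threshold = variance_threshold
    spec.n_preselected = selected.n_features
    return scaled, spec


def apply_preprocess(view: OmicsView, spec: PreprocessSpec) -> OmicsView:
    """Apply a fitted spec to new samples of the same view."""
    pos = {f: i for i, f in enumerate(view.feature_names)}
    missing = [f for f in spec.feature_names if f not in pos]
    if missing:
        raise ValueError(
            f"view {view.name!r}: {len(missing)} fitted features absent "
            f"(first: {missing[0]!r})"
        )
    subset = view.subset_features(np.array([pos[f] for f in spec.feature_names]))
    scaled, _ = minmax_scale(subset, spec)
    return scaled
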