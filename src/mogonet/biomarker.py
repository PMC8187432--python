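"""Ablation-based biomarker ranking.

Because inputs are scaled to [0, 1], setting a feature's column to zero
removes its signal; a feature's importance is the drop in test-set
classification performance (F1 for binary tasks, macro-averaged F1 for
multi-class tasks) when its test values are zeroed, with the trained model
left untouched.  Randomness in training is averaged out by repeating the
experiment over independent train/test splits and summing the drops.
Because every omics type carries equal weight in the integration head while
different numbers of features were preselected per type, the summed drop is
scaled by the view's preselected feature count before the global ranking.

By default the ablated feature also enters the recomputation of the test
sample's similarity row, since the graph is part of the prediction path; a
``recompute_graph=False`` flag freezes the graph for comparison.  Only the
test rows are zeroed — the fitted training graph is never altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .datatypes import MultiOmicsDataset, OmicsView
from .preprocess import apply_preprocess
from .train import TrainedModel, _integrate, _view_test_probs

__all__ = ["zero_column", "feature_importance", "aggregate_importance", "rank_biomarkers"]


def zero_column(view: OmicsView, feature: str) -> OmicsView:
    """Copy of the view with one feature column zeroed; the input is untouched."""
    try:
        j = view.feature_names.index(feature)
    except ValueError:
        raise KeyError(f"feature {feature!r} not in view {view.name!r}") from None
    values = view.values.copy()
    values[:, j] = 0.0
    return view.with_values(values)


def _metric(y_true: np.ndarray, proba: np.ndarray, metric: str) -> float:
    y_pred = np.argmax(proba, axis=1)
    if metric == "F1":
        return float(f1_score(y_true, y_pred))
    if metric == "F1_macro":
        return float(f1_score(y_true, y_pred, average="macro"))
    raise ValueError("metric must be 'F1' or 'F1_macro'")


def feature_importance(
    model: TrainedModel,
    test_data: MultiOmicsDataset,
    metric: str | None = None,
    recompute_graph: bool = True,
    preprocess: bool = True,
) -> pd.DataFrame:
    """One repeat of zero-ablation importance for every preselected feature.

    Returns a table of (view, feature, importance) where importance is the
    baseline-minus-ablated test metric.  Negative values (ablation helped)
    are kept.  The default metric follows the task: F1 for two classes,
    F1_macro otherwise.  With ``preprocess=False`` the views are taken
    as-is and must already lie in [0, 1] (zeroing only removes signal on
    bounded inputs).
    """
    if metric is None:
        metric = "F1" if model.n_classes == 2 else "F1_macro"
    if preprocess:
        matrices = [
            apply_preprocess(v, spec).values
            for v, spec in zip(test_data.views, model.specs)
        ]
    else:
        matrices = [np.asarray(v.values, dtype=float) for v in test_data.views]
    for name, X in zip(model.view_names, matrices):
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError(
                f"view {name!r}: test inputs must be scaled to [0, 1] before ablation"
            )
    y_true = test_data.labels.labels
    base_view_probs = [
        _view_test_probs(model, i, X) for i, X in enumerate(matrices)
    ]
    baseline = _metric(y_true, _integrate(model, base_view_probs), metric)

    rows = []
    for vi, (name, X) in enumerate(zip(model.view_names, matrices)):
        feature_names = model.specs[vi].feature_names
        for j, feat in enumerate(feature_names):
            if not np.any(X[:, j]):  # already all-zero: ablation changes nothing
                rows.append({"view": name, "feature": feat, "importance": 0.0})
                continue
            X_abl = X.copy()
            X_abl[:, j] = 0.0
            if recompute_graph:
                probs_vi = _view_test_probs(model, vi, X_abl)
            else:
                # freeze the similarity rows: forward with original graph but
                # ablated node features
                probs_vi = _frozen_graph_probs(model, vi, X, X_abl)
            view_probs = list(base_view_probs)
            view_probs[vi] = probs_vi
            drop = baseline - _metric(y_true, _integrate(model, view_probs), metric)
            rows.append({"view": name, "feature": feat, "importance": drop})
    return pd.DataFrame(rows)


def _frozen_graph_probs(
    model: TrainedModel, vi: int, X_orig: np.ndarray, X_abl: np.ndarray
) -> np.ndarray:
    """Forward the ablated features through the un-ablated extended graph."""
    from .autodiff import softmax
    from .graph import extend_for_test

    X_tr = model.train_matrices[vi]
    g = model.graphs[vi]
    n_tr = X_tr.shape[0]
    eps = np.inf if g is None else g.epsilon
    A_tr = np.zeros((n_tr, n_tr)) if g is None else g.A
    A_ext = extend_for_test(X_tr, X_orig, eps, A_tr=A_tr)
    # only the test rows are zeroed; the fitted training block is untouched
    X_stack = np.empty((X_abl.shape[0], n_tr + 1, X_tr.shape[1]))
    X_stack[:, :n_tr, :] = X_tr
    X_stack[:, n_tr, :] = X_abl
    logits = model.gcns[vi].forward_numpy(X_stack, A_ext)
    return softmax(logits[:, n_tr, :])


def aggregate_importance(
    tables: list[pd.DataFrame], preselect_counts: dict[str, int]
) -> pd.DataFrame:
    """Sum drops over repeats, scale by each view's preselected feature count,
    and rank all features globally (descending; ties by view order then name)."""
    if not tables:
        raise ValueError("no importance tables to aggregate")
    ref = tables[0][["view", "feature"]]
    for t in tables[1:]:
        if not ref.equals(t[["view", "feature"]].reset_index(drop=True)):
            raise ValueError("importance tables cover different feature sets")
    combined = pd.concat(tables, ignore_index=True)
    summed = (
        combined.groupby(["view", "feature"], sort=False)["importance"]
        .sum()
        .reset_index()
    )
    summed["scaled_importance"] = summed.apply(
        lambda r: r["importance"] * preselect_counts[r["view"]], axis=1
    )
    view_order = {v: i for i, v in enumerate(ref["view"].drop_duplicates())}
    summed["_vo"] = summed["view"].map(view_order)
    summed = summed.sort_values(
        by=["scaled_importance", "_vo", "feature"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="_vo")
    summed["rank"] = np.arange(1, len(summed) + 1)
    return summed.reset_index(drop=True)


def rank_biomarkers(
    data: MultiOmicsDataset,
    config,
    variant: str = "mogonet",
    n_repeats: int = 5,
    metric: str | None = None,
    preprocess: bool = True,
    top: int | None = None,
) -> pd.DataFrame:
    """Full biomarker pipeline: repeated splits, per-repeat ablation, ranking.

    Each repeat re-trains the model on a fresh stratified split (the same
    split stream as the evaluation protocol) and ablates on that repeat's
    test set; drops are summed over repeats and scaled per view.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    from ._rng import substream
    from .train import fit

    seed = int(substream(config.seed, "split").integers(2**31))
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=config.test_fraction, random_state=seed
    )
    ids = np.array(data.sample_ids)
    tables = []
    counts: dict[str, int] = {}
    for tr_idx, te_idx in sss.split(ids, data.labels.labels):
        train = data.subset(list(ids[tr_idx]))
        test = data.subset(list(ids[te_idx]))
        model = fit(train, config, variant=variant, preprocess=preprocess)
        tables.append(feature_importance(model, test, metric=metric))
        counts = {
            name: len(spec.feature_names)
            for name, spec in zip(model.view_names, model.specs)
        }
    table = aggregate_importance(tables, counts)
    return table.head(top) if top else table
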