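"""End-to-end training, transductive prediction, and evaluation.

Training follows the published recipe: each omics view's GCN is first
pretrained alone on class-weighted cross-entropy, then all networks are
optimised jointly on the total loss

    L = sum_i L_GCN^(i) + gamma * L_VCDN,   gamma = 1 by default,

alternating within every epoch — the integration head is held fixed while
the GCNs step against L, then the GCNs are held fixed while the head steps.
Optimisation is full-batch adaptive-moment gradient descent (the
transductive graphs preclude mini-batching).

Prediction of new samples is transductive: each test sample is appended to
every view's training similarity graph, the extended renormalized adjacency
is computed with the training threshold, the GCNs are run on the extended
graph, and the test rows' probability rows are fused by the integration
head.  The graph-density parameter ``k`` can be tuned by stratified
cross-validation on the training data.

Four model variants share this machinery:

==========   ===============   =================
variant      per-view model    integration head
==========   ===============   =================
mogonet      GCN on graph      cross-omics tensor (VCDN)
mogonet_nn   GCN on graph      concatenation
nn_vcdn      identity graph    cross-omics tensor (VCDN)
nn_nn        identity graph    concatenation
==========   ===============   =================

With ``k = 1`` the similarity graphs are edgeless, the GCNs collapse to
fully connected networks, and ``mogonet`` coincides with ``nn_vcdn``
prediction for prediction.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from ._rng import substream
from .autodiff import Adam, Tensor, log_softmax, softmax
from .config import RunConfig
from .datatypes import LabelVector, MultiOmicsDataset
from .graph import SimilarityGraph, build_graph, extend_for_test
from .networks import GCNModel, VCDNModel, class_weights, weighted_cross_entropy
from .preprocess import PreprocessSpec, apply_preprocess, fit_preprocess

__all__ = [
    "TrainedModel",
    "MetricsReport",
    "VARIANTS",
    "fit",
    "pretrain_gcns",
    "train_joint",
    "predict",
    "predict_proba",
    "tune_k",
    "evaluate",
    "repeated_splits",
    "save_model",
    "load_model",
]

VARIANTS = ("mogonet", "mogonet_nn", "nn_vcdn", "nn_nn")


@dataclass
class TrainedModel:
    """A fitted multi-omics classifier with everything prediction needs."""

    variant: str
    gcns: list[GCNModel]
    head: VCDNModel | None
    graphs: list[SimilarityGraph | None]  # None for identity-graph variants
    specs: list[PreprocessSpec]
    config: RunConfig
    train_matrices: list[np.ndarray]  # preprocessed, one per view
    view_names: list[str]
    n_classes: int
    classes_: list[str]
    class_weights_: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    pretrain_traces: list[list[float]] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.gcns)

    @property
    def uses_graph(self) -> bool:
        return self.variant in ("mogonet", "mogonet_nn")

    @property
    def integration(self) -> str:
        return "vcdn" if self.variant in ("mogonet", "nn_vcdn") else "concat"


@dataclass
class MetricsReport:
    """Evaluation metrics, optionally aggregated as mean +/- sd over repeats."""

    metrics: dict[str, float]
    sd: dict[str, float] | None = None
    per_repeat: list[dict[str, float]] | None = None


# --------------------------------------------------------------------------
# differentiable helpers
# --------------------------------------------------------------------------


def _tensor_input(prob_tensors: list[Tensor]) -> Tensor:
    """Differentiable flattened outer product of per-view probability rows
    (first view slowest-varying)."""
    z = prob_tensors[0]
    n = z.shape[0]
    for y in prob_tensors[1:]:
        c = y.shape[1]
        z = z.reshape(n, -1, 1) * y.reshape(n, 1, c)
        z = z.reshape(n, -1)
    return z


def _concat_input(prob_tensors: list[Tensor]) -> Tensor:
    """Differentiable concatenation along the class axis via block matmuls."""
    n = prob_tensors[0].shape[0]
    widths = [p.shape[1] for p in prob_tensors]
    total = sum(widths)
    out = None
    offset = 0
    for p, w in zip(prob_tensors, widths):
        pad = np.zeros((w, total))
        pad[:, offset : offset + w] = np.eye(w)
        block = p @ Tensor(pad)
        out = block if out is None else out + block
        offset += w
    return out


def _probs(logits: Tensor) -> Tensor:
    return log_softmax(logits).exp()


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


def _build_view_graphs(
    matrices: list[np.ndarray], k: int, use_graph: bool
) -> tuple[list[SimilarityGraph | None], list[np.ndarray]]:
    graphs: list[SimilarityGraph | None] = []
    adjacencies: list[np.ndarray] = []
    for X in matrices:
        if use_graph:
            g = build_graph(X, k)
            graphs.append(g)
            adjacencies.append(g.A_tilde)
        else:
            graphs.append(None)
            adjacencies.append(np.eye(X.shape[0]))
    return graphs, adjacencies


def pretrain_gcns(
    matrices: list[np.ndarray],
    adjacencies: list[np.ndarray],
    labels: np.ndarray,
    n_classes: int,
    view_names: list[str],
    config: RunConfig,
) -> tuple[list[GCNModel], list[np.random.Generator], list[list[float]]]:
    """Train each view's GCN alone on class-weighted cross-entropy.

    Returns the models, the (partially consumed) dropout streams so joint
    training continues them, and the per-view loss traces.
    """
    weights = class_weights(labels, n_classes)
    gcns: list[GCNModel] = []
    dropout_rngs: list[np.random.Generator] = []
    traces: list[list[float]] = []
    for X, A, name in zip(matrices, adjacencies, view_names):
        init_rng = substream(config.seed, f"init/gcn/{name}")
        gcn = GCNModel(
            X.shape[1],
            list(config.gcn_hidden),
            n_classes,
            init_rng,
            slope=config.activation_slope,
            dropout=config.dropout,
        )
        drop_rng = substream(config.seed, f"dropout/{name}")
        opt = Adam(gcn.parameters(), lr=config.lr_pretrain)
        trace: list[float] = []
        for _ in range(config.pretrain_epochs):
            logits = gcn.forward(X, A, training=True, rng=drop_rng)
            loss = weighted_cross_entropy(logits, labels, weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite pretraining loss for view {name!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
        gcns.append(gcn)
        dropout_rngs.append(drop_rng)
        traces.append(trace)
    return gcns, dropout_rngs, traces


def train_joint(
    matrices: list[np.ndarray],
    adjacencies: list[np.ndarray],
    labels: np.ndarray,
    n_classes: int,
    gcns: list[GCNModel],
    dropout_rngs: list[np.random.Generator],
    config: RunConfig,
) -> tuple[VCDNModel | None, list[float]]:
    """Alternating joint optimisation of the total loss; returns the head."""
    m = len(gcns)
    weights = class_weights(labels, n_classes)
    head: VCDNModel | None = None
    if m > 1:
        in_dim = n_classes**m if config.integration_mode == "vcdn" else m * n_classes
        head = VCDNModel(
            in_dim,
            n_classes,
            substream(config.seed, "init/head"),
            hidden=config.vcdn_hidden,
            slope=config.activation_slope,
        )
    gcn_params = [p for g in gcns for p in g.parameters()]
    opt_gcn = Adam(gcn_params, lr=config.lr_gcn)
    opt_head = Adam(head.parameters(), lr=config.lr_vcdn) if head else None

    def total_loss() -> Tensor:
        per_view = [
            g.forward(X, A, training=True, rng=rng)
            for g, X, A, rng in zip(gcns, matrices, adjacencies, dropout_rngs)
        ]
        loss = None
        for logits in per_view:
            term = weighted_cross_entropy(logits, labels, weights)
            loss = term if loss is None else loss + term
        if head is not None:
            prob_rows = [_probs(l) for l in per_view]
            x = (
                _tensor_input(prob_rows)
                if config.integration_mode == "vcdn"
                else _concat_input(prob_rows)
            )
            loss = loss + config.gamma * weighted_cross_entropy(
                head.forward(x), labels, weights
            )
        return loss

    trace: list[float] = []
    for epoch in range(config.joint_epochs):
        # (a) head fixed, GCNs step against the total loss
        loss = total_loss()
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"joint loss diverged at epoch {epoch}")
        opt_gcn.zero_grad()
        if opt_head:
            opt_head.zero_grad()
        loss.backward()
        opt_gcn.step()
        # (b) GCNs fixed, head steps against the (recomputed) total loss
        if opt_head:
            loss = total_loss()
            opt_gcn.zero_grad()
            opt_head.zero_grad()
            loss.backward()
            opt_head.step()
        trace.append(float(loss.data))
        if (
            config.loss_tol > 0
            and len(trace) > config.patience
            and abs(trace[-1 - config.patience] - trace[-1])
            < config.loss_tol * max(abs(trace[-1 - config.patience]), 1e-12)
        ):
            break
    return head, trace


def fit(
    train_data: MultiOmicsDataset,
    config: RunConfig,
    variant: str = "mogonet",
    preprocess: bool = True,
) -> TrainedModel:
    """Fit preprocessing, graphs, GCNs and the integration head on training data.

    With ``preprocess=False`` the views are assumed already filtered and
    scaled to [0, 1] and are only min-max refitted (a no-op on [0,1] data
    spanning the range).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    cfg = config.replace(
        integration_mode="vcdn" if variant in ("mogonet", "nn_vcdn") else "concat"
    )
    labels = train_data.labels
    matrices: list[np.ndarray] = []
    specs: list[PreprocessSpec] = []
    for view in train_data.views:
        if preprocess:
            processed, spec = fit_preprocess(
                view,
                labels,
                variance_threshold=cfg.variance_thresholds.get(view.name, 0.0),
                n_keep=cfg.preselect_counts.get(view.name, "all"),
                candidates=cfg.preselect_grid,
                fdr_alpha=cfg.fdr_alpha,
                pc1_max_fraction=cfg.pc1_max_fraction,
            )
        else:
            from .preprocess import minmax_scale

            processed, spec = minmax_scale(view)
        matrices.append(processed.values)
        specs.append(spec)

    use_graph = variant in ("mogonet", "mogonet_nn")
    k = cfg.k
    if k == "auto":
        k = tune_k(train_data, cfg, variant=variant, preprocess=preprocess)
        cfg = cfg.replace(k=k)
    graphs, adjacencies = _build_view_graphs(matrices, int(k) if use_graph else 1, use_graph)

    view_names = [v.name for v in train_data.views]
    gcns, drop_rngs, pretraces = pretrain_gcns(
        matrices, adjacencies, labels.labels, labels.n_classes, view_names, cfg
    )
    head, trace = train_joint(
        matrices, adjacencies, labels.labels, labels.n_classes, gcns, drop_rngs, cfg
    )
    return TrainedModel(
        variant=variant,
        gcns=gcns,
        head=head,
        graphs=graphs,
        specs=specs,
        config=cfg,
        train_matrices=matrices,
        view_names=view_names,
        n_classes=labels.n_classes,
        classes_=list(labels.classes_),
        class_weights_=class_weights(labels.labels, labels.n_classes),
        loss_trace=trace,
        pretrain_traces=pretraces,
    )


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def _view_test_probs(
    model: TrainedModel, view_index: int, X_te: np.ndarray, mode: str = "per_sample"
) -> np.ndarray:
    """Transductive per-view class probabilities for preprocessed test rows."""
    X_tr = model.train_matrices[view_index]
    if X_te.shape[1] != X_tr.shape[1]:
        raise ValueError(
            f"view {model.view_names[view_index]!r}: test feature dimension "
            f"{X_te.shape[1]} differs from fitted {X_tr.shape[1]}"
        )
    gcn = model.gcns[view_index]
    g = model.graphs[view_index]
    n_tr, n_te = X_tr.shape[0], X_te.shape[0]
    if g is None:  # identity-graph variant: the test sample stands alone
        eps = np.inf
        A_tr = np.zeros((n_tr, n_tr))
    else:
        eps = g.epsilon
        A_tr = g.A
    A_ext = extend_for_test(X_tr, X_te, eps, A_tr=A_tr, mode=mode)
    if mode == "batch":
        X_full = np.vstack([X_tr, X_te])
        logits = gcn.forward_numpy(X_full, A_ext)
        return softmax(logits[n_tr:])
    X_stack = np.empty((n_te, n_tr + 1, X_tr.shape[1]))
    X_stack[:, :n_tr, :] = X_tr
    X_stack[:, n_tr, :] = X_te
    logits = gcn.forward_numpy(X_stack, A_ext)
    return softmax(logits[:, n_tr, :])


def _integrate(model: TrainedModel, view_probs: list[np.ndarray]) -> np.ndarray:
    if model.m == 1 or model.head is None:
        return view_probs[0]
    from .networks import concat_predictions, cross_omics_tensor

    if model.integration == "vcdn":
        x = cross_omics_tensor(view_probs).flat
    else:
        x = concat_predictions(view_probs)
    return softmax(model.head.forward_numpy(x))


def predict_proba(
    model: TrainedModel,
    test_data: MultiOmicsDataset | list,
    preprocess: bool = True,
    mode: str = "per_sample",
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Final and per-view test class probabilities.

    ``test_data`` is a MultiOmicsDataset of raw views (preprocessed with the
    fitted specs) or, with ``preprocess=False``, a list of already-processed
    matrices in fitted feature space.
    """
    if preprocess:
        views = test_data.views if isinstance(test_data, MultiOmicsDataset) else test_data
        matrices = [
            apply_preprocess(v, spec).values for v, spec in zip(views, model.specs)
        ]
    else:
        matrices = list(test_data)
    view_probs = [
        _view_test_probs(model, i, X_te, mode=mode) for i, X_te in enumerate(matrices)
    ]
    return _integrate(model, view_probs), view_probs


def predict(
    model: TrainedModel,
    test_data: MultiOmicsDataset | list,
    preprocess: bool = True,
    mode: str = "per_sample",
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and final probabilities; argmax ties break low."""
    proba, _ = predict_proba(model, test_data, preprocess=preprocess, mode=mode)
    return np.argmax(proba, axis=1), proba


# --------------------------------------------------------------------------
# evaluation and model selection
# --------------------------------------------------------------------------


def evaluate(
    y_true: np.ndarray,
    proba: np.ndarray,
    scheme: str | None = None,
    positive_class: int = 1,
) -> MetricsReport:
    """ACC/F1/AUC for binary tasks; ACC plus weighted/macro F1 and AUC for
    multi-class tasks (one-vs-rest AUC)."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    c = proba.shape[1]
    if scheme is None:
        scheme = "binary" if c == 2 else "multiclass"
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: test truth contains a single class")
    y_pred = np.argmax(proba, axis=1)
    if scheme == "binary":
        metrics = {
            "ACC": accuracy_score(y_true, y_pred),
            "F1": f1_score(y_true, y_pred, pos_label=positive_class),
            "AUC": roc_auc_score(y_true == positive_class, proba[:, positive_class]),
        }
    else:
        metrics = {
            "ACC": accuracy_score(y_true, y_pred),
            "F1_weighted": f1_score(y_true, y_pred, average="weighted"),
            "F1_macro": f1_score(y_true, y_pred, average="macro"),
            "AUC_weighted": roc_auc_score(
                y_true, proba, multi_class="ovr", average="weighted"
            ),
            "AUC_macro": roc_auc_score(
                y_true, proba, multi_class="ovr", average="macro"
            ),
        }
    return MetricsReport(metrics={k: float(v) for k, v in metrics.items()})


def tune_k(
    train_data: MultiOmicsDataset,
    config: RunConfig,
    variant: str = "mogonet",
    n_folds: int = 5,
    preprocess: bool = True,
) -> int:
    """Pick k from the grid by stratified CV accuracy on the training data.

    Ties go to the smaller k; a single-element grid short-circuits.
    """
    grid = sorted(config.k_grid)
    if not grid:
        raise ValueError("empty k grid")
    if len(grid) == 1:
        return grid[0]
    labels = train_data.labels.labels
    if np.min(np.bincount(labels)) < n_folds:
        raise ValueError("a class is too small for stratified k-fold tuning")
    seed = int(substream(config.seed, "tune_k/split").integers(2**31))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = np.array(train_data.sample_ids)
    best_k, best_acc = grid[0], -1.0
    for k in grid:
        accs = []
        for tr_idx, va_idx in skf.split(ids, labels):
            sub_cfg = config.replace(k=k)
            model = fit(
                train_data.subset(list(ids[tr_idx])),
                sub_cfg,
                variant=variant,
                preprocess=preprocess,
            )
            va = train_data.subset(list(ids[va_idx]))
            y_pred, _ = predict(model, va)
            accs.append(accuracy_score(va.labels.labels, y_pred))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:
            best_k, best_acc = k, mean_acc
    return best_k


def repeated_splits(
    data: MultiOmicsDataset,
    config: RunConfig,
    variant: str = "mogonet",
    n_repeats: int | None = None,
    test_fraction: float | None = None,
    preprocess: bool = True,
) -> MetricsReport:
    """Mean +/- sd metrics over stratified random train/test splits.

    Defaults: 30% of samples held out, 5 repeats, class distribution
    preserved in both parts.
    """
    n_repeats = n_repeats if n_repeats is not None else config.n_repeats
    test_fraction = test_fraction if test_fraction is not None else config.test_fraction
    seed = int(substream(config.seed, "split").integers(2**31))
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    ids = np.array(data.sample_ids)
    labels = data.labels.labels
    per_repeat: list[dict[str, float]] = []
    for tr_idx, te_idx in sss.split(ids, labels):
        train = data.subset(list(ids[tr_idx]))
        test = data.subset(list(ids[te_idx]))
        model = fit(train, config, variant=variant, preprocess=preprocess)
        _, proba = predict(model, test)
        report = evaluate(
            test.labels.labels, proba, positive_class=config.positive_class
        )
        per_repeat.append(report.metrics)
    keys = per_repeat[0].keys()
    mean = {k: float(np.mean([r[k] for r in per_repeat])) for k in keys}
    sd = {k: float(np.std([r[k] for r in per_repeat])) for k in keys}
    return MetricsReport(metrics=mean, sd=sd, per_repeat=per_repeat)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
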