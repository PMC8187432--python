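import numpy as np
import pytest

import mogonet as mg
from conftest import split_dataset
from mogonet.autodiff import softmax
from mogonet.train import _integrate, pretrain_gcns, train_joint


def _matrices(dataset):
    return [v.values for v in dataset.views]


class TestPretraining:
    def test_loss_trace_decreases_on_separable_data(self, trio_small, quick_cfg):
        data, _ = trio_small
        gcns, _, traces = pretrain_gcns(
            _matrices(data), [np.eye(data.n_samples)] * 3,
            data.labels.labels, 3, [v.name for v in data.views], quick_cfg,
        )
        for trace in traces:
            assert trace[-1] < trace[0]
            # broadly non-increasing: early average above late average
            assert np.mean(trace[:10]) > np.mean(trace[-10:])

    def test_zero_epochs_returns_initialisation(self, trio_small, quick_cfg):
        data, _ = trio_small
        cfg0 = quick_cfg.replace(pretrain_epochs=0)
        gcns, _, traces = pretrain_gcns(
            _matrices(data), [np.eye(data.n_samples)] * 3,
            data.labels.labels, 3, [v.name for v in data.views], cfg0,
        )
        assert all(t == [] for t in traces)
        # weights equal a fresh initialisation from the same substream
        from mogonet._rng import substream
        from mogonet.networks import GCNModel
        ref = GCNModel(
            data.views[0].n_features, list(cfg0.gcn_hidden), 3,
            substream(cfg0.seed, f"init/gcn/{data.views[0].name}"),
        )
        np.testing.assert_array_equal(gcns[0].weights[0].data, ref.weights[0].data)

    def test_same_seed_identical_weights(self, trio_small, quick_cfg):
        data, _ = trio_small
        args = (
            _matrices(data), [np.eye(data.n_samples)] * 3,
            data.labels.labels, 3, [v.name for v in data.views], quick_cfg,
        )
        g1, _, _ = pretrain_gcns(*args)
        g2, _, _ = pretrain_gcns(*args)
        for a, b in zip(g1, g2):
            for wa, wb in zip(a.parameters(), b.parameters()):
                np.testing.assert_array_equal(wa.data, wb.data)


class TestJointTraining:
    def test_gamma_zero_reduces_gcn_gradients_to_ce_only(self, trio_small):
        """With gamma = 0 the integration loss contributes nothing to the
        GCN gradients: the total-loss gradient equals the plain per-view
        cross-entropy gradient."""
        from mogonet._rng import substream
        from mogonet.autodiff import Tensor
        from mogonet.networks import VCDNModel, class_weights, weighted_cross_entropy
        from mogonet.train import _probs, _tensor_input

        data, _ = trio_small
        cfg = mg.RunConfig(k=3, gcn_hidden=[8], pretrain_epochs=0, dropout=0.0, seed=1)
        mats = _matrices(data)
        adjs = [np.eye(data.n_samples)] * 3
        names = [v.name for v in data.views]
        gcns, _, _ = pretrain_gcns(mats, adjs, data.labels.labels, 3, names, cfg)
        head = VCDNModel(27, 3, substream(1, "init/head"))
        w = class_weights(data.labels.labels, 3)

        def total_loss(gamma):
            per_view = [g.forward(X, A) for g, X, A in zip(gcns, mats, adjs)]
            loss = None
            for logits in per_view:
                term = weighted_cross_entropy(logits, data.labels.labels, w)
                loss = term if loss is None else loss + term
            x = _tensor_input([_probs(l) for l in per_view])
            return loss + gamma * weighted_cross_entropy(
                head.forward(x), data.labels.labels, w
            )

        # reference: CE-only gradient on view 0's first weight matrix
        logits = gcns[0].forward(mats[0], adjs[0])
        weighted_cross_entropy(logits, data.labels.labels, w).backward()
        ref = gcns[0].weights[0].grad.copy()
        for p in gcns[0].parameters():
            p.grad = None
        total_loss(0.0).backward()
        np.testing.assert_allclose(gcns[0].weights[0].grad, ref, atol=1e-12)
        # and with gamma > 0 the head loss does perturb the GCN gradient
        for p in gcns[0].parameters():
            p.grad = None
        total_loss(1.0).backward()
        assert not np.allclose(gcns[0].weights[0].grad, ref, atol=1e-12)

    def test_joint_loss_finite_and_traced(self, trio_model):
        model, *_ = trio_model
        assert len(model.loss_trace) > 0
        assert np.all(np.isfinite(model.loss_trace))

    def test_early_stop_on_flat_loss(self, trio_small):
        data, _ = trio_small
        cfg = mg.RunConfig(
            k=3, gcn_hidden=[8], pretrain_epochs=10, joint_epochs=500,
            loss_tol=0.5, patience=5, seed=2,
        )
        model = mg.fit(data, cfg)
        assert len(model.loss_trace) < 500


class TestPredict:
    def test_deterministic_given_seed(self, trio_small, quick_cfg):
        data, _ = trio_small
        train, test = split_dataset(data, seed=1)
        m1 = mg.fit(train, quick_cfg)
        m2 = mg.fit(train, quick_cfg)
        p1 = mg.predict(m1, test)[1]
        p2 = mg.predict(m2, test)[1]
        np.testing.assert_array_equal(p1, p2)

    def test_single_view_prediction_is_gcn_prediction(self, trio_small, quick_cfg):
        data, _ = trio_small
        solo = mg.MultiOmicsDataset([data.views[0]], data.labels)
        train, test = split_dataset(solo, seed=2)
        model = mg.fit(train, quick_cfg)
        assert model.head is None
        final, view_probs = mg.predict_proba(model, test)
        np.testing.assert_array_equal(final, view_probs[0])

    def test_tie_breaks_toward_lowest_class(self):
        proba = np.array([[0.4, 0.4, 0.2], [0.25, 0.25, 0.5]])
        assert np.argmax(proba, axis=1).tolist() == [0, 2]

    def test_duplicated_training_sample_keeps_its_label(self, trio_model):
        model, train, _, _ = trio_model
        dup = mg.MultiOmicsDataset(list(train.views), train.labels)
        y_dup, p_dup = mg.predict(model, dup)
        # training-sample predictions from the fitted graphs
        tr_probs = [
            softmax(g.forward_numpy(X, gr.A_tilde))
            for g, X, gr in zip(model.gcns, model.train_matrices, model.graphs)
        ]
        y_tr = _integrate(model, tr_probs).argmax(1)
        # the unit-test model is small and lightly trained, so its posteriors
        # are flat; the check here is that an appended duplicate echoes the
        # training node's prediction for the vast majority of samples
        assert (y_dup == y_tr).mean() >= 0.9

    def test_feature_dimension_mismatch_errors(self, trio_model):
        model, train, test, _ = trio_model
        bad = [v.values[:, :-1] for v in test.views]
        with pytest.raises(ValueError, match="dimension"):
            mg.predict_proba(model, bad, preprocess=False)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        proba = np.eye(2)[y]
        rep = mg.evaluate(y, proba)
        assert rep.metrics["ACC"] == 1.0 and rep.metrics["F1"] == 1.0
        assert rep.metrics["AUC"] == 1.0

    def test_binary_f1_from_confusion_counts(self):
        # TP=3, FP=1, FN=1, TN=5 -> F1 = 2*3 / (2*3 + 1 + 1) = 0.75
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        proba = np.zeros((10, 2))
        proba[np.arange(10), y_pred] = 0.9
        proba[np.arange(10), 1 - y_pred] = 0.1
        rep = mg.evaluate(y_true, proba)
        assert rep.metrics["F1"] == pytest.approx(0.75)

    def test_macro_equals_weighted_at_equal_support(self):
        # per-class F1 by hand: class 0 perfect -> 1; class 1 has TP=1, FN=1,
        # FP=2 -> 2/(2+2+1) = 0.4; class 2 never predicted right -> 0.
        # macro = (1 + 0.4 + 0)/3 = 7/15, and weighted coincides at equal support.
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 0, 1, 2, 1, 1])
        proba = np.full((6, 3), 0.1)
        proba[np.arange(6), y_pred] = 0.8
        rep = mg.evaluate(y_true, proba)
        assert rep.metrics["F1_macro"] == pytest.approx(7 / 15)
        assert rep.metrics["F1_weighted"] == pytest.approx(rep.metrics["F1_macro"])

    def test_single_class_truth_errors(self):
        with pytest.raises(ValueError, match="single class"):
            mg.evaluate(np.zeros(4, dtype=int), np.full((4, 2), 0.5))


class TestModelSelectionAndRepeats:
    def test_single_element_grid_short_circuits(self, trio_small):
        data, _ = trio_small
        cfg = mg.RunConfig(k="auto", k_grid=[4], seed=0)
        assert mg.tune_k(data, cfg) == 4

    def test_repeated_splits_reports_mean_and_sd(self, trio_small):
        data, _ = trio_small
        cfg = mg.RunConfig(
            k=3, gcn_hidden=[8], pretrain_epochs=20, joint_epochs=30, seed=5
        )
        rep = mg.repeated_splits(data, cfg, n_repeats=2)
        assert set(rep.metrics) == {"ACC", "F1_weighted", "F1_macro",
                                    "AUC_weighted", "AUC_macro"}
        assert all(0 <= v <= 1 for v in rep.metrics.values())
        assert len(rep.per_repeat) == 2

    def test_one_repeat_gives_zero_sd(self, trio_small):
        data, _ = trio_small
        cfg = mg.RunConfig(
            k=3, gcn_hidden=[8], pretrain_epochs=15, joint_epochs=20, seed=6
        )
        rep = mg.repeated_splits(data, cfg, n_repeats=1)
        assert all(v == 0.0 for v in rep.sd.values())

    def test_split_indices_reproducible(self, trio_small):
        from sklearn.model_selection import StratifiedShuffleSplit

        from mogonet._rng import substream

        data, _ = trio_small
        for _ in range(2):
            seed = int(substream(3, "split").integers(2**31))
            sss = StratifiedShuffleSplit(n_splits=1, test_size=0.3, random_state=seed)
            idx = next(sss.split(np.array(data.sample_ids), data.labels.labels))
            if _ == 0:
                first = idx
        np.testing.assert_array_equal(first[0], idx[0])


class TestPersistence:
    def test_save_load_round_trip(self, trio_model, tmp_path):
        model, train, test, _ = trio_model
        mg.save_model(model, tmp_path / "m.pkl")
        back = mg.load_model(tmp_path / "m.pkl")
        p1 = mg.predict(model, test)[1]
        p2 = mg.predict(back, test)[1]
        np.testing.assert_array_equal(p1, p2)
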