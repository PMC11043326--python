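"""Masked focal loss, network builders, gradient correctness and training loop."""

import numpy as np
import pytest

from phenoscreen import model as mdl


def reference_bce(scores, labels):
    """Independent plain-BCE implementation over observed cells."""
    mask = ~np.isnan(labels)
    p = np.clip(scores[mask], 1e-12, 1 - 1e-12)
    y = labels[mask]
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


class TestMaskedFocalBce:
    def test_all_missing_gives_zero_with_warning(self):
        labels = np.full((3, 4), np.nan)
        with pytest.warns(UserWarning, match="no observed"):
            assert mdl.masked_focal_bce(np.full((3, 4), 0.3), labels) == 0.0

    def test_gamma_zero_matches_independent_bce(self, rng):
        for _ in range(20):
            scores = rng.random((6, 9))
            labels = rng.choice([0.0, 1.0, np.nan], size=(6, 9))
            if np.isnan(labels).all():
                continue
            ours = mdl.masked_focal_bce(scores, labels, gamma=0.0)
            assert ours == pytest.approx(reference_bce(scores, labels), abs=1e-8)

    def test_focal_value_hand_computed(self):
        # p = 0.5, label 1, gamma 2: (1-0.5)^2 * ln 2 = 0.25 ln 2
        val = mdl.masked_focal_bce(np.array([[0.5]]), np.array([[1.0]]), gamma=2.0)
        assert val == pytest.approx(0.25 * np.log(2.0), abs=1e-12)

    def test_missing_labels_are_exactly_inert(self, rng):
        scores = rng.random((5, 7))
        labels = rng.choice([0.0, 1.0, np.nan], size=(5, 7), p=[0.4, 0.2, 0.4])
        labels[0, 0] = np.nan
        base = mdl.masked_focal_bce(scores, labels, gamma=2.0)
        for delta in (0.3, -0.2, 0.45):
            bumped = scores.copy()
            bumped[0, 0] = np.clip(bumped[0, 0] + delta, 0.01, 0.99)
            assert mdl.masked_focal_bce(bumped, labels, gamma=2.0) == base

    def test_bce_plus_focal_is_the_sum(self, rng):
        scores = rng.random((4, 4))
        labels = rng.choice([0.0, 1.0], size=(4, 4))
        s = mdl.masked_focal_bce(scores, labels, loss="bce+focal")
        assert s == pytest.approx(
            mdl.masked_focal_bce(scores, labels, loss="bce")
            + mdl.masked_focal_bce(scores, labels, loss="focal"), abs=1e-12)


class TestLossGradients:
    @pytest.mark.parametrize("loss,gamma", [("bce", 0.0), ("focal", 2.0),
                                            ("focal", 0.5), ("bce+focal", 2.0)])
    def test_logit_gradient_matches_finite_differences(self, loss, gamma, rng):
        logits = rng.normal(0, 2, size=(4, 5))
        labels = rng.choice([0.0, 1.0, np.nan], size=(4, 5))
        labels[0, 0] = 1.0  # ensure at least one observed cell
        _, grad = mdl._loss_grad_logits(logits, labels, gamma, loss)
        eps = 1e-6
        for i in range(4):
            for j in range(5):
                zp, zm = logits.copy(), logits.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                lp, _ = mdl._loss_grad_logits(zp, labels, gamma, loss)
                lm, _ = mdl._loss_grad_logits(zm, labels, gamma, loss)
                assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_gradient_zero_at_missing_cells(self, rng):
        logits = rng.normal(size=(3, 3))
        labels = np.array([[1.0, np.nan, 0.0]] * 3)
        _, grad = mdl._loss_grad_logits(logits, labels, 2.0, "focal")
        assert np.all(grad[:, 1] == 0.0)


class TestBuildModel:
    def test_mlp_output_shape_and_range(self, rng):
        cfg = mdl.ModelConfig(hidden_layers=3, hidden_width=32, seed=0)
        net = mdl.build_model(cfg, 20, n_assays=140)
        out = net.predict_proba(rng.normal(size=(7, 20)))
        assert out.shape == (7, 140)
        assert np.all((out > 0) & (out < 1))

    def test_seed_determinism(self, rng):
        cfg = mdl.ModelConfig(hidden_layers=2, hidden_width=16, seed=5)
        x = rng.normal(size=(4, 10))
        a = mdl.build_model(cfg, 10, 6).predict_proba(x)
        b = mdl.build_model(cfg, 10, 6).predict_proba(x)
        assert np.array_equal(a, b)

    def test_cnn_five_channel_forward(self, rng):
        cfg = mdl.ModelConfig(modality="image", conv_channels=(4, 8), seed=0)
        net = mdl.build_model(cfg, (5, 16, 16), n_assays=9)
        out = net.predict_proba(rng.normal(size=(3, 5, 16, 16)))
        assert out.shape == (3, 9)
        assert np.all((out > 0) & (out < 1))

    def test_cnn_backward_matches_finite_differences(self, rng):
        cfg = mdl.ModelConfig(modality="image", conv_channels=(2, 2), seed=1)
        net = mdl.build_model(cfg, (1, 8, 8), n_assays=2)
        x = rng.normal(size=(2, 1, 8, 8))
        labels = np.array([[1.0, 0.0], [0.0, np.nan]])
        logits, cache = net.forward(x)
        _, dlogits = mdl._loss_grad_logits(logits, labels, 2.0, "focal")
        grads = net.backward(cache, dlogits)
        params = net.parameters()
        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = mdl._loss_grad_logits(net.logits(x), labels, 2.0, "focal")
                flat[idx] = orig - eps
                lm, _ = mdl._loss_grad_logits(net.logits(x), labels, 2.0, "focal")
                flat[idx] = orig
                assert g.reshape(-1)[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


class TestExpandInputChannels:
    def test_copy_rule_on_kernel_sums(self, rng):
        kernel = rng.normal(size=(6, 3, 3, 3))
        out = mdl.expand_input_channels(kernel, target_channels=5)
        sums = out.sum(axis=(0, 2, 3))
        a, b, c = kernel.sum(axis=(0, 2, 3))
        assert np.allclose(sums, [a, b, c, a, b])

    def test_target_three_is_identity(self, rng):
        kernel = rng.normal(size=(2, 3, 3, 3))
        assert np.array_equal(mdl.expand_input_channels(kernel, 3), kernel)

    def test_target_below_three_raises(self, rng):
        with pytest.raises(ValueError):
            mdl.expand_input_channels(rng.normal(size=(2, 3, 3, 3)), 2)


class TestTrainPredict:
    def _toy_data(self, rng, n=300, d=8, a=3):
        x = rng.normal(size=(n, d))
        w = rng.normal(size=(d, a))
        logits = x @ w
        y = (logits > np.quantile(logits, 0.8, axis=0)).astype(float)
        y[rng.random((n, a)) < 0.3] = np.nan
        return x, y

    def test_zero_epochs_returns_initial_model(self, rng):
        cfg = mdl.ModelConfig(hidden_layers=1, hidden_width=8, max_epochs=0, seed=0)
        net = mdl.build_model(cfg, 8, 3)
        before = net.state_dict()
        x, y = self._toy_data(rng)
        net, hist = mdl.train(net, x, y, x, y, cfg)
        assert hist.epochs == []
        for w0, w1 in zip(before["weights"], net.state_dict()["weights"]):
            assert np.array_equal(w0, w1)

    def test_empty_training_set_raises(self, rng):
        cfg = mdl.ModelConfig(hidden_layers=1, hidden_width=8, seed=0)
        net = mdl.build_model(cfg, 8, 3)
        with pytest.raises(ValueError, match="empty"):
            mdl.train(net, np.empty((0, 8)), np.empty((0, 3)), None, None, cfg)

    def test_learns_separable_signal(self, rng):
        x, y = self._toy_data(rng, n=600)
        cfg = mdl.ModelConfig(hidden_layers=2, hidden_width=32, optimizer="adam",
                              learning_rate=3e-3, max_epochs=25, patience=5, seed=2)
        net = mdl.build_model(cfg, 8, 3)
        net, hist = mdl.train(net, x[:400], y[:400], x[400:], y[400:], cfg)
        assert hist.best_val_auc > 0.85

    def test_replicate_scores_average_per_compound(self):
        cfg = mdl.ModelConfig(hidden_layers=1, hidden_width=4, seed=0)
        net = mdl.build_model(cfg, 2, 1)
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        pm = mdl.predict(net, x, groups=["c1", "c1", "c2"])
        raw = net.predict_proba(x)
        assert pm.compounds == ["c1", "c2"]
        assert pm.scores[0, 0] == pytest.approx(raw[:2, 0].mean())
        assert pm.scores[1, 0] == pytest.approx(raw[2, 0])

    def test_predict_deterministic_and_checks_dims(self, rng):
        cfg = mdl.ModelConfig(hidden_layers=1, hidden_width=4, seed=0)
        net = mdl.build_model(cfg, 5, 2)
        x = rng.normal(size=(6, 5))
        a = mdl.predict(net, x).scores
        b = mdl.predict(net, x).scores
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="dimension"):
            mdl.predict(net, rng.normal(size=(6, 4)))


def test_auc_degrades_monotonically_with_label_noise():
    """More single-point label noise cannot improve generalisation (noise band 0.03)."""
    from phenoscreen import chem, evaluate as ev, preprocess as pre, synthetic as syn

    aucs = []
    for flip in (0.0, 0.2, 0.4):
        cfg = syn.GeneratorConfig(n_compounds=700, n_assays=4, n_clusters=70, fp_bits=256,
                                  fill_rate=0.8, hit_rate=0.05, n_plates=6, n_features=48,
                                  replicates_per_compound=2, phenotype_snr=4.0,
                                  label_flip_rate=flip, seed=31)
        lib = syn.generate_library(cfg)
        panel = syn.generate_panel(cfg)
        labels = syn.generate_labels(lib, panel, cfg)
        prof, _ = pre.variance_filter(
            pre.robust_z_normalize(syn.generate_profiles(lib, panel, cfg)), 1.0)
        folds = chem.assign_folds(chem.butina_cluster(lib.fingerprints, 0.6), k=3)
        bundle = ev.bundle_from_profiles(prof, labels, folds.fold_ids)
        mcfg = mdl.ModelConfig(hidden_layers=2, hidden_width=64, optimizer="adam",
                               learning_rate=1e-3, max_epochs=20, patience=4, seed=31)
        tab, _, _ = ev.cross_validate(bundle, mcfg, ev.make_split_plan(3))
        aucs.append(tab["roc_auc"].mean())
    assert aucs[0] >= aucs[1] - 0.03
    assert aucs[1] >= aucs[2] - 0.03
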