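"""ROC-AUC, split plans, nested cross-validation and summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen import evaluate as ev
from phenoscreen.model import ModelConfig
from phenoscreen.synthetic import LabelMatrix


def brute_force_auc(scores, labels):
    """Pairwise-comparison oracle: P(active outranks inactive), ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return float("nan")
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_example(self):
        # actives ranked 1st and 3rd of 4: 3 of 4 pairs concordant
        assert ev.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert ev.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_class_returns_nan(self):
        assert np.isnan(ev.roc_auc([0.1, 0.9], [1, 1]))

    def test_unknown_labels_excluded(self):
        full = ev.roc_auc([0.9, 0.1, 0.5], [1.0, 0.0, np.nan])
        assert full == ev.roc_auc([0.9, 0.1], [1.0, 0.0]) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.2], [1])

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 31)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # deliberate ties
        labels = rng.choice([0.0, 1.0], size=n)
        ours = ev.roc_auc(scores, labels)
        oracle = brute_force_auc(scores, labels)
        if np.isnan(oracle):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_on_tied_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            scores = rng.choice(np.linspace(0, 1, 5), size=40)
            labels = rng.choice([0.0, 1.0], size=40)
            labels[:2] = [0.0, 1.0]
            assert ev.roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_score_negation_complements(self, rng):
        scores = rng.permutation(np.linspace(0.01, 0.99, 25))  # tie-free
        labels = rng.choice([0.0, 1.0], size=25)
        labels[:2] = [0.0, 1.0]
        assert ev.roc_auc(scores, labels) + ev.roc_auc(-scores, labels) == pytest.approx(1.0)


class TestSplitPlan:
    def test_six_fold_rotation(self):
        plan = ev.make_split_plan(6)
        tests = [t for _, _, t in plan]
        assert sorted(tests) == list(range(6))
        for train, val, test in plan:
            assert val == (test + 1) % 6
            assert len(train) == 4
            assert set(train) | {val, test} == set(range(6))
            assert val not in train and test not in train and val != test

    def test_k_below_three_raises(self):
        with pytest.raises(ValueError):
            ev.make_split_plan(2)


def oracle_bundle(rng, n=600, a=4):
    """Inputs that ARE the truth plus tiny noise: any learner should ace this."""
    truth = (rng.random((n, a)) < 0.25).astype(float)
    inputs = truth + 0.01 * rng.standard_normal((n, a))
    compounds = [f"c{i}" for i in range(n)]
    labels = truth.copy()
    fold_ids = np.arange(n) % 6
    return ev.DataBundle(
        compound_ids=compounds, assay_ids=[f"A{j}" for j in range(a)], labels=labels,
        inputs=inputs, row_compound=np.arange(n), fold_ids=fold_ids, modality="features",
    )


class TestCrossValidate:
    def test_oracle_inputs_reach_near_perfect_auc(self, rng):
        bundle = oracle_bundle(rng)
        cfg = ModelConfig(hidden_layers=1, hidden_width=16, optimizer="adam",
                          learning_rate=1e-2, max_epochs=15, patience=4, seed=0)
        table, pms, hists = ev.cross_validate(bundle, cfg, ev.make_split_plan(6))
        defined = table["roc_auc"].dropna()
        assert (defined > 0.99).all()

    def test_each_compound_tested_exactly_once(self, rng):
        bundle = oracle_bundle(rng, n=240)
        cfg = ModelConfig(hidden_layers=1, hidden_width=8, optimizer="adam",
                          learning_rate=1e-2, max_epochs=2, patience=2, seed=0)
        _, pms, _ = ev.cross_validate(bundle, cfg, ev.make_split_plan(6))
        tested = [c for pm in pms for c in pm.compounds]
        assert sorted(tested) == sorted(bundle.compound_ids)

    def test_training_batches_exclude_validation_and_test_compounds(self, rng):
        bundle = oracle_bundle(rng, n=120)
        cfg = ModelConfig(hidden_layers=1, hidden_width=8, optimizer="adam",
                          learning_rate=1e-2, max_epochs=2, patience=2, seed=0)
        plan = ev.make_split_plan(6)
        _, _, hists = ev.cross_validate(bundle, cfg, plan)
        for hist, (train_folds, val, test) in zip(hists, plan):
            heldout = {c for c, f in zip(bundle.compound_ids, bundle.fold_ids)
                       if f in (val, test)}
            assert hist.train_groups.isdisjoint(heldout)

    def test_single_class_assay_yields_sentinel_not_failure(self, rng):
        bundle = oracle_bundle(rng, n=120, a=2)
        bundle.labels[:, 1] = 1.0  # an assay with only actives
        cfg = ModelConfig(hidden_layers=1, hidden_width=8, optimizer="adam",
                          learning_rate=1e-2, max_epochs=1, patience=1, seed=0)
        table, _, _ = ev.cross_validate(bundle, cfg, ev.make_split_plan(6))
        assert table.loc[table["assay_id"] == "A1", "roc_auc"].isna().all()


class TestSummarize:
    def test_grand_mean_and_threshold_fractions(self):
        rows = []
        for assay, auc in zip("abcd", [0.65, 0.75, 0.85, 0.95]):
            rows.append({"assay_id": assay, "split_id": 0, "modality": "m", "roc_auc": auc})
        out = ev.summarize(pd.DataFrame(rows))["m"]
        assert out["mean_auc_over_assays"] == pytest.approx(0.80)
        assert out["frac_assays_auc_ge_0.7"] == pytest.approx(0.75)
        assert out["frac_assays_auc_ge_0.8"] == pytest.approx(0.50)
        assert out["frac_assays_auc_ge_0.9"] == pytest.approx(0.25)

    def test_all_chance_level_gives_zero_fractions(self):
        rows = [{"assay_id": a, "split_id": 0, "modality": "m", "roc_auc": 0.5}
                for a in "abc"]
        out = ev.summarize(pd.DataFrame(rows))["m"]
        assert out["frac_assays_auc_ge_0.7"] == 0.0

    def test_single_assay_zero_sd(self):
        rows = [{"assay_id": "a", "split_id": s, "modality": "m", "roc_auc": 0.7}
                for s in range(3)]
        out = ev.summarize(pd.DataFrame(rows))["m"]
        assert out["sd_auc_over_assays"] == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            ev.summarize(pd.DataFrame(columns=["assay_id", "split_id", "modality", "roc_auc"]))
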