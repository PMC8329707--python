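"""Sequence classifier: folds, training, prediction and calibration."""

import numpy as np
import pandas as pd
import pytest

import pawprint as pp
from tests.conftest import make_planted_feature_cohort


class TestGroupedKFold:
    def test_ten_animals_five_folds_of_two(self):
        manifest = pd.DataFrame(
            {"trial_id": [f"t{i}" for i in range(10)],
             "animal_id": [f"a{i}" for i in range(10)],
             "group": ["control", "mpne"] * 5}
        )
        folds = pp.grouped_kfold_split(manifest, k=5, seed=1)
        sizes = folds.value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_group_keys_never_split_across_folds(self):
        rng = np.random.default_rng(0)
        manifest = pd.DataFrame(
            {"trial_id": [f"t{i}" for i in range(40)],
             "animal_id": [f"a{i % 13}" for i in range(40)],
             "group": rng.choice(["control", "mpne"], 40)}
        )
        folds = pp.grouped_kfold_split(manifest, k=5, seed=3)
        by_animal = pd.DataFrame(
            {"animal": manifest.animal_id.to_numpy(), "fold": folds.to_numpy()}
        )
        assert (by_animal.groupby("animal").fold.nunique() == 1).all()

    def test_balanced_data_gives_twenty_percent_test_folds(self):
        manifest = pd.DataFrame(
            {"trial_id": [f"t{i}" for i in range(100)],
             "animal_id": [f"a{i}" for i in range(100)],
             "group": ["control", "mpne"] * 50}
        )
        folds = pp.grouped_kfold_split(manifest, k=5, seed=0)
        assert (folds.value_counts() == 20).all()

    def test_fewer_groups_than_folds_rejected(self):
        manifest = pd.DataFrame(
            {"trial_id": ["t0", "t1", "t2"], "animal_id": ["a", "a", "b"],
             "group": ["control", "control", "mpne"]}
        )
        with pytest.raises(ValueError, match="distinct"):
            pp.grouped_kfold_split(manifest, k=5)


class TestTraining:
    def test_separable_cohort_training_loss_decreases(self, tiny_trained_lstm):
        model, _, _ = tiny_trained_lstm
        losses = model.loss_history_
        assert losses[-1] < losses[0] / 2

    def test_single_class_training_rejected(self, planted_feature_cohort):
        manifest, feats = planted_feature_cohort
        ids = manifest[manifest.group == "mpne"].trial_id
        with pytest.raises(ValueError, match="2 classes"):
            pp.train_fold([feats[t] for t in ids], ["mpne"] * len(ids))

    def test_same_seed_reproduces_identical_weights(self, planted_feature_cohort):
        manifest, feats = planted_feature_cohort
        config = pp.ModelConfig(lstm_units=8, epochs=2, batch_size=16, seed=5)
        fl = [feats[t] for t in manifest.trial_id]
        labels = manifest.group.to_numpy()
        m1 = pp.train_fold(fl, labels, config=config)
        m2 = pp.train_fold(fl, labels, config=config)
        for k in ("Wx", "Wh", "b", "Wo", "bo"):
            np.testing.assert_array_equal(getattr(m1, k), getattr(m2, k))

    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, tiny_trained_lstm):
        model, manifest, feats = tiny_trained_lstm
        fm = feats[manifest.trial_id.iloc[0]]
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = pp.LSTMClassifier.load(path)
        assert loaded.predict_proba(fm) == pytest.approx(model.predict_proba(fm))


class TestPrediction:
    def test_softmax_pair_sums_to_one(self, tiny_trained_lstm):
        model, manifest, feats = tiny_trained_lstm
        from pawprint.classifier import _softmax

        X = model._as_sequences(feats[manifest.trial_id.iloc[0]])
        logits = model.forward(model._standardize(X))
        np.testing.assert_allclose(_softmax(logits).sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_output_layer_gives_half(self, planted_feature_cohort):
        manifest, feats = planted_feature_cohort
        model = pp.LSTMClassifier(12, pp.ModelConfig(lstm_units=8))
        model.Wo[:] = 0.0
        model.bo[:] = 0.0
        p = model.predict_proba(feats[manifest.trial_id.iloc[0]])
        assert p[0] == pytest.approx(0.5)

    def test_feature_dimension_mismatch_rejected(self, tiny_trained_lstm):
        model, _, _ = tiny_trained_lstm
        bad = np.zeros((5, 60))
        with pytest.raises(ValueError, match="does not match"):
            model.predict_proba([bad])

    @pytest.mark.parametrize(
        "prob, expected",
        [(0.82, "control"), (0.13, "mpne"), (0.5, "control"), (0.9, "control")],
    )
    def test_threshold_rule(self, prob, expected):
        assert pp.classify(prob) == expected

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            pp.classify(1.2)


class TestEvaluateCV:
    def test_planted_signal_recovered_above_chance(self, planted_feature_cohort):
        manifest, feats = planted_feature_cohort
        config = pp.ModelConfig(
            lstm_units=16, epochs=40, batch_size=8, learning_rate=3e-3, seed=0
        )
        res = pp.evaluate_cv(manifest, feats, config=config, k=5)
        assert res.accuracy >= 0.85
        assert res.group_stats["control"]["mean"] > res.group_stats["mpne"]["mean"]

    def test_every_trial_predicted_exactly_once(self, planted_feature_cohort):
        manifest, feats = planted_feature_cohort
        config = pp.ModelConfig(lstm_units=8, epochs=3, batch_size=16, seed=0)
        res = pp.evaluate_cv(manifest, feats, config=config, k=5)
        assert res.probabilities.notna().all()
        assert len(res.probabilities) == len(manifest)
        res.assert_no_leakage(manifest)

    def test_label_permutation_yields_chance_accuracy(self):
        # binomial null at p=0.5, n=60: 10 permuted cohorts should stay
        # inside the exact central 99% band in >=9 cases
        from scipy import stats

        manifest, feats = make_planted_feature_cohort(
            n_per_group=30, n_features=8, n_frames=40, seed=4
        )
        config = pp.ModelConfig(lstm_units=8, epochs=5, batch_size=16, seed=0)
        rng = np.random.default_rng(123)
        lo, hi = stats.binom.ppf([0.005, 0.995], 60, 0.5) / 60
        inside = 0
        for rep in range(10):
            permuted = manifest.copy()
            permuted["group"] = rng.permutation(permuted["group"].to_numpy())
            # permuted labels break the animal/label nesting, so fold by trial
            permuted["animal_id"] = permuted["trial_id"]
            res = pp.evaluate_cv(permuted, feats, config=config, k=5)
            inside += lo <= res.accuracy <= hi
        assert inside >= 9

    def test_lstm_size_robustness_on_planted_signal(self, planted_feature_cohort):
        # halving/doubling the hidden width moves accuracy < 10 points
        manifest, feats = planted_feature_cohort
        accs = {}
        for units in (8, 16, 32):
            config = pp.ModelConfig(
                lstm_units=units, epochs=40, batch_size=8, learning_rate=3e-3, seed=0
            )
            accs[units] = pp.evaluate_cv(manifest, feats, config=config, k=5).accuracy
        assert max(accs.values()) - min(accs.values()) < 0.10
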