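"""Relevance propagation: closed forms, conservation, oracle agreement."""

import numpy as np
import pytest
from scipy import stats

import pawprint as pp
from pawprint.relevance import DenseNet


@pytest.fixture
def linear_model():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(12, 2))
    return DenseNet([W]), W


@pytest.fixture
def two_layer_toy():
    # zero biases keep epsilon-LRP exactly conservative up to the stabilizer
    rng = np.random.default_rng(1)
    return DenseNet([rng.normal(size=(10, 6)), rng.normal(size=(6, 2))])


class TestClosedForms:
    def test_linear_model_lrp_equals_w_times_x(self, linear_model):
        model, W = linear_model
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 4))
        rel = pp.lrp_explain(model, x, target_class=1, epsilon=1e-12)
        np.testing.assert_allclose(
            rel.values, (W[:, 1] * x.ravel()).reshape(3, 4), rtol=1e-6
        )

    def test_linear_model_gradient_input_matches_lrp(self, linear_model):
        model, _ = linear_model
        x = np.random.default_rng(3).normal(size=(3, 4))
        lrp = pp.lrp_explain(model, x, target_class=0, epsilon=1e-12)
        gxi = pp.gradient_explain(model, x, target_class=0)
        np.testing.assert_allclose(lrp.values, gxi.values, rtol=1e-6)

    def test_dead_input_dimension_gets_zero_relevance(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(6, 2))
        W[2, :] = 0.0  # input 2 has no outgoing weights
        model = DenseNet([W])
        rel = pp.lrp_explain(model, rng.normal(size=(6, 1)), target_class=1)
        assert rel.values[2, 0] == 0.0

    def test_constant_output_model_zero_gradient_relevance(self):
        model = DenseNet([np.zeros((6, 2))])
        x = np.random.default_rng(5).normal(size=(6, 1))
        rel = pp.gradient_explain(model, x, target_class=0)
        np.testing.assert_array_equal(rel.values, 0.0)


class TestConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_two_layer_toy_net_conserves_score(self, seed):
        rng = np.random.default_rng(seed)
        model = DenseNet([rng.normal(size=(10, 6)), rng.normal(size=(6, 2))])
        x = rng.normal(size=(10, 1))
        score = model.score(x, 1)
        if abs(score) < 1e-3:  # skip near-degenerate draws
            x = x + 0.5
            score = model.score(x, 1)
        rel = pp.lrp_explain(model, x, target_class=1, epsilon=1e-6)
        assert abs(rel.values.sum() - score) < 1e-3 * abs(score)

    def test_class_swap_flips_summed_relevance_contrast(self, two_layer_toy):
        x = np.abs(np.random.default_rng(6).normal(size=(10, 1)))
        r0 = pp.lrp_explain(two_layer_toy, x, target_class=0).total()
        r1 = pp.lrp_explain(two_layer_toy, x, target_class=1).total()
        s0 = two_layer_toy.score(x, 0)
        s1 = two_layer_toy.score(x, 1)
        assert np.sign(r0 - r1) == np.sign(s0 - s1)


class TestLSTMExplanations:
    def test_relevance_shape_matches_feature_matrix(self, tiny_trained_lstm):
        model, manifest, feats = tiny_trained_lstm
        fm = feats[manifest.trial_id.iloc[0]]
        rel = pp.lrp_explain(model, fm)
        assert rel.values.shape == fm.values.shape

    @staticmethod
    def _graded_model():
        from tests.conftest import make_graded_feature_cohort

        manifest, feats = make_graded_feature_cohort()
        # moderate fit: a saturated model flattens every deletion-based
        # importance signal, so agreement checks use early stopping
        config = pp.ModelConfig(lstm_units=8, epochs=15, batch_size=8, seed=1)
        model = pp.train_fold(
            [feats[t] for t in manifest.trial_id], manifest.group.to_numpy(),
            config=config,
        )
        return model, manifest, feats

    def test_method_agreement_lrp_vs_gradient_rank_correlation(self):
        model, manifest, feats = self._graded_model()
        corrs = []
        for tid in manifest[manifest.group == "mpne"].trial_id.iloc[:5]:
            a = pp.frame_importance(pp.lrp_explain(model, feats[tid])).values
            b = pp.frame_importance(pp.gradient_explain(model, feats[tid])).values
            corrs.append(stats.spearmanr(a, b).statistic)
        assert np.mean(corrs) > 0.7

    def test_occlusion_oracle_agreement(self):
        # leave-one-frame-out drop of the explained (pre-softmax) score
        # is an independent importance oracle; LRP must rank frames
        # consistently with it on a tiny model
        model, manifest, feats = self._graded_model()

        def logit(values):
            X = model._standardize(model._as_sequences([values]))
            return float(model.forward(X)[0, model.control_index])

        rhos = []
        for tid in manifest[manifest.group == "mpne"].trial_id.iloc[:5]:
            fm = feats[tid]
            imp = pp.frame_importance(pp.lrp_explain(model, fm)).values
            base = logit(fm.values)
            drops = []
            for t in range(fm.n_frames):
                occluded = fm.values.copy()
                occluded[:, t] = 0.0
                drops.append(abs(base - logit(occluded)))
            rhos.append(stats.spearmanr(imp, drops).statistic)
        assert np.mean(rhos) >= 0.6

    def test_planted_frames_dominate_importance(self, tiny_trained_lstm):
        # class is defined by bumps at frames 0, 11, 22, ...: the trained
        # model's relevance should put most planted frames among the top
        # importance peaks
        from pawprint.relevance import peak_frames

        model, manifest, feats = tiny_trained_lstm
        mpne_ids = manifest[manifest.group == "mpne"].trial_id
        curves = [
            pp.frame_importance(pp.lrp_explain(model, feats[t])).values
            for t in mpne_ids.iloc[:10]
        ]
        mean_curve = np.mean(curves, axis=0)
        n = len(mean_curve)
        planted = set(range(0, n, 11))
        top = set(peak_frames(mean_curve, top_fraction=(len(planted) + 1) / n))
        assert len(planted & top) / len(planted) >= 0.8


class TestFrameImportance:
    def test_zero_relevance_zero_importance(self):
        rel = pp.RelevanceMatrix(np.zeros((4, 9)), "control", "lrp-epsilon")
        imp = pp.frame_importance(rel)
        np.testing.assert_array_equal(imp.values, 0.0)

    def test_single_frame_relevance_gives_delta(self):
        values = np.zeros((4, 9))
        values[:, 0] = [1.0, -2.0, 0.5, 1.5]
        rel = pp.RelevanceMatrix(values, "control", "lrp-epsilon")
        imp = pp.frame_importance(rel, rule="abs_sum")
        assert imp.values[0] == pytest.approx(5.0)
        np.testing.assert_array_equal(imp.values[1:], 0.0)

    def test_aggregation_rules_differ_on_signed_input(self):
        values = np.array([[1.0, -1.0], [-1.0, -1.0]])
        rel = pp.RelevanceMatrix(values, "control", "lrp-epsilon")
        assert pp.frame_importance(rel, "abs_sum").values.tolist() == [2.0, 2.0]
        assert pp.frame_importance(rel, "signed_sum").values.tolist() == [0.0, -2.0]
        assert pp.frame_importance(rel, "positive_sum").values.tolist() == [1.0, 0.0]

    def test_unknown_rule_rejected(self):
        rel = pp.RelevanceMatrix(np.zeros((2, 2)), "control", "lrp-epsilon")
        with pytest.raises(ValueError, match="aggregation"):
            pp.frame_importance(rel, rule="max")


class TestGroupAverage:
    def test_identical_trials_zero_sem(self):
        imp = pp.FrameImportance(np.arange(5.0), "abs_sum")
        gi = pp.group_average_importance([imp, imp, imp, imp], ["a", "a", "b", "b"])
        np.testing.assert_array_equal(gi.groups["a"]["sem"], 0.0)

    def test_single_trial_group_mean_is_that_trial(self):
        a = pp.FrameImportance(np.array([1.0, 2.0, 3.0]), "abs_sum")
        b = pp.FrameImportance(np.array([3.0, 2.0, 1.0]), "abs_sum")
        gi = pp.group_average_importance([a, b], ["x", "y"])
        np.testing.assert_array_equal(gi.groups["x"]["mean"], a.values)
        np.testing.assert_array_equal(gi.difference, a.values - b.values)

    def test_mismatched_lengths_rejected(self):
        a = pp.FrameImportance(np.zeros(3), "abs_sum")
        b = pp.FrameImportance(np.zeros(4), "abs_sum")
        with pytest.raises(ValueError, match="mismatched"):
            pp.group_average_importance([a, b], ["x", "y"])


class TestPixelRelevance:
    def test_patch_relevance_lands_exactly_on_its_patch(self):
        be = pp.PatchFeatureBackend(grid_shape=(4, 5))
        rel = np.zeros(40)
        rel[7] = 2.0  # intensity feature of patch 7
        heat = pp.pixel_relevance(be, np.zeros((40, 50)), rel)
        mask = be.patch_mask(7, (40, 50))
        assert heat[mask].sum() == pytest.approx(2.0)
        assert np.all(heat[~mask] == 0.0)

    def test_zero_feature_relevance_zero_heatmap(self):
        be = pp.PatchFeatureBackend(grid_shape=(2, 2))
        heat = pp.pixel_relevance(be, np.zeros((8, 8)), np.zeros(8))
        np.testing.assert_array_equal(heat, 0.0)

    def test_heatmap_mass_concentrates_on_the_animal(self, small_cohort):
        _, _, trials = small_cohort
        trial = trials[0]
        frames = trial.render()
        be = pp.PatchFeatureBackend()
        fm = pp.extract_features(frames, be)
        # intensity features of the bright-on-black frame stand in for a
        # relevance column concentrated on the animal
        col = fm.values[:, 0].copy()
        col[be.spec.n_features // 2 :] = 0.0
        heat = np.abs(pp.pixel_relevance(be, frames.frames[0], col))
        ys, xs = np.nonzero(frames.frames[0] > 128)
        pad = 40
        box = np.zeros_like(heat, dtype=bool)
        box[max(ys.min() - pad, 0) : ys.max() + pad, max(xs.min() - pad, 0) : xs.max() + pad] = True
        assert heat[box].sum() / heat.sum() >= 0.6
        trial.frames = None
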