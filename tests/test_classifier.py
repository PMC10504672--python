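"""Random-forest bundle: balancing, routing, determinism, importance."""

import numpy as np
import pandas as pd
import pytest

from ptascrub.classifier import (
    COLUMNS_FULL,
    COLUMNS_NO_AI,
    COLUMNS_NO_AI_NO_RT,
    balanced_accuracy,
    artifact_probabilities,
    feature_importance,
    importance_and_ablation,
    load_bundle,
    save_bundle,
    train_rf,
)
from ptascrub.config import PipelineConfig
from ptascrub.features import FeatureVector
from ptascrub.simulate import simulate_candidates

FAST = PipelineConfig().replace(rf_n_trees=150)


@pytest.fixture(scope="module")
def sim_bundle():
    _v, vectors, truth = simulate_candidates(150, 150, 1.0, seed=3)
    labels = (truth.labels == "artifact").astype(int)
    return vectors, labels, train_rf(vectors, labels, seed=3, config=FAST)


def _fv(ai=-1.0, rt=20.0, mt="C>T", ctx=None, rng=None):
    rng = rng or np.random.default_rng(0)
    ctx = ctx or "".join(rng.choice(list("ACGT"), 20))
    return FeatureVector(ai, mt, ctx, float(rng.uniform(0, 1e5)),
                         float(rng.uniform(0, 1e5)), "plus", rt)


class TestTraining:
    def test_majority_class_subsampled_to_one_to_one(self):
        _v, vec_a, tru_a = simulate_candidates(0, 500, 1.0, seed=1,
                                               undefined_ai_fraction=0,
                                               undefined_rt_fraction=0)
        _v, vec_t, tru_t = simulate_candidates(200, 0, 1.0, seed=2,
                                               undefined_ai_fraction=0,
                                               undefined_rt_fraction=0)
        vectors = vec_a + vec_t
        labels = np.r_[np.ones(500, int), np.zeros(200, int)]
        bundle = train_rf(vectors, labels, seed=0, config=FAST)
        assert bundle.class_counts == {0: 200, 1: 200}
        assert len(bundle.training_labels) == 400

    def test_rows_with_undefined_features_excluded_from_training(self):
        vectors = [_fv(ai=None), _fv(rt=None), _fv(), _fv(ai=-3.0)]
        labels = [0, 1, 0, 1]
        bundle = train_rf(vectors * 10, labels * 10, seed=0, config=FAST)
        X = bundle.training_features
        assert not X[["ai_log_p", "replication_timing"]].isna().any().any()

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            train_rf([_fv(), _fv()], [1, 1], seed=0, config=FAST)

    def test_seeded_determinism(self):
        _v, vectors, truth = simulate_candidates(80, 80, 1.0, seed=5)
        labels = (truth.labels == "artifact").astype(int)
        b1 = train_rf(vectors, labels, seed=9, config=FAST)
        b2 = train_rf(vectors, labels, seed=9, config=FAST)
        assert np.array_equal(b1.oob_probabilities(), b2.oob_probabilities())

    def test_three_models_trained_on_identical_rows(self, sim_bundle):
        _, _, bundle = sim_bundle
        assert bundle.model_full.n_features_in_ == 26
        assert bundle.model_no_ai.n_features_in_ == 25
        assert bundle.model_no_ai_no_rt.n_features_in_ == 24


class TestScoring:
    def test_routing_by_defined_features(self, sim_bundle):
        _, _, bundle = sim_bundle
        rng = np.random.default_rng(1)
        full = _fv(rng=rng)
        no_ai = _fv(ai=None, rng=rng)
        no_rt = _fv(ai=None, rt=None, rng=rng)
        X_full = pd.DataFrame(
            [artifact_probabilities(bundle, [v])[0] for v in (full, no_ai, no_rt)]
        )
        # verify routing by comparing against each model called directly
        from ptascrub.features import encode_features

        enc = encode_features([full, no_ai, no_rt])
        assert X_full.iloc[0, 0] == pytest.approx(
            bundle.model_full.predict_proba(enc.iloc[[0]][COLUMNS_FULL])[0, 1]
        )
        assert X_full.iloc[1, 0] == pytest.approx(
            bundle.model_no_ai.predict_proba(enc.iloc[[1]][COLUMNS_NO_AI])[0, 1]
        )
        assert X_full.iloc[2, 0] == pytest.approx(
            bundle.model_no_ai_no_rt.predict_proba(enc.iloc[[2]][COLUMNS_NO_AI_NO_RT])[0, 1]
        )

    def test_probabilities_within_unit_interval(self, sim_bundle):
        _, _, bundle = sim_bundle
        rng = np.random.default_rng(2)
        vecs = [_fv(ai=float(rng.normal(-2, 3)), rt=float(rng.normal(40, 20)), rng=rng)
                for _ in range(50)]
        probs = artifact_probabilities(bundle, vecs)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_three_models_rank_correlated(self, sim_bundle):
        """Where all models apply, their probabilities agree strongly."""
        from scipy.stats import spearmanr

        vectors, _labels, bundle = sim_bundle
        defined = [v for v in vectors if v.ai_defined and v.rt_defined][:150]
        from ptascrub.features import encode_features

        enc = encode_features(defined)
        p_full = bundle.model_full.predict_proba(enc[COLUMNS_FULL])[:, 1]
        p_no_ai = bundle.model_no_ai.predict_proba(enc[COLUMNS_NO_AI])[:, 1]
        p_no_rt = bundle.model_no_ai_no_rt.predict_proba(enc[COLUMNS_NO_AI_NO_RT])[:, 1]
        assert spearmanr(p_full, p_no_ai).statistic > 0.8
        assert spearmanr(p_full, p_no_rt).statistic > 0.8

    def test_bundle_round_trip_and_schema_guard(self, sim_bundle, tmp_path):
        vectors, _, bundle = sim_bundle
        path = tmp_path / "bundle.joblib"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        assert np.array_equal(
            artifact_probabilities(loaded, vectors[:5]),
            artifact_probabilities(bundle, vectors[:5]),
        )
        import joblib

        payload = joblib.load(path)
        payload["schema_version"] = -1
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="schema"):
            load_bundle(path)


class TestImportance:
    def test_balanced_accuracy_formula(self):
        # TPR 0.8, TNR 0.6 -> 0.7
        y_true = np.r_[np.ones(10, int), np.zeros(10, int)]
        y_pred = np.r_[np.ones(8, int), np.zeros(2, int), np.ones(4, int), np.zeros(6, int)]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.7)

    def test_perfectly_predictive_feature_ranks_first(self):
        rng = np.random.default_rng(7)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 26)), columns=COLUMNS_FULL)
        y = rng.integers(0, 2, n)
        X["replication_timing"] = y * 10.0 + rng.normal(0, 0.01, n)
        bundle = train_rf(X, y, seed=7, config=FAST)
        assert feature_importance(bundle).index[0] == "replication_timing"

    def test_no_informative_features_gives_chance_accuracy(self):
        rng = np.random.default_rng(8)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 26)), columns=COLUMNS_FULL)
        y = rng.integers(0, 2, n)
        bundle = train_rf(X, y, seed=8, config=FAST)
        assert abs(bundle.oob_balanced_accuracy() - 0.5) < 0.1

    def test_ablation_curve_shape(self):
        rng = np.random.default_rng(9)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 26)), columns=COLUMNS_FULL)
        y = rng.integers(0, 2, n)
        X["ai_log_p"] = y * 5.0 + rng.normal(0, 0.1, n)
        cfg = PipelineConfig().replace(rf_n_trees=60)
        bundle = train_rf(X, y, seed=9, config=cfg)
        importance, curve = importance_and_ablation(bundle)
        assert list(curve["k"]) == list(range(26, 0, -1))
        # the informative feature survives to the very end
        assert curve["balanced_accuracy"].iloc[-1] > 0.9
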