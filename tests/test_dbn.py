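import numpy as np
import pytest

from cardiodbn.dbn import (
    DBNModel,
    GrowthConfig,
    candidate_hidden_units,
    finetune,
    grow_pretrain,
    layers_to_keep,
    load_model,
    model_from_dict,
    model_to_dict,
    predict_label,
    predict_proba,
    save_model,
    select_hidden_units,
)
from cardiodbn.rbm import RBMParams, TrainConfig


def quick_config(seed=0, **kw):
    return GrowthConfig(rbm_config=TrainConfig(seed=seed), **kw)


class TestCandidateWidths:
    @pytest.mark.parametrize("m, n, rng_, expected", [
        (13, 1, (1, 5), [5, 6, 7, 8, 9]),
        (1, 1, (1, 5), [2, 3, 4, 5, 6]),
        (13, 1, (1, 1), [5]),
        (9, 4, (1, 2), [7, 8]),
    ])
    def test_sqrt_heuristic(self, m, n, rng_, expected):
        assert candidate_hidden_units(m, n, rng_) == expected

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            candidate_hidden_units(0, 1)


class TestWidthSelection:
    def test_single_candidate_returned(self, rng):
        data = rng.random((30, 4))
        best, errs, params = select_hidden_units(data, [3], TrainConfig(seed=1))
        assert best == 3
        assert params.n_hidden == 3

    def test_error_table_complete_and_nonnegative(self, rng):
        data = rng.random((40, 5))
        cands = [2, 3, 4]
        best, errs, _ = select_hidden_units(data, cands, TrainConfig(seed=2))
        assert sorted(errs) == cands
        assert all(e >= 0 for e in errs.values())
        assert errs[best] == min(errs.values())

    def test_recovers_at_least_factor_count(self):
        """On data driven by exactly c binary latent factors the chosen
        width should be >= c in the majority of seeded trials."""
        c, m, wins, trials = 3, 6, 0, 20
        for s in range(trials):
            rng = np.random.default_rng(1000 + s)
            factors = rng.integers(0, 2, size=(80, c))
            X = factors[:, np.arange(m) % c].astype(float)
            flip = rng.random(X.shape) < 0.05
            X = np.abs(X - flip)
            cands = candidate_hidden_units(m, 1, (-2, 2))  # widths 1..5
            best, _, _ = select_hidden_units(X, cands, TrainConfig(seed=s))
            wins += best >= c
        assert wins > trials / 2


class TestDepthRule:
    def test_scripted_trace_keeps_two_layers(self):
        assert layers_to_keep([1.00, 0.50, 0.48], epsilon=0.03) == 2

    def test_immediate_stop_keeps_one_layer(self):
        assert layers_to_keep([0.30, 0.29], epsilon=0.03) == 1

    def test_keep_stopping_layer_variant(self):
        assert layers_to_keep([1.00, 0.50, 0.48], 0.03,
                              keep_stopping_layer=True) == 3

    def test_all_large_improvements_keep_everything(self):
        assert layers_to_keep([1.0, 0.8, 0.6, 0.4], epsilon=0.03) == 4

    def test_empty_trace(self):
        assert layers_to_keep([], epsilon=0.03) == 0


class TestGrowth:
    def test_always_at_least_one_layer(self, encoded_synthetic):
        X, _ = encoded_synthetic
        model, trace = grow_pretrain(X[:100], quick_config(seed=4))
        assert len(model.layers) >= 1
        assert model.depth == len(model.layers) + 1

    def test_kept_errors_strictly_decreasing(self, encoded_synthetic):
        X, _ = encoded_synthetic
        _, trace = grow_pretrain(X, quick_config(seed=5))
        diffs = np.diff(trace.r_errors)
        assert np.all(diffs < 0)

    def test_depth_monotone_in_epsilon(self, encoded_synthetic):
        X, _ = encoded_synthetic
        depths = []
        for eps in (0.01, 0.02, 0.03, 0.04, 0.05):
            model, _ = grow_pretrain(X, quick_config(seed=6, epsilon=eps))
            depths.append(model.depth)
        assert all(b <= a for a, b in zip(depths, depths[1:]))

    def test_forced_depth_ignores_epsilon(self, encoded_synthetic):
        X, _ = encoded_synthetic
        model, trace = grow_pretrain(X, quick_config(seed=7), forced_layers=3)
        assert len(model.layers) == 3
        assert len(trace.r_errors) == 3

    def test_architecture_string(self, encoded_synthetic):
        X, _ = encoded_synthetic
        model, _ = grow_pretrain(X, quick_config(seed=8), forced_layers=2)
        widths = model.architecture.split("-")
        assert widths[0] == "13"
        assert len(widths) == 3

    def test_epsilon_outside_band_warns(self):
        with pytest.warns(UserWarning):
            quick_config(epsilon=0.5)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            grow_pretrain(np.empty((0, 5)), quick_config())


def separable_problem(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2))
    y = (X[:, 0] > X[:, 1]).astype(int)
    return X, y


class TestFinetune:
    def test_zero_epochs_is_identity(self, encoded_synthetic):
        X, y = encoded_synthetic
        cfg = quick_config(seed=9, head_epochs=0)
        model, _ = grow_pretrain(X[:80], cfg, forced_layers=1)
        tuned = finetune(model, X[:80], y[:80], cfg)
        np.testing.assert_array_equal(tuned.layers[0].w, model.layers[0].w)

    def test_reaches_perfect_accuracy_on_separable_data(self):
        X, y = separable_problem(seed=3)
        cfg = quick_config(seed=3, head_epochs=500, head_learning_rate=2.0,
                           finetune_val_fraction=0.0)
        model, _ = grow_pretrain(X, cfg, forced_layers=1)
        tuned = finetune(model, X, y, cfg)
        assert np.mean(predict_label(tuned, X) == y) == 1.0

    def test_training_loss_non_increasing_for_small_rate(self, encoded_synthetic):
        X, y = encoded_synthetic
        cfg = quick_config(seed=10, head_epochs=60, head_learning_rate=0.05,
                           finetune_val_fraction=0.0)
        model, _ = grow_pretrain(X[:120], cfg, forced_layers=1)
        losses = []
        finetune(model, X[:120], y[:120], cfg,
                 loss_callback=lambda e, ce: losses.append(ce))
        assert all(b <= a + 1e-10 for a, b in zip(losses, losses[1:]))

    def test_topology_unchanged(self, encoded_synthetic):
        X, y = encoded_synthetic
        cfg = quick_config(seed=11, head_epochs=40)
        model, _ = grow_pretrain(X[:100], cfg)
        tuned = finetune(model, X[:100], y[:100], cfg)
        assert tuned.architecture == model.architecture

    def test_label_mismatch_rejected(self, encoded_synthetic):
        X, y = encoded_synthetic
        cfg = quick_config(seed=12)
        model, _ = grow_pretrain(X[:50], cfg, forced_layers=1)
        with pytest.raises(ValueError):
            finetune(model, X[:50], y[:49], cfg)


@pytest.fixture(scope="module")
def tuned(encoded_synthetic):
    X, y = encoded_synthetic
    cfg = quick_config(seed=13, head_epochs=100)
    model, _ = grow_pretrain(X, cfg, forced_layers=2)
    return finetune(model, X, y, cfg), X


class TestPrediction:
    def test_probabilities_strictly_inside_unit_interval(self, tuned):
        model, X = tuned
        p = predict_proba(model, X)
        assert np.all((p > 0) & (p < 1))

    def test_row_permutation_equivariance(self, tuned):
        model, X = tuned
        perm = np.random.default_rng(0).permutation(X.shape[0])
        np.testing.assert_allclose(
            predict_proba(model, X)[perm], predict_proba(model, X[perm])
        )

    def test_zero_weight_model_outputs_half(self):
        layer = RBMParams(w=np.zeros((4, 3)), a=np.zeros(4), b=np.zeros(3))
        model = DBNModel(layers=[layer], head_w=np.zeros(3), head_b=0.0)
        np.testing.assert_allclose(predict_proba(model, np.zeros((5, 4))), 0.5)

    def test_thresholds(self, tuned):
        model, X = tuned
        p = predict_proba(model, X)
        assert np.array_equal(predict_label(model, X, 0.0), np.ones(len(p), int))
        assert predict_label(model, X, 1.0).sum() == np.sum(p >= 1.0)
        np.testing.assert_array_equal(
            predict_label(model, X, 0.5), (p >= 0.5).astype(int)
        )

    def test_dimension_mismatch_rejected(self, tuned):
        model, X = tuned
        with pytest.raises(ValueError):
            predict_proba(model, X[:, :5])


def test_model_serialization_round_trip(tmp_path, encoded_synthetic):
    X, y = encoded_synthetic
    cfg = quick_config(seed=14, head_epochs=30)
    model, _ = grow_pretrain(X[:100], cfg)
    model = finetune(model, X[:100], y[:100], cfg)
    path = tmp_path / "model.json"
    save_model(model, path)
    restored = load_model(path)
    assert restored.architecture == model.architecture
    assert restored.trace.r_errors == model.trace.r_errors
    np.testing.assert_allclose(
        predict_proba(restored, X[:20]), predict_proba(model, X[:20])
    )


def test_model_dict_rejects_mismatched_chain():
    a = RBMParams(w=np.zeros((3, 2)), a=np.zeros(3), b=np.zeros(2))
    b = RBMParams(w=np.zeros((4, 2)), a=np.zeros(4), b=np.zeros(2))
    with pytest.raises(ValueError):
        DBNModel(layers=[a, b], head_w=np.zeros(2), head_b=0.0)
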