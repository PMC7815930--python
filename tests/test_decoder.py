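import numpy as np
import pytest

import fnirsflow as ff
from fnirsflow.decoder import (VARIANT_FILTERS, TrainingError, build_network,
                               save_model, load_model)
from fnirsflow.hemodynamics import ConfigError, DataError
from fnirsflow.paradigm import EpochWindow

from conftest import make_separable_tensors


def loop_conv(x, kernels):
    """Brute-force same-padded temporal convolution oracle."""
    t, c = x.shape
    h, _, f = kernels.shape
    pad = h // 2
    xp = np.zeros((t + 2 * pad, c))
    xp[pad:pad + t] = x
    out = np.zeros((t, f))
    for i in range(t):
        for j in range(f):
            acc = 0.0
            for k in range(h):
                for ci in range(c):
                    acc += xp[i + k, ci] * kernels[k, ci, j]
            out[i, j] = acc
    return out


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(-1, 0), (2, 2), (0, 0)])
    def test_scalar_branches(self, x, expected):
        assert ff.relu(x) == expected

    def test_elementwise(self):
        assert np.array_equal(ff.relu(np.array([-2.0, 3.0])), [0.0, 3.0])


class TestTemporalConv:
    def test_delta_kernel_is_identity(self):
        x = np.arange(8.0)[:, None]
        k = np.zeros((3, 1, 1))
        k[1, 0, 0] = 1.0
        assert np.allclose(ff.temporal_conv(x, k), x)

    def test_hand_convolution(self):
        x = np.array([0.0, 1.0, 0.0, 0.0])[:, None]
        k = np.ones((3, 1, 1))
        assert np.allclose(ff.temporal_conv(x, k)[:, 0], [1, 1, 1, 0])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(11, 5))
        k = rng.normal(size=(3, 5, 4))
        assert np.allclose(ff.temporal_conv(x, k), loop_conv(x, k), atol=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(DataError):
            ff.temporal_conv(np.zeros((4, 2)), np.zeros((3, 3, 1)))


class TestMaxPool:
    def test_definition(self):
        assert np.allclose(ff.max_pool(np.array([1.0, 3.0, 2.0, 5.0])[:, None])[:, 0],
                           [3, 5])

    def test_printed_length_halving(self):
        assert ff.max_pool(np.zeros((208, 12))).shape == (104, 12)

    def test_odd_trailing_sample_dropped(self):
        out = ff.max_pool(np.arange(5.0)[:, None])
        assert np.allclose(out[:, 0], [1, 3])

    def test_constant_preserved(self):
        assert np.allclose(ff.max_pool(np.full((6, 2), 4.2)), 4.2)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            ff.max_pool(np.zeros((1, 2)))


TABLE3_ROWS = [
    ("Convolutional layer 1", (208, 24), (208, 12)),
    ("Max-pooling 1", (208, 12), (104, 12)),
    ("Dropout 1", (104, 12), (104, 12)),
    ("Convolutional layer 2", (104, 12), (104, 12)),
    ("Max-pooling 2", (104, 12), (52, 12)),
    ("Dropout 2", (52, 12), (52, 12)),
    ("Convolutional layer 3", (52, 12), (52, 12)),
    ("Max-pooling 3", (52, 12), (26, 12)),
    ("Dropout 3", (26, 12), (26, 12)),
    ("Fully connected layer 1", 312, 52),
    ("Fully connected layer 2", 52, 26),
    ("Output layer", 26, 3),
]


class TestShapeReport:
    def test_compat_mode_reproduces_printed_table(self):
        spec = ff.NetworkSpec(variant="CNN3-a", compat_table3=True)
        assert ff.shape_report(spec, (208, 24)) == TABLE3_ROWS

    def test_standard_mode_cnn3b(self):
        spec = ff.NetworkSpec(variant="CNN3-b")
        rows = ff.shape_report(spec, (208, 24))
        assert rows[0][2] == (208, 16)
        assert rows[-3][1] == 26 * 16  # flatten 416

    def test_standard_mode_cnn1a_short_input(self):
        spec = ff.NetworkSpec(variant="CNN1-a")
        rows = ff.shape_report(spec, (16, 24))
        assert rows[1][2] == (8, 8)
        assert rows[-3][1] == 64

    def test_input_too_short_for_pooling(self):
        spec = ff.NetworkSpec(variant="CNN3-a")
        with pytest.raises(ConfigError):
            ff.shape_report(spec, (4, 24))

    @pytest.mark.parametrize("variant", sorted(VARIANT_FILTERS))
    @pytest.mark.parametrize("compat", [False, True])
    def test_consistent_with_forward_pass(self, variant, compat):
        spec = ff.NetworkSpec(variant=variant, compat_table3=compat)
        m = 64
        rows = ff.shape_report(spec, (m, 24))
        model = build_network(spec, (m, 24), init_seed=0)
        x = np.random.default_rng(1).normal(size=(2, m, 24))
        out = x
        ri = 0
        for layer in model.blocks[:model._n_feature_layers]:
            prev_shape = out.shape[1:]
            out = layer.forward(out, False, None)
            if layer.__class__.__name__ in ("_Conv", "_MaxPool", "_Dropout"):
                name, ishape, oshape = rows[ri]
                assert tuple(ishape) == tuple(prev_shape)
                assert tuple(oshape) == tuple(out.shape[1:])
                ri += 1
        assert rows[ri][1] == out.shape[1]  # flatten feeds FC1


class TestBuildNetwork:
    def test_softmax_output_normalized(self):
        spec = ff.NetworkSpec(variant="CNN2-a")
        model = build_network(spec, (32, 24), init_seed=0)
        x = np.random.default_rng(0).normal(size=(3, 32, 24))
        p = model.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_seeded_initialization_deterministic(self):
        spec = ff.NetworkSpec(variant="CNN1-a")
        a = build_network(spec, (16, 24), init_seed=9)
        b = build_network(spec, (16, 24), init_seed=9)
        for (pa, _), (pb, _) in zip(a.parameters, b.parameters):
            assert np.array_equal(pa, pb)

    def test_inference_deterministic_dropout_off(self):
        spec = ff.NetworkSpec(variant="CNN2-a", dropout_rate=0.5)
        model = build_network(spec, (32, 24), init_seed=2)
        x = np.random.default_rng(3).normal(size=(4, 32, 24))
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_forward_equals_functional_composition(self):
        # layer-by-layer brute-force oracle through a 2-conv-layer network
        spec = ff.NetworkSpec(variant="CNN2-a", dropout_rate=0.0)
        model = build_network(spec, (20, 24), init_seed=4)
        x = np.random.default_rng(5).normal(size=(20, 24))
        out = x
        for li in range(2):
            conv = model.blocks[4 * li]
            out = ff.relu(ff.temporal_conv(out, conv.w[0]) + conv.b[0])
            out = ff.max_pool(out, 2)
        out = out.reshape(-1)
        for dense_i, act in ((model._n_feature_layers, True),
                             (model._n_feature_layers + 2, True),
                             (model._n_feature_layers + 4, False)):
            d = model.blocks[dense_i]
            out = out @ d.w + d.b
            if act:
                out = ff.relu(out)
        assert np.allclose(out, model.logits(x)[0], atol=1e-6)


class TestTensorize:
    def test_window_shape(self, small_hemo):
        t = ff.tensorize(small_hemo, [EpochWindow(0, 208, 0, "like")])
        assert t[0].matrix.shape == (208, 24)

    def test_zero_series_gives_zero_tensors(self):
        hemo = ff.HemoSeries(np.zeros((50, 12)), np.zeros((50, 12)))
        t = ff.tensorize(hemo, [EpochWindow(0, 30, 0, "like")])
        assert np.count_nonzero(t[0].matrix) == 0

    def test_out_of_bounds_rejected(self, small_hemo):
        with pytest.raises(DataError):
            ff.tensorize(small_hemo, [EpochWindow(300, 200, 0, "like")])

    def test_column_order_hbo_then_hbr(self, small_hemo):
        t = ff.tensorize(small_hemo, [EpochWindow(5, 10, 0, "like")])[0]
        assert np.array_equal(t.matrix[:, :12], small_hemo.dhbo[5:15])
        assert np.array_equal(t.matrix[:, 12:], small_hemo.dhbr[5:15])

    def test_zscore_on_fit_set(self, small_hemo):
        tensors = ff.tensorize(small_hemo, [EpochWindow(i * 40, 40, i, "like")
                                            for i in range(5)])
        stats = ff.zscore_fit(tensors)
        normed = ff.zscore_apply(tensors, stats)
        stacked = np.concatenate([t.matrix for t in normed])
        assert np.allclose(stacked.mean(axis=0), 0, atol=1e-6)
        assert np.allclose(stacked.std(axis=0), 1, atol=1e-6)


class TestAugmentWindows:
    def test_full_phase_gives_one_window(self, small_hemo):
        out = ff.augment_windows(small_hemo, [EpochWindow(0, 100, 0, "like")],
                                 window_len=100, stride=7)
        assert len(out) == 1

    def test_stride_count_formula(self, small_hemo):
        out = ff.augment_windows(small_hemo, [EpochWindow(0, 234, 0, "like")],
                                 window_len=208, stride=13)
        assert len(out) == 3  # starts 0, 13, 26

    def test_windows_stay_inside_trial(self, small_hemo):
        wins = [EpochWindow(0, 150, 0, "like"), EpochWindow(200, 150, 1, "dislike")]
        out = ff.augment_windows(small_hemo, wins, window_len=64, stride=20)
        for t in out:
            assert t.label in ("like", "dislike")
        assert {t.trial_index for t in out} == {0, 1}

    def test_nonpositive_stride_rejected(self, small_hemo):
        with pytest.raises(ConfigError):
            ff.augment_windows(small_hemo, [EpochWindow(0, 100, 0, "like")], 50, 0)

    def test_max_per_trial_cap(self, small_hemo):
        out = ff.augment_windows(small_hemo, [EpochWindow(0, 234, 0, "like")],
                                 window_len=100, stride=10, max_per_trial=4)
        assert len(out) == 4


class TestTrain:
    def test_separable_data_reaches_full_training_accuracy(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        cfg = ff.TrainConfig(epochs=30, batch_size=8, learning_rate=0.001, seed=0)
        fitted = ff.train(separable_tensors, spec, cfg, classes=("dislike", "like"))
        preds = ff.predict(fitted, separable_tensors)
        assert ff.accuracy(preds, [t.label for t in separable_tensors]) == 100.0

    def test_loss_log_finite_and_decreasing_overall(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        cfg = ff.TrainConfig(epochs=20, batch_size=8, learning_rate=0.001, seed=1)
        fitted = ff.train(separable_tensors, spec, cfg, classes=("dislike", "like"))
        assert np.all(np.isfinite(fitted.loss_log))
        assert fitted.loss_log[-1] <= fitted.loss_log[0]

    def test_single_class_rejected(self):
        tensors = make_separable_tensors(classes=("like",))
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        with pytest.raises(TrainingError):
            ff.train(tensors, spec, ff.TrainConfig(epochs=1), classes=("dislike", "like"))

    def test_training_deterministic_given_seed(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        cfg = ff.TrainConfig(epochs=3, batch_size=8, learning_rate=0.001, seed=7)
        a = ff.train(separable_tensors, spec, cfg, classes=("dislike", "like"))
        b = ff.train(separable_tensors, spec, cfg, classes=("dislike", "like"))
        assert a.loss_log == b.loss_log
        for (pa, _), (pb, _) in zip(a.model.parameters, b.model.parameters):
            assert np.array_equal(pa, pb)

    def test_paper_beta2_selectable(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        cfg = ff.TrainConfig(epochs=5, batch_size=8, learning_rate=0.001,
                             adam_beta2=0.1, seed=0)
        fitted = ff.train(separable_tensors, spec, cfg, classes=("dislike", "like"))
        assert np.all(np.isfinite(fitted.loss_log))


class TestGridSearch:
    def test_single_point_grid_returned(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        base = ff.TrainConfig(epochs=2, batch_size=8, learning_rate=0.001)
        best, scores = ff.grid_search(separable_tensors, spec,
                                      {"batch_size": [8], "learning_rate": [0.001]},
                                      k=4, seed=0, classes=("dislike", "like"),
                                      base=base)
        assert (best.batch_size, best.learning_rate) == (8, 0.001)
        assert len(scores) == 1

    def test_best_score_is_table_max_and_duplicates_tie(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        base = ff.TrainConfig(epochs=2, batch_size=8, learning_rate=0.001)
        best, scores = ff.grid_search(separable_tensors, spec,
                                      {"batch_size": [8, 8], "learning_rate": [0.001]},
                                      k=4, seed=0, classes=("dislike", "like"),
                                      base=base)
        accs = [s["mean_accuracy"] for s in scores]
        assert accs[0] == accs[1]  # identical grid points score identically
        assert max(accs) == accs[0]

    def test_empty_grid_rejected(self, separable_tensors):
        spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
        with pytest.raises(ConfigError):
            ff.grid_search(separable_tensors, spec, {"batch_size": []}, k=4, seed=0)


def test_model_roundtrip_serialization(tmp_path, separable_tensors):
    spec = ff.NetworkSpec(variant="CNN1-a", n_classes=2)
    cfg = ff.TrainConfig(epochs=2, batch_size=8, learning_rate=0.001, seed=0)
    fitted = ff.train(separable_tensors, spec, cfg, classes=("dislike", "like"))
    path = tmp_path / "model.npz"
    save_model(fitted, path)
    loaded = load_model(path)
    x = np.stack([t.matrix for t in separable_tensors[:3]])
    assert np.allclose(loaded.model.predict_proba(x), fitted.model.predict_proba(x))
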