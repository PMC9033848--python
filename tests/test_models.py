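import numpy as np
import pytest

from frpbp.models import (
    FusionShapeError,
    LayerSpec,
    ModelConfig,
    TrainConfig,
    TwoStreamRegressor,
    build_1d_stream,
    build_2d_stream,
    build_concat_model,
    build_single_model,
    fuse,
    load_model,
    predict,
    train_model,
)

SMALL = ModelConfig(window=64, side=32, filters_1d=(2, 2, 2, 2, 2),
                    filters_2d=(2, 2, 2, 2, 2, 2, 2), head_units=(8,), dropout=0.1)


def brute_fuse(a, b, method, filters=None, bias=None):
    h, w, n = a.shape
    if method == "sum":
        out = np.zeros_like(a)
        for i in range(h):
            for j in range(w):
                for k in range(n):
                    out[i, j, k] = a[i, j, k] + b[i, j, k]
        return out
    if method == "max":
        out = np.zeros_like(a)
        for i in range(h):
            for j in range(w):
                for k in range(n):
                    out[i, j, k] = max(a[i, j, k], b[i, j, k])
        return out
    cat = np.zeros((h, w, 2 * n))
    for i in range(h):
        for j in range(w):
            for k in range(n):
                cat[i, j, k] = a[i, j, k]
                cat[i, j, n + k] = b[i, j, k]
    if method == "concat":
        return cat
    out = np.zeros((h, w, n))
    for i in range(h):
        for j in range(w):
            for k in range(n):
                out[i, j, k] = bias[k] + sum(
                    cat[i, j, m] * filters[0, 0, m, k] for m in range(2 * n)
                )
    return out


def shape_calc_1d(specs, window):
    """Independent symbolic propagation: (channels, length)."""
    ch, ln = 1, window
    for s in specs:
        if s.kind == "conv1d":
            ch = s.filters  # stride-1 same-padding keeps length
        elif s.kind == "avgpool":
            ln = ln // s.pool
        elif s.kind == "flatten":
            return ch * ln
    return ch, ln


def shape_calc_2d(specs, side):
    ch, h, w = 1, side, side
    for s in specs:
        if s.kind == "conv2d":
            ch = s.filters
        elif s.kind == "avgpool":
            h, w = h // s.pool, w // s.pool
        elif s.kind == "flatten":
            return ch * h * w
    return ch, h, w


class TestFuse:
    def test_hand_examples_on_two_channel_maps(self):
        a = np.array([[[1.0, 2.0]]])
        b = np.array([[[3.0, 4.0]]])
        np.testing.assert_array_equal(fuse(a, b, "sum")[0, 0], [4, 6])
        np.testing.assert_array_equal(fuse(a, b, "max")[0, 0], [3, 4])
        np.testing.assert_array_equal(fuse(a, b, "concat")[0, 0], [1, 2, 3, 4])

    def test_identity_filter_conv_fusion_returns_first_map(self, rng):
        a = rng.standard_normal((3, 4, 2))
        b = rng.standard_normal((3, 4, 2))
        f = np.zeros((1, 1, 4, 2))
        f[0, 0, 0, 0] = f[0, 0, 1, 1] = 1.0  # select the first N stacked channels
        np.testing.assert_allclose(fuse(a, b, "conv", filters=f), a, atol=1e-12)

    def test_max_fusion_idempotent(self, rng):
        a = rng.standard_normal((2, 3, 4))
        np.testing.assert_array_equal(fuse(a, a, "max"), a)

    def test_shape_mismatch_names_both_shapes(self, rng):
        with pytest.raises(FusionShapeError, match=r"\(2, 2, 1\).*\(2, 3, 1\)"):
            fuse(np.zeros((2, 2, 1)), np.zeros((2, 3, 1)), "sum")

    @pytest.mark.parametrize("method", ["sum", "max", "concat", "conv"])
    def test_matches_brute_force_loops(self, method, rng):
        for _ in range(25):
            h, w, n = (int(v) for v in rng.integers(1, 5, size=3))
            a = rng.standard_normal((h, w, n))
            b = rng.standard_normal((h, w, n))
            if method == "conv":
                f = rng.standard_normal((1, 1, 2 * n, n))
                bias = rng.standard_normal(n)
                got = fuse(a, b, method, filters=f, bias=bias)
                np.testing.assert_allclose(got, brute_fuse(a, b, method, f, bias), atol=1e-6)
            else:
                np.testing.assert_array_equal(fuse(a, b, method), brute_fuse(a, b, method))


class TestStreamBuilders:
    def test_1d_kernels_all_25_by_default(self):
        specs = build_1d_stream(ModelConfig())
        kernels = [s.kernel for s in specs if s.kind == "conv1d"]
        assert kernels == [25] * 6

    def test_1d_flattened_width_matches_shape_oracle(self):
        cfg = ModelConfig()
        specs = build_1d_stream(cfg)
        # brute-force propagation: 1024 -> 512 -> 256 -> 128 -> 64, 128 channels
        assert shape_calc_1d(specs, cfg.window) == 128 * 64

    def test_1d_rejects_zero_filters(self):
        with pytest.raises(ValueError, match="positive"):
            build_1d_stream(ModelConfig(filters_1d=(32, 0, 64, 64, 128, 128)))

    def test_1d_rejects_collapsing_window(self):
        with pytest.raises(ValueError, match="window"):
            build_1d_stream(ModelConfig(window=8))

    def test_2d_has_exactly_7_convs(self):
        specs = build_2d_stream(ModelConfig())
        assert sum(s.kind == "conv2d" for s in specs) == 7

    def test_2d_pool_placement_after_first_five_relus_only(self):
        specs = build_2d_stream(ModelConfig())
        pools = sum(s.kind == "avgpool" for s in specs)
        assert pools == 5
        assert specs[-1].kind == "flatten"
        assert specs[-2].kind == "relu"  # no pool after the last relu

    def test_2d_floor_chain_88_to_2(self):
        cfg = ModelConfig(side=88)
        specs = build_2d_stream(cfg)
        # 88 -> 44 -> 22 -> 11 -> 5 -> 2 under floor-halving
        assert shape_calc_2d(specs, 88) == 128 * 2 * 2

    def test_2d_rejects_small_side(self):
        with pytest.raises(ValueError, match="side"):
            build_2d_stream(ModelConfig(side=16))


class TestModelAssembly:
    def test_default_fusion_is_concatenation(self):
        spec = build_concat_model(ModelConfig())
        assert spec.fusion == "concat"

    def test_head_ends_in_single_linear_unit(self):
        spec = build_concat_model(SMALL)
        dense = [s for s in spec.head if s.kind == "dense"]
        assert dense[-1].units == 1

    def test_separate_targets_produce_distinct_specs(self):
        sbp = build_concat_model(ModelConfig(target="sbp"))
        dbp = build_concat_model(ModelConfig(target="dbp"))
        assert sbp.target == "sbp" and dbp.target == "dbp"

    def test_param_count_contains_both_streams(self):
        model = TwoStreamRegressor(build_concat_model(SMALL), seed=0)
        only_1d = TwoStreamRegressor(build_single_model(SMALL, "1d"), seed=0)
        only_2d = TwoStreamRegressor(build_single_model(SMALL, "2d"), seed=0)
        conv_params = sum(
            layer.params[p].size
            for src in (only_1d.stream_1d, only_2d.stream_2d)
            for _, layer, p in src.named_params()
        )
        assert model.n_params() >= conv_params

    def test_network_forward_shapes_match_oracle(self, rng):
        model = TwoStreamRegressor(build_concat_model(SMALL), seed=0)
        x1 = rng.standard_normal((3, 1, SMALL.window)).astype(np.float32)
        x2 = rng.standard_normal((3, 1, SMALL.side, SMALL.side)).astype(np.float32)
        f1 = model.stream_1d.forward(x1, False)
        f2 = model.stream_2d.forward(x2, False)
        assert f1.shape[1] == shape_calc_1d(build_1d_stream(SMALL), SMALL.window)
        assert f2.shape[1] == shape_calc_2d(build_2d_stream(SMALL), SMALL.side)

    @pytest.mark.parametrize("fusion", ["sum", "max", "conv"])
    def test_equal_width_fusions_require_matching_streams(self, fusion):
        with pytest.raises(FusionShapeError):
            build_concat_model(ModelConfig(**{**SMALL.__dict__, "fusion": fusion}))


def tiny_dataset(rng, n=64, window=64, side=32):
    x1 = rng.standard_normal((n, window))
    x2 = rng.random((n, side, side))
    # target is a simple function of the sequence so learning is possible
    y = 100.0 + 20.0 * x1[:, :8].mean(axis=1)
    return x1, x2, y


class TestTraining:
    def test_two_epoch_smoke_records_history(self, rng):
        data = tiny_dataset(rng)
        val = tiny_dataset(rng, n=16)
        model, history = train_model(
            build_concat_model(SMALL), data, val,
            TrainConfig(batch=16, max_epochs=2, seed=0),
        )
        assert len(history) == 2
        assert {"epoch", "train_loss", "val_loss"} <= set(history[0])

    def test_same_seed_identical_history(self, rng):
        data = tiny_dataset(rng)
        val = tiny_dataset(rng, n=16)
        hyper = TrainConfig(batch=16, max_epochs=2, seed=7)
        _, h1 = train_model(build_concat_model(SMALL), data, val, hyper)
        _, h2 = train_model(build_concat_model(SMALL), data, val, hyper)
        assert [r["train_loss"] for r in h1] == [r["train_loss"] for r in h2]

    def test_empty_split_rejected(self, rng):
        data = tiny_dataset(rng)
        empty = (np.zeros((0, 64)), np.zeros((0, 32, 32)), np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            train_model(build_concat_model(SMALL), data, empty, TrainConfig(max_epochs=1))

    def test_save_load_reproduces_predictions(self, rng, tmp_path):
        data = tiny_dataset(rng)
        val = tiny_dataset(rng, n=16)
        model, _ = train_model(build_concat_model(SMALL), data, val,
                               TrainConfig(batch=16, max_epochs=2, seed=1))
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = load_model(path)
        a = model.predict(val[0], val[1])
        b = reloaded.predict(val[0], val[1])
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_batch_of_one_equals_scalar_call(self, rng):
        data = tiny_dataset(rng)
        val = tiny_dataset(rng, n=16)
        model, _ = train_model(build_concat_model(SMALL), data, val,
                               TrainConfig(batch=16, max_epochs=1, seed=2))
        scalar = predict(model, val[0][0], val[1][0])
        batch = predict(model, val[0][:1], val[1][:1])
        assert scalar == pytest.approx(float(batch[0]), abs=1e-6)
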