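"""Network architecture: 1-D stream, 2-D stream, fusion, two-stream regressor.

The estimator couples two convolutional feature extractors: a 1-D stream
over the raw pulse window (kernel length 25 throughout, conv -> batchnorm ->
ReLU blocks, average pooling after the first four blocks, dropout after the
last two) and a 2-D stream over the fuzzy recurrence plot (exactly seven 3x3
conv -> batchnorm -> ReLU blocks, 2x2 average pooling after all ReLUs except
the last two). The flattened stream outputs are fused — by channel
concatenation by default, with sum, max and learnable 1x1-conv fusion also
available — and passed to a dense head ending in a single linear unit.
Separate models are fitted for systolic and diastolic pressure.

Training minimises mean squared error with Adam (batch 100, learning rate
0.001 by default) with early stopping on validation loss; inputs are
per-segment z-scored and targets z-scored on training statistics.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "LayerSpec", "ModelSpec", "ModelConfig", "TrainConfig", "FusionShapeError",
    "TrainingDivergedError", "fuse", "build_1d_stream", "build_2d_stream",
    "build_concat_model", "build_single_model", "TwoStreamRegressor",
    "train_model", "predict", "load_model",
]

FUSIONS = ("sum", "max", "concat", "conv")


class FusionShapeError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer."""

    kind: str  # conv1d | conv2d | batchnorm | relu | avgpool | dropout | flatten | dense
    kernel: int | tuple[int, int] | None = None
    filters: int | None = None
    pool: int | None = None
    rate: float | None = None
    units: int | None = None


@dataclass(frozen=True)
class ModelSpec:
    stream_1d: tuple[LayerSpec, ...]
    stream_2d: tuple[LayerSpec, ...]
    fusion: str
    head: tuple[LayerSpec, ...]
    target: str  # "sbp" | "dbp"
    window: int
    side: int
    streams: str = "both"  # "both" | "1d" | "2d"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs; defaults follow the published configuration."""

    window: int = 1024
    side: int = 88
    kernel_1d: int = 25
    filters_1d: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    kernel_2d: int = 3
    filters_2d: tuple[int, ...] = (16, 32, 32, 64, 64, 128, 128)
    fusion: str = "concat"
    head_units: tuple[int, ...] = (256, 64)
    dropout: float = 0.25
    target: str = "sbp"

    @classmethod
    def small(cls, target: str = "sbp") -> "ModelConfig":
        """Reduced-width profile for single-CPU experiments."""
        return cls(
            window=512,
            side=32,
            filters_1d=(8, 8, 16, 16, 32, 32),
            filters_2d=(4, 8, 8, 16, 16, 32, 32),
            target=target,
        )


@dataclass(frozen=True)
class TrainConfig:
    batch: int = 100
    lr: float = 1e-3
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0


def fuse(a: np.ndarray, b: np.ndarray, method: str,
         filters: np.ndarray | None = None, bias: np.ndarray | None = None) -> np.ndarray:
    """Combine two (H, W, N) feature maps at co-located positions.

    * ``sum`` / ``max``: elementwise, shapes must match exactly.
    * ``concat``: channel stacking of a then b, output (H, W, 2N).
    * ``conv``: concat followed by a 1x1 convolution with a filter bank of
      shape (1, 1, 2N, N) and a bias of length N.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 3 or b.ndim != 3:
        raise FusionShapeError(f"feature maps must be (H, W, N); got {a.shape} and {b.shape}")
    if method in ("sum", "max"):
        if a.shape != b.shape:
            raise FusionShapeError(f"{method} fusion needs identical shapes; got {a.shape} vs {b.shape}")
        return a + b if method == "sum" else np.maximum(a, b)
    if a.shape[:2] != b.shape[:2]:
        raise FusionShapeError(
            f"concat/conv fusion needs matching (H, W); got {a.shape[:2]} vs {b.shape[:2]}"
        )
    cat = np.concatenate([a, b], axis=2)
    if method == "concat":
        return cat
    if method == "conv":
        if a.shape[2] != b.shape[2]:
            raise FusionShapeError("conv fusion needs equal channel counts in both maps")
        n = a.shape[2]
        if filters is None or filters.shape != (1, 1, 2 * n, n):
            got = None if filters is None else filters.shape
            raise FusionShapeError(f"conv fusion needs a (1, 1, {2*n}, {n}) filter bank; got {got}")
        if bias is None:
            bias = np.zeros(n)
        # 1x1 convolution == per-position linear map across channels
        return np.tensordot(cat, filters[0, 0], axes=([2], [0])) + bias
    raise ValueError(f"unknown fusion method {method!r}; choose from {FUSIONS}")


def build_1d_stream(cfg: ModelConfig) -> tuple[LayerSpec, ...]:
    """Conv blocks for the raw-sequence stream (kernel length 25 everywhere)."""
    if any(f < 1 for f in cfg.filters_1d):
        raise ValueError("all 1-D filter counts must be positive")
    if len(cfg.filters_1d) < 5:
        raise ValueError("the 1-D stream needs at least 5 conv blocks (4 pooled + 1)")
    n_pool = 4
    if cfg.window < 2**n_pool:
        raise ValueError(
            f"window {cfg.window} collapses under {n_pool} poolings; need at least {2**n_pool}"
        )
    specs: list[LayerSpec] = []
    n_blocks = len(cfg.filters_1d)
    for i, f in enumerate(cfg.filters_1d):
        specs.append(LayerSpec(kind="conv1d", kernel=cfg.kernel_1d, filters=f))
        specs.append(LayerSpec(kind="batchnorm"))
        specs.append(LayerSpec(kind="relu"))
        if i < n_pool:
            specs.append(LayerSpec(kind="avgpool", pool=2))
        if i >= n_blocks - 2:
            specs.append(LayerSpec(kind="dropout", rate=cfg.dropout))
    specs.append(LayerSpec(kind="flatten"))
    return tuple(specs)


def build_2d_stream(cfg: ModelConfig) -> tuple[LayerSpec, ...]:
    """Seven conv2d blocks; 2x2 average pooling after all ReLUs but the last two."""
    if any(f < 1 for f in cfg.filters_2d):
        raise ValueError("all 2-D filter counts must be positive")
    if len(cfg.filters_2d) != 7:
        raise ValueError("the 2-D stream has exactly 7 convolutional layers")
    if cfg.side < 32:
        raise ValueError(
            f"FRP side {cfg.side} too small to survive 5 poolings; need side >= 32"
        )
    specs: list[LayerSpec] = []
    for i, f in enumerate(cfg.filters_2d):
        specs.append(LayerSpec(kind="conv2d", kernel=cfg.kernel_2d, filters=f))
        specs.append(LayerSpec(kind="batchnorm"))
        specs.append(LayerSpec(kind="relu"))
        if i < 5:
            specs.append(LayerSpec(kind="avgpool", pool=2))
    specs.append(LayerSpec(kind="flatten"))
    return tuple(specs)


def build_head(cfg: ModelConfig) -> tuple[LayerSpec, ...]:
    specs: list[LayerSpec] = []
    for i, units in enumerate(cfg.head_units):
        specs.append(LayerSpec(kind="dense", units=units))
        specs.append(LayerSpec(kind="relu"))
        if i == 0:
            specs.append(LayerSpec(kind="dropout", rate=cfg.dropout))
    specs.append(LayerSpec(kind="dense", units=1))
    return tuple(specs)


def build_concat_model(cfg: ModelConfig) -> ModelSpec:
    """Two-stream spec with the configured fusion (concatenation by default)."""
    if cfg.fusion not in FUSIONS:
        raise ValueError(f"unknown fusion {cfg.fusion!r}; choose from {FUSIONS}")
    if cfg.target not in ("sbp", "dbp"):
        raise ValueError("target must be 'sbp' or 'dbp'")
    spec = ModelSpec(
        stream_1d=build_1d_stream(cfg),
        stream_2d=build_2d_stream(cfg),
        fusion=cfg.fusion,
        head=build_head(cfg),
        target=cfg.target,
        window=cfg.window,
        side=cfg.side,
    )
    if cfg.fusion in ("sum", "max", "conv"):
        f1 = _stream_out_dim(spec.stream_1d, ("1d", cfg.window))
        f2 = _stream_out_dim(spec.stream_2d, ("2d", cfg.side))
        if f1 != f2:
            raise FusionShapeError(
                f"{cfg.fusion} fusion needs equal flattened stream widths; got {f1} vs {f2}"
            )
    return spec


def build_single_model(cfg: ModelConfig, which: str) -> ModelSpec:
    """Single-stream variant ('1d' or '2d') with the same dense head."""
    if which not in ("1d", "2d"):
        raise ValueError("which must be '1d' or '2d'")
    if cfg.target not in ("sbp", "dbp"):
        raise ValueError("target must be 'sbp' or 'dbp'")
    return ModelSpec(
        stream_1d=build_1d_stream(cfg),
        stream_2d=build_2d_stream(cfg),
        fusion="concat",
        head=build_head(cfg),
        target=cfg.target,
        window=cfg.window,
        side=cfg.side,
        streams=which,
    )


def _stream_out_dim(specs: tuple[LayerSpec, ...], inp: tuple[str, int]) -> int:
    """Propagate shapes through a stream spec (floor pooling, same conv)."""
    kind, size = inp
    channels = 1
    if kind == "1d":
        length = size
        for s in specs:
            if s.kind == "conv1d":
                channels = s.filters
            elif s.kind == "avgpool":
                length //= s.pool
        return channels * length
    h = w = size
    for s in specs:
        if s.kind == "conv2d":
            channels = s.filters
        elif s.kind == "avgpool":
            h //= s.pool
            w //= s.pool
    return channels * h * w


def _realize_stream(specs: tuple[LayerSpec, ...], dims: int, in_size: tuple,
                    rng: np.random.Generator, dtype) -> nn.Sequential:
    layers: list[nn.Layer] = []
    channels = 1
    for s in specs:
        if s.kind == "conv1d":
            layers.append(nn.Conv1D(channels, s.filters, s.kernel, rng, dtype=dtype))
            channels = s.filters
        elif s.kind == "conv2d":
            layers.append(nn.Conv2D(channels, s.filters, s.kernel, rng, dtype=dtype))
            channels = s.filters
        elif s.kind == "batchnorm":
            layers.append(nn.BatchNorm(channels, dtype=dtype))
        elif s.kind == "relu":
            layers.append(nn.ReLU())
        elif s.kind == "avgpool":
            layers.append(nn.AvgPool1D(s.pool) if dims == 1 else nn.AvgPool2D(s.pool))
        elif s.kind == "dropout":
            layers.append(nn.Dropout(s.rate, rng=np.random.default_rng(rng.integers(2**31))))
        elif s.kind == "flatten":
            layers.append(nn.Flatten())
        else:
            raise ValueError(f"layer kind {s.kind!r} not valid in a conv stream")
    return nn.Sequential(layers)


def _realize_head(specs: tuple[LayerSpec, ...], in_features: int,
                  rng: np.random.Generator, dtype) -> nn.Sequential:
    layers: list[nn.Layer] = []
    feats = in_features
    for s in specs:
        if s.kind == "dense":
            layers.append(nn.Dense(feats, s.units, rng, dtype=dtype))
            feats = s.units
        elif s.kind == "relu":
            layers.append(nn.ReLU())
        elif s.kind == "dropout":
            layers.append(nn.Dropout(s.rate, rng=np.random.default_rng(rng.integers(2**31))))
        else:
            raise ValueError(f"layer kind {s.kind!r} not valid in the head")
    return nn.Sequential(layers)


class TwoStreamRegressor:
    """Trainable two-stream network mapping (window, FRP) -> BP in mmHg."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        use_1d = spec.streams in ("both", "1d")
        use_2d = spec.streams in ("both", "2d")
        self.stream_1d = (_realize_stream(spec.stream_1d, 1, (spec.window,), rng, dtype)
                          if use_1d else None)
        self.stream_2d = (_realize_stream(spec.stream_2d, 2, (spec.side, spec.side), rng, dtype)
                          if use_2d else None)
        f1 = _stream_out_dim(spec.stream_1d, ("1d", spec.window)) if use_1d else 0
        f2 = _stream_out_dim(spec.stream_2d, ("2d", spec.side)) if use_2d else 0
        self._f1, self._f2 = f1, f2
        if spec.streams != "both":
            head_in = f1 + f2
            self.fusion_layer = None
        elif spec.fusion == "concat":
            head_in = f1 + f2
            self.fusion_layer = None
        elif spec.fusion in ("sum", "max"):
            if f1 != f2:
                raise FusionShapeError(f"{spec.fusion} fusion needs equal widths; got {f1} vs {f2}")
            head_in = f1
            self.fusion_layer = None
        elif spec.fusion == "conv":
            if f1 != f2:
                raise FusionShapeError(f"conv fusion needs equal widths; got {f1} vs {f2}")
            # learnable 1x1 conv over stacked channels at a single position
            self.fusion_layer = nn.Dense(2 * f1, f1, rng, dtype=dtype)
            head_in = f1
        else:
            raise ValueError(f"unknown fusion {spec.fusion!r}")
        self.head = _realize_head(spec.head, head_in, rng, dtype)
        # target scaling, set by train_model
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- parameter traversal -------------------------------------------------
    def named_params(self):
        if self.stream_1d is not None:
            yield from self.stream_1d.named_params("s1.")
        if self.stream_2d is not None:
            yield from self.stream_2d.named_params("s2.")
        if self.fusion_layer is not None:
            for name in self.fusion_layer.params:
                yield f"fuse.{name}", self.fusion_layer, name
        yield from self.head.named_params("head.")

    def _streams(self):
        for tag, stream in (("s1", self.stream_1d), ("s2", self.stream_2d), ("head", self.head)):
            if stream is not None:
                yield tag, stream

    def n_params(self) -> int:
        return sum(layer.params[p].size for _, layer, p in self.named_params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {key: layer.params[p] for key, layer, p in self.named_params()}
        for tag, stream in self._streams():
            for i, layer in enumerate(stream.layers):
                if isinstance(layer, nn.BatchNorm):
                    out[f"{tag}.{i}.running_mean"] = layer.running_mean
                    out[f"{tag}.{i}.running_var"] = layer.running_var
        return out

    # -- forward/backward ----------------------------------------------------
    def _prep(self, x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x1 = np.asarray(x1, dtype=self.dtype)
        x2 = np.asarray(x2, dtype=self.dtype)
        if x1.ndim == 2:
            x1 = x1[:, None, :]  # (B, 1, L)
        if x2.ndim == 3:
            x2 = x2[:, None, :, :]  # (B, 1, S, S)
        if x1.shape[2] != self.spec.window:
            raise ValueError(f"window length {x1.shape[2]} != model window {self.spec.window}")
        if x2.shape[2:] != (self.spec.side, self.spec.side):
            raise ValueError(f"FRP shape {x2.shape[2:]} != model side {self.spec.side}")
        # per-segment z-score of the raw sequence
        mu = x1.mean(axis=2, keepdims=True)
        sd = x1.std(axis=2, keepdims=True)
        x1 = (x1 - mu) / np.maximum(sd, 1e-8)
        return x1, x2

    def forward(self, x1: np.ndarray, x2: np.ndarray, training: bool = False) -> np.ndarray:
        if self.spec.streams == "1d":
            return self.head.forward(self.stream_1d.forward(x1, training), training)[:, 0]
        if self.spec.streams == "2d":
            return self.head.forward(self.stream_2d.forward(x2, training), training)[:, 0]
        f1 = self.stream_1d.forward(x1, training)
        f2 = self.stream_2d.forward(x2, training)
        if self.spec.fusion == "concat":
            fused = np.concatenate([f1, f2], axis=1)
        elif self.spec.fusion == "sum":
            fused = f1 + f2
        elif self.spec.fusion == "max":
            self._max_take_first = f1 >= f2
            fused = np.maximum(f1, f2)
        else:  # conv
            fused = self.fusion_layer.forward(np.concatenate([f1, f2], axis=1), training)
        return self.head.forward(fused, training)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        grad = self.head.backward(grad_out[:, None])
        if self.spec.streams == "1d":
            self.stream_1d.backward(grad)
            return
        if self.spec.streams == "2d":
            self.stream_2d.backward(grad)
            return
        if self.spec.fusion == "concat":
            g1, g2 = grad[:, : self._f1], grad[:, self._f1 :]
        elif self.spec.fusion == "sum":
            g1, g2 = grad, grad
        elif self.spec.fusion == "max":
            g1 = grad * self._max_take_first
            g2 = grad * ~self._max_take_first
        else:
            gcat = self.fusion_layer.backward(grad)
            g1, g2 = gcat[:, : self._f1], gcat[:, self._f1 :]
        self.stream_1d.backward(g1)
        self.stream_2d.backward(g2)

    # -- inference -----------------------------------------------------------
    def predict(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Batched prediction in mmHg; order preserved."""
        x1p, x2p = self._prep(np.atleast_2d(x1), x2 if np.asarray(x2).ndim >= 3 else np.asarray(x2)[None])
        out = []
        for lo in range(0, x1p.shape[0], 256):
            sl = slice(lo, lo + 256)
            out.append(self.forward(x1p[sl], x2p[sl], training=False))
        z = np.concatenate(out)
        return z * self.y_std + self.y_mean

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "spec": _spec_to_jsonable(self.spec),
            "seed": self.seed,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "dtype": np.dtype(self.dtype).name,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_arrays())


def _spec_to_jsonable(spec: ModelSpec) -> dict:
    d = asdict(spec)
    return d


def _spec_from_jsonable(d: dict) -> ModelSpec:
    d = dict(d)
    d["stream_1d"] = tuple(LayerSpec(**ls) for ls in d["stream_1d"])
    d["stream_2d"] = tuple(LayerSpec(**ls) for ls in d["stream_2d"])
    d["head"] = tuple(LayerSpec(**ls) for ls in d["head"])
    return ModelSpec(**d)


def load_model(path) -> TwoStreamRegressor:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = TwoStreamRegressor(_spec_from_jsonable(meta["spec"]), seed=meta["seed"],
                                   dtype=np.dtype(meta["dtype"]))
        model.y_mean = float(meta["y_mean"])
        model.y_std = float(meta["y_std"])
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    for key, layer, pname in model.named_params():
        layer.params[pname] = arrays[key]
    for tag, stream in model._streams():
        for i, layer in enumerate(stream.layers):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = arrays[f"{tag}.{i}.running_mean"]
                layer.running_var = arrays[f"{tag}.{i}.running_var"]
    return model


def _check_dataset(name, x1, x2, y):
    if len(y) == 0:
        raise ValueError(f"{name} split is empty")
    if not (len(x1) == len(x2) == len(y)):
        raise ValueError(f"{name} split has inconsistent lengths")


def train_model(
    model_or_spec: TwoStreamRegressor | ModelSpec,
    train_set: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray, np.ndarray],
    hyper: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> tuple[TwoStreamRegressor, list[dict]]:
    """Fit a two-stream regressor with Adam on MSE; early-stop on validation.

    Each dataset is ``(X1, X2, y)`` with raw windows (n, window), FRPs
    (n, side, side) and targets in mmHg. Targets are z-scored on the training
    statistics; the best-validation weights are restored before returning.
    """
    model = (model_or_spec if isinstance(model_or_spec, TwoStreamRegressor)
             else TwoStreamRegressor(model_or_spec, seed=hyper.seed))
    x1_tr, x2_tr, y_tr = train_set
    x1_va, x2_va, y_va = val_set
    _check_dataset("train", x1_tr, x2_tr, y_tr)
    _check_dataset("validation", x1_va, x2_va, y_va)

    y_tr = np.asarray(y_tr, dtype=float)
    y_va = np.asarray(y_va, dtype=float)
    model.y_mean = float(y_tr.mean())
    model.y_std = float(max(y_tr.std(), 1e-8))
    z_tr = ((y_tr - model.y_mean) / model.y_std).astype(model.dtype)
    z_va = ((y_va - model.y_mean) / model.y_std).astype(model.dtype)

    x1p, x2p = model._prep(x1_tr, x2_tr)
    x1v, x2v = model._prep(x1_va, x2_va)

    opt = nn.Adam(model.named_params(), lr=hyper.lr)
    rng = np.random.default_rng(hyper.seed)
    n = len(z_tr)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    wait = 0
    for epoch in range(1, hyper.max_epochs + 1):
        t0 = time.time()
        perm = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, hyper.batch):
            idx = perm[lo : lo + hyper.batch]
            pred = model.forward(x1p[idx], x2p[idx], training=True)
            err = pred - z_tr[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {lo // hyper.batch} "
                    f"(lr={hyper.lr}, batch={hyper.batch}); lower the learning rate"
                )
            total += loss * len(idx)
            model.backward((2.0 / len(idx)) * err.astype(model.dtype))
            opt.step()
        train_loss = total / n
        val_pred = _forward_eval(model, x1v, x2v)
        val_loss = float(np.mean((val_pred - z_va) ** 2))
        history.append({
            "epoch": epoch,
            "train_loss": train_loss,
            "val_loss": val_loss,
            "seconds": round(time.time() - t0, 3),
        })
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            wait = 0
        else:
            wait += 1
            if wait >= hyper.patience:
                break
    if best_state is not None:
        _restore_state(model, best_state)
    return model, history


def _forward_eval(model: TwoStreamRegressor, x1p: np.ndarray, x2p: np.ndarray) -> np.ndarray:
    out = []
    for lo in range(0, x1p.shape[0], 256):
        sl = slice(lo, lo + 256)
        out.append(model.forward(x1p[sl], x2p[sl], training=False))
    return np.concatenate(out)


def _restore_state(model: TwoStreamRegressor, state: dict[str, np.ndarray]) -> None:
    for key, layer, pname in model.named_params():
        layer.params[pname] = state[key].copy()
    for tag, stream in model._streams():
        for i, layer in enumerate(stream.layers):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = state[f"{tag}.{i}.running_mean"].copy()
                layer.running_var = state[f"{tag}.{i}.running_var"].copy()


def predict(model: TwoStreamRegressor, segment, frp) -> float | np.ndarray:
    """Predict BP (mmHg) for one segment (1-D array) or a batch (2-D array)."""
    seg = np.asarray(getattr(segment, "samples", segment), dtype=float)
    m = np.asarray(getattr(frp, "M", frp), dtype=float)
    if seg.ndim == 1:
        return float(model.predict(seg[None, :], m[None, :, :])[0])
    return model.predict(seg, m)
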