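"""Multi-scale and conventional 3D convolutional viability classifiers.

Implemented directly on NumPy (forward and backward passes, Adam updates)
so training is fully deterministic under a fixed seed and runs on one CPU.

Tensor convention: block data ``(n, s, s, K)`` is fed to the network as
``(n, 1, D, H, W)`` with the spectral axis as depth ``D = K``; kernel
triples are ``(depth, height, width)``.  All convolutions use same-padding
and stride 1 so the parallel branches of a multi-scale module can be
concatenated on the channel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockSet, SeedPrediction, vote_seed

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "ViabilityNet",
    "build_model",
    "train_model",
    "predict_blocks",
    "predict_seeds",
]

DEFAULT_KERNEL_BANK = ((3, 3, 3), (3, 3, 5), (3, 5, 5), (5, 5, 5))


@dataclass
class ModelConfig:
    architecture: str = "multiscale"  # or "conventional"
    input_shape: tuple[int, int, int] = (5, 5, 18)  # (s, s, K)
    kernel_bank: tuple = DEFAULT_KERNEL_BANK
    filters_per_module: tuple[int, int, int] = (16, 32, 64)
    # pooling extents (depth, height, width) applied after each module;
    # None disables pooling for that module
    pool_per_module: tuple = ((2, 2, 2), (2, 2, 2), None)
    fc_width: int = 128
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("multiscale", "conventional"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if len(self.filters_per_module) != 3:
            raise ValueError("filters_per_module must have length 3")
        s = self.input_shape[0]
        for kd, kh, kw in self.kernel_bank:
            if min(kd, kh, kw) < 1 or kh % 2 == 0 or kw % 2 == 0 or kd % 2 == 0:
                raise ValueError("kernel extents must be odd and >= 1")
            # same-padding guarantees padded extent >= kernel, but the spatial
            # kernel should not dwarf the block
            if max(kh, kw) > s + (max(kh, kw) // 2) * 2:
                raise ValueError("kernel larger than padded input")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# layers


class Conv3D:
    """Same-padded, stride-1 3-D convolution, channels-last.

    Blocks have tiny spatial grids (s = 5 or smaller after pooling) and a
    deep spectral axis, so the convolution is factored as an unfold along
    depth followed by one dense GEMM that mixes (depth offset, row, col,
    channel) into (row, col, filter).  The spatial part of the kernel is
    expanded into that dense mixing matrix each step (a small gather), which
    avoids the large im2col buffers a generic 3-D conv would need.

    Tensors are ``(n, D, H, W, C)``; weights are ``(kd, kh, kw, C, F)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        kd, kh, kw = kernel
        self.kernel = kernel
        fan_in = c_in * kd * kh * kw
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.W = (rng.standard_normal((kd, kh, kw, c_in, c_out)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None
        self._maps: dict = {}

    def _spatial_maps(self, H: int, W: int):
        """Gather/scatter index tables for the dense spatial mixing.

        ``jl_map[h, w, ho, wo]`` is the flat (kh, kw) kernel index linking
        input pixel (h, w) to output pixel (ho, wo), or a sentinel for
        out-of-kernel pairs; ``fold`` is its 0/1 matrix transpose used to
        fold the mixing-matrix gradient back onto the shared kernel.
        """
        key = (H, W)
        if key not in self._maps:
            kd, kh, kw = self.kernel
            ph, pw = kh // 2, kw // 2
            sentinel = kh * kw
            jl = np.full((H, W, H, W), sentinel, dtype=np.intp)
            for h in range(H):
                for w in range(W):
                    for ho in range(H):
                        for wo in range(W):
                            j, l = h - ho + ph, w - wo + pw
                            if 0 <= j < kh and 0 <= l < kw:
                                jl[h, w, ho, wo] = j * kw + l
            fold = np.zeros((H * W * H * W, kh * kw), dtype=np.float32)
            flat = jl.ravel()
            valid = flat < sentinel
            fold[np.flatnonzero(valid), flat[valid]] = 1.0
            self._maps[key] = (jl.ravel(), fold)
        return self._maps[key]

    def _mixing_matrix(self, H: int, W: int) -> np.ndarray:
        """Expand kernel weights into the (kd*H*W*C, H*W*F) dense mixer."""
        kd, kh, kw = self.kernel
        c, f = self.W.shape[3:]
        jl_map, _ = self._spatial_maps(H, W)
        wt = self.W.transpose(0, 3, 1, 2, 4).reshape(kd, c, kh * kw, f)
        wt = np.concatenate([wt, np.zeros((kd, c, 1, f), dtype=np.float32)], axis=2)
        v = wt[:, :, jl_map, :]  # (kd, c, H*W*H*W, f)
        v = v.reshape(kd, c, H, W, H, W, f).transpose(0, 2, 3, 1, 4, 5, 6)
        return np.ascontiguousarray(v).reshape(kd * H * W * c, H * W * f)

    def _unfold_depth(self, x: np.ndarray) -> np.ndarray:
        n, D, H, W, c = x.shape
        kd = self.kernel[0]
        pdepth = kd // 2
        xp = np.pad(x, ((0, 0), (pdepth, pdepth), (0, 0), (0, 0), (0, 0)))
        u = np.empty((n, D, kd, H, W, c), dtype=np.float32)
        for i in range(kd):
            u[:, :, i] = xp[:, i : i + D]
        return u

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, D, H, W, c = x.shape
        f = self.W.shape[-1]
        umat = self._unfold_depth(x).reshape(n * D, -1)
        v = self._mixing_matrix(H, W)
        out = umat @ v + np.tile(self.b, H * W)
        if train:
            self._cache = (umat, v, x.shape)
        return out.reshape(n, D, H, W, f)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        umat, v, xshape = self._cache
        n, D, H, W, c = xshape
        kd, kh, kw = self.kernel
        f = self.W.shape[-1]
        dmat = dout.reshape(n * D, -1)
        self.db = dout.reshape(-1, f).sum(axis=0)
        # kernel gradient: mixing-matrix gradient folded back onto shared taps
        dv = (umat.T @ dmat).reshape(kd, H, W, c, H, W, f)
        _, fold = self._spatial_maps(H, W)
        dvp = dv.transpose(0, 3, 6, 1, 2, 4, 5).reshape(kd * c * f, -1)
        dw = (dvp @ fold).reshape(kd, c, f, kh, kw)
        self.dW = np.ascontiguousarray(dw.transpose(0, 3, 4, 1, 2))
        # input gradient: back through the GEMM, then fold the depth unfold
        du = (dmat @ v.T).reshape(n, D, kd, H, W, c)
        pdepth = kd // 2
        dxp = np.zeros((n, D + 2 * pdepth, H, W, c), dtype=np.float32)
        for i in range(kd):
            dxp[:, i : i + D] += du[:, :, i]
        return dxp[:, pdepth : pdepth + D]


class ReLU:
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool3D:
    """Non-overlapping max pooling (channels-last); remainders are cropped."""

    def __init__(self, pool: tuple[int, int, int]):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pd, ph, pw = self.pool
        n, D, H, W, c = x.shape
        Do, Ho, Wo = max(D // pd, 1), max(H // ph, 1), max(W // pw, 1)
        pd_, ph_, pw_ = min(pd, D), min(ph, H), min(pw, W)
        xc = x[:, : Do * pd_, : Ho * ph_, : Wo * pw_, :]
        win = xc.reshape(n, Do, pd_, Ho, ph_, Wo, pw_, c)
        win = win.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(n, Do, Ho, Wo, c, -1)
        if train:
            self._arg = win.argmax(axis=-1)
            self._shape = x.shape
            self._crop = (pd_, ph_, pw_, Do, Ho, Wo)
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, D, H, W, c = self._shape
        pd_, ph_, pw_, Do, Ho, Wo = self._crop
        dwin = np.zeros((n, Do, Ho, Wo, c, pd_ * ph_ * pw_), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(n, Do, Ho, Wo, c, pd_, ph_, pw_)
        dwin = dwin.transpose(0, 1, 5, 2, 6, 3, 7, 4)
        dx = np.zeros((n, D, H, W, c), dtype=np.float32)
        dx[:, : Do * pd_, : Ho * ph_, : Wo * pw_, :] = dwin.reshape(
            n, Do * pd_, Ho * ph_, Wo * pw_, c
        )
        return dx


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = (self._x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return dout @ self.W.T


class MultiScaleModule:
    """Parallel conv branches (one per kernel shape) fused on the channel axis.

    Each branch is conv + ReLU; branch outputs concatenate, so the module's
    output width is ``len(kernel_bank) * filters``.
    """

    def __init__(self, c_in: int, filters: int, kernel_bank, rng):
        self.branches = [Conv3D(c_in, filters, k, rng) for k in kernel_bank]
        self.relus = [ReLU() for _ in kernel_bank]
        self.c_out = filters * len(kernel_bank)

    def forward(self, x, train=False):
        outs = [r.forward(c.forward(x, train), train)
                for c, r in zip(self.branches, self.relus)]
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, dout):
        parts = np.split(dout, self._splits, axis=-1)
        dx = None
        for c, r, dp in zip(self.branches, self.relus, parts):
            d = c.backward(r.backward(dp))
            dx = d if dx is None else dx + d
        return dx

    def conv_layers(self):
        return self.branches


class ViabilityNet:
    """Three convolution modules, optional pooling, one hidden FC, softmax out."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        s, _, K = config.input_shape
        kernel_bank = (
            config.kernel_bank
            if config.architecture == "multiscale"
            else ((3, 3, 3),)
        )
        self.modules: list = []
        self.pools: list = []
        c_in = 1
        shape = (K, s, s)
        for filters, pool in zip(config.filters_per_module, config.pool_per_module):
            mod = MultiScaleModule(c_in, filters, kernel_bank, rng)
            self.modules.append(mod)
            c_in = mod.c_out
            if pool is not None:
                self.pools.append(MaxPool3D(pool))
                shape = tuple(max(d // p, 1) for d, p in zip(shape, pool))
            else:
                self.pools.append(None)
        self.flat_dim = c_in * int(np.prod(shape))
        self.fc = Dense(self.flat_dim, config.fc_width, rng)
        self.fc_relu = ReLU()
        self.out = Dense(config.fc_width, config.n_classes, rng)

    # -- forward / backward ------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x.astype(np.float32)
        for mod, pool in zip(self.modules, self.pools):
            h = mod.forward(h, train)
            if pool is not None:
                h = pool.forward(h, train)
        self._last_pooled_shape = h.shape  # backward reshapes the FC grad to this
        n = h.shape[0]
        h = h.reshape(n, -1)
        h = self.fc_relu.forward(self.fc.forward(h, train), train)
        return self.out.forward(h, train)

    def forward_proba(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = self.forward_logits(x, train)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, dlogits: np.ndarray, pooled_shape) -> None:
        d = self.fc.backward(self.fc_relu.backward(self.out.backward(dlogits)))
        d = d.reshape(pooled_shape)
        for mod, pool in zip(reversed(self.modules), reversed(self.pools)):
            if pool is not None:
                d = pool.backward(d)
            d = mod.backward(d)

    def parameters(self) -> list:
        layers = [c for m in self.modules for c in m.conv_layers()] + [self.fc, self.out]
        return layers

    def module_output_channels(self) -> list[int]:
        return [m.c_out for m in self.modules]


def build_model(config: ModelConfig) -> ViabilityNet:
    """Instantiate the configured classifier with seeded initial weights."""
    return ViabilityNet(config)


class _Adam:
    def __init__(self, layers, lr):
        self.layers = layers
        self.lr = lr
        self.t = 0
        self.state = {}
        for i, layer in enumerate(layers):
            for name in ("W", "b"):
                p = getattr(layer, name)
                self.state[(i, name)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self):
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        for i, layer in enumerate(self.layers):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                m, v = self.state[(i, name)]
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p = getattr(layer, name)
                p -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)


def _to_tensor(bs: BlockSet) -> np.ndarray:
    # (n, s, s, K) -> (n, K, s, s, 1): spectral axis becomes depth,
    # trailing singleton channel (channels-last)
    data = bs.data_array().astype(np.float32)
    return np.ascontiguousarray(data.transpose(0, 3, 1, 2))[..., None]


def _to_class_index(labels: np.ndarray) -> np.ndarray:
    # class labels are 1 (viable) / 2 (nonviable) -> 0 / 1
    return np.asarray(labels, dtype=int) - 1


def train_model(
    model: ViabilityNet,
    train_blocks: BlockSet,
    eval_blocks: BlockSet | None,
    config: ModelConfig | None = None,
) -> tuple[ViabilityNet, TrainingHistory]:
    """Minimise cross-entropy with Adam; history recorded every epoch.

    All randomness (shuffling) derives from ``config.seed``, so two runs with
    the same data and seed produce identical histories.
    """
    config = config or model.config
    X = _to_tensor(train_blocks)
    y = _to_class_index(train_blocks.labels())
    if len(np.unique(y)) < 2:
        raise ValueError("training set holds a single class")
    Xe = _to_tensor(eval_blocks) if eval_blocks is not None and len(eval_blocks) else None
    ye = _to_class_index(eval_blocks.labels()) if Xe is not None else None

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.parameters(), config.learning_rate)
    hist = TrainingHistory()
    n = len(y)
    onehot = np.eye(config.n_classes, dtype=np.float32)

    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            probs = model.forward_proba(xb, train=True)
            ep_loss += float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum())
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = (probs - onehot[yb]) / len(yb)
            pooled = model._last_pooled_shape  # set during forward
            model.backward(dlogits.astype(np.float32), pooled)
            opt.step()
        hist.train_loss.append(ep_loss / n)
        hist.train_accuracy.append(ep_correct / n)
        if Xe is not None:
            pe = model.forward_proba(Xe)
            hist.test_accuracy.append(float((pe.argmax(axis=1) == ye).mean()))
        else:
            hist.test_accuracy.append(float("nan"))
    return model, hist


def predict_blocks(model: ViabilityNet, blocks: BlockSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-block class scores (rows sum to 1) and argmax labels in {1, 2}."""
    if len(blocks) == 0:
        raise ValueError("empty block set")
    X = _to_tensor(blocks)
    expected = (model.config.input_shape[2],) + model.config.input_shape[:2] + (1,)
    if X.shape[1:] != expected:
        raise ValueError(f"block tensor shape {X.shape[1:]} != model input {expected}")
    scores = []
    for start in range(0, len(X), 256):
        scores.append(model.forward_proba(X[start : start + 256]))
    scores = np.concatenate(scores)
    labels = scores.argmax(axis=1) + 1
    return scores, labels


def predict_seeds(model: ViabilityNet, blocks: BlockSet, tie_rule: int = 2
                  ) -> list[SeedPrediction]:
    """Predict every block, then majority-vote each seed's blocks."""
    scores, labels = predict_blocks(model, blocks)
    seed_ids = blocks.seed_ids()
    preds = []
    for sid in np.unique(seed_ids):
        sel = seed_ids == sid
        preds.append(
            vote_seed(labels[sel], seed_id=int(sid), tie_rule=tie_rule,
                      block_scores=scores[sel])
        )
    return preds


def save_model(model: ViabilityNet, path: str) -> None:
    """Serialise weights and config together in one ``.npz`` archive."""
    import json
    from dataclasses import asdict

    arrays = {"config_json": np.array(json.dumps(asdict(model.config)))}
    for i, layer in enumerate(model.parameters()):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    np.savez(path, **arrays)


def load_model(path: str) -> ViabilityNet:
    import json

    with np.load(path) as z:
        cfg = json.loads(str(z["config_json"]))
        for key in ("input_shape", "filters_per_module", "pool_per_module",
                    "kernel_bank"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in cfg[key]
                )
        model = build_model(ModelConfig(**cfg))
        for i, layer in enumerate(model.parameters()):
            layer.W = z[f"W{i}"]
            layer.b = z[f"b{i}"]
    return model
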