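"""Dual-frame U-Net for sparse-view streak-artifact reduction.

The network is trained per view-subset in a residual fashion: its input is
the lung-windowed, (0,1)-normalized sparse-view FBP image and its target
is the difference between the windowed full-view and sparse-view images.
At inference the predicted residual is added back to the input, so the
network only has to model the streak artifacts, not the anatomy.

Architecture (dual-frame U-Net): four encoder blocks of two 3x3 conv +
ReLU layers with 2x2 max pooling after each, a two-conv bottleneck, and
four decoder blocks with 2x2 unpooling before each. Encoder outputs reach
the decoder via skip-and-concatenate connections; in addition, the feature
maps directly after each pooling are subtracted from those directly before
the matched unpooling (skip-and-subtraction bypass), which makes the
encoder/decoder decomposition satisfy the frame condition. Unpooling
re-uses the switch indices of the matched pooling layer, i.e. it is the
pooling operator's adjoint. A final 1x1 convolution produces the residual.

Channel widths double per level from ``base_channels``. Convolutions are
zero-padded ("same") so every block preserves spatial shape and the output
matches the input size exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .recon import ReconImage

__all__ = [
    "WindowSpec",
    "LUNG_WINDOW",
    "SOFT_TISSUE_WINDOW",
    "UNetConfig",
    "TrainConfig",
    "TrainedModel",
    "TrainingDivergedError",
    "DualFrameUNet",
    "preprocess_window",
    "build_dual_frame_unet",
    "make_training_pairs",
    "lr_schedule",
    "train_residual",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class WindowSpec:
    """A CT display/preprocessing window (center/width, HU)."""

    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def low(self) -> float:
        return self.center - self.width / 2.0

    @property
    def high(self) -> float:
        return self.center + self.width / 2.0


#: Preprocessing window applied before network input/target construction.
LUNG_WINDOW = WindowSpec(center=-600.0, width=1700.0)
#: Display window used for mediastinal/vascular structures.
SOFT_TISSUE_WINDOW = WindowSpec(center=60.0, width=380.0)


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    convs_per_block: int = 2
    conv_kernel: int = 3
    pool_kernel: int = 2
    base_channels: int = 64
    dual_frame: bool = True
    final_kernel: int = 1

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("invalid UNetConfig")

    @property
    def min_divisor(self) -> int:
        return self.pool_kernel**self.depth


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"
    epochs: int = 50
    batch_size: int = 16
    lr0: float = 1e-3
    lr_decay: float = 0.1  # per-epoch exponential rate: lr_n = lr_{n-1} e^{-0.1}
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


def preprocess_window(hu_image: np.ndarray, window: WindowSpec = LUNG_WINDOW) -> np.ndarray:
    """Clip to the window and map affinely onto [0, 1]."""
    hu_image = np.asarray(hu_image, dtype=np.float64)
    clipped = np.clip(hu_image, window.low, window.high)
    return (clipped - window.low) / window.width


class DualFrameUNet:
    """Explicit-NumPy dual-frame U-Net (see module docstring)."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        if config.convs_per_block != 2 or config.conv_kernel != 3 or config.pool_kernel != 2:
            raise ValueError("this implementation fixes 2x(3x3 conv) blocks and 2x2 pooling")
        self.config = config
        rng = np.random.default_rng(seed)
        b = config.base_channels
        self.channels = [b * 2**l for l in range(config.depth)]
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for l, ch in enumerate(self.channels):
            p[f"enc{l}_0_w"], p[f"enc{l}_0_b"] = nn.he_init(rng, c_in, ch, 3, 3)
            p[f"enc{l}_1_w"], p[f"enc{l}_1_b"] = nn.he_init(rng, ch, ch, 3, 3)
            c_in = ch
        top = self.channels[-1]
        p["bot_0_w"], p["bot_0_b"] = nn.he_init(rng, top, 2 * top, 3, 3)
        p["bot_1_w"], p["bot_1_b"] = nn.he_init(rng, 2 * top, top, 3, 3)
        for l in reversed(range(config.depth)):
            ch = self.channels[l]
            ch_out = self.channels[l - 1] if l > 0 else self.channels[0]
            p[f"dec{l}_0_w"], p[f"dec{l}_0_b"] = nn.he_init(rng, 2 * ch, ch_out, 3, 3)
            p[f"dec{l}_1_w"], p[f"dec{l}_1_b"] = nn.he_init(rng, ch_out, ch_out, 3, 3)
        # Residual head starts at zero so the untrained network is the
        # identity correction; training can only move away from that.
        p["final_w"], p["final_b"] = nn.he_init(rng, self.channels[0], 1, 1, 1)
        p["final_w"][:] = 0.0
        self.params = p

    # -- weight management -------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[:, :, :, None]
        if x.ndim != 4 or x.shape[3] != 1:
            raise ValueError("input must be (H,W), (N,H,W) or (N,H,W,1)")
        d = self.config.min_divisor
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(
                f"input sides must be divisible by {d} "
                f"(depth {self.config.depth} with 2x2 pooling)"
            )
        return x

    def _conv_block(self, x, prefix, cache):
        p = self.params
        h1, c1 = nn.conv_forward(x, p[f"{prefix}_0_w"], p[f"{prefix}_0_b"])
        a1, m1 = nn.relu_forward(h1)
        h2, c2 = nn.conv_forward(a1, p[f"{prefix}_1_w"], p[f"{prefix}_1_b"])
        a2, m2 = nn.relu_forward(h2)
        cache[prefix] = (c1, m1, c2, m2)
        return a2

    def _conv_block_backward(self, dout, prefix, cache, grads):
        p = self.params
        c1, m1, c2, m2 = cache[prefix]
        d = nn.relu_backward(dout, m2)
        d, grads[f"{prefix}_1_w"], grads[f"{prefix}_1_b"] = nn.conv_backward(
            d, p[f"{prefix}_1_w"], c2
        )
        d = nn.relu_backward(d, m1)
        d, grads[f"{prefix}_0_w"], grads[f"{prefix}_0_b"] = nn.conv_backward(
            d, p[f"{prefix}_0_w"], c1
        )
        return d

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Predict the residual for a batch; returns (out, cache)."""
        x = self._check_input(x)
        cache: dict = {}
        enc_out = []   # e_l (pre-pooling features)
        pooled = []    # (p_l, idx_l, hw_l)
        feats = x
        for l in range(self.config.depth):
            e = self._conv_block(feats, f"enc{l}", cache)
            pl, idx, hw = nn.maxpool_forward(e)
            enc_out.append(e)
            pooled.append((pl, idx, hw))
            feats = pl
        btm = self._conv_block(feats, "bot", cache)
        d = btm
        for l in reversed(range(self.config.depth)):
            pl, idx, hw = pooled[l]
            sub = d - pl if self.config.dual_frame else d
            up = nn.maxunpool_forward(sub, idx, hw)
            cat = np.concatenate([up, enc_out[l]], axis=-1)
            d = self._conv_block(cat, f"dec{l}", cache)
        out, cf = nn.conv_forward(d, self.params["final_w"], self.params["final_b"])
        if not want_cache:
            return out, None
        cache["final"] = cf
        cache["pooled_meta"] = [(idx, hw) for _, idx, hw in pooled]
        return out, cache

    def backward(self, dout: np.ndarray, cache: dict) -> dict:
        grads: dict = {}
        depth = self.config.depth
        d, grads["final_w"], grads["final_b"] = nn.conv_backward(
            dout, self.params["final_w"], cache["final"]
        )
        de = [None] * depth  # accumulated grads at e_l
        dp = [None] * depth  # accumulated grads at p_l
        def acc(store, l, g):
            store[l] = g if store[l] is None else store[l] + g

        do = d  # gradient w.r.t. the running decoder output
        for l in range(depth):  # reverse of decoder execution order
            idx, hw = cache["pooled_meta"][l]
            dcat = self._conv_block_backward(do, f"dec{l}", cache, grads)
            ch = self.channels[l]
            dup, dskip = dcat[..., :ch], dcat[..., ch:]
            acc(de, l, dskip)
            dsub = nn.maxunpool_backward(dup, idx)
            if self.config.dual_frame:
                acc(dp, l, -dsub)
            if l + 1 < depth:
                do = dsub  # feeds decoder block l+1's output
            else:
                dbtm = dsub
        dbot_in = self._conv_block_backward(dbtm, "bot", cache, grads)
        acc(dp, depth - 1, dbot_in)
        for l in reversed(range(depth)):
            idx, hw = cache["pooled_meta"][l]
            acc(de, l, nn.maxpool_backward(dp[l], idx, hw))
            dins = self._conv_block_backward(de[l], f"enc{l}", cache, grads)
            if l > 0:
                acc(dp, l - 1, dins)
        return grads

    def __call__(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x)
        return out


@dataclass
class TrainedModel:
    """A trained residual network plus its training record."""

    net: DualFrameUNet
    train_config: TrainConfig
    best_epoch: int
    history: dict
    n_views: int | None = None

    @property
    def config(self) -> UNetConfig:
        return self.net.config


def build_dual_frame_unet(config: UNetConfig = UNetConfig(), seed: int = 0) -> DualFrameUNet:
    """Construct an untrained dual-frame U-Net with He-initialized weights."""
    return DualFrameUNet(config, seed=seed)


def _as_hu(img) -> np.ndarray:
    return img.image if isinstance(img, ReconImage) else np.asarray(img, dtype=np.float64)


def make_training_pairs(full_view, sparse_view, window: WindowSpec = LUNG_WINDOW):
    """Build one (input, target) residual pair from HU-domain images.

    input  = windowed sparse-view image in (0,1)
    target = windowed full-view - windowed sparse-view

    so that input + target reconstructs the windowed full-view image
    exactly. Accepts :class:`ReconImage` (assumed HU) or raw arrays.
    """
    full = _as_hu(full_view)
    sparse = _as_hu(sparse_view)
    if full.shape != sparse.shape:
        raise ValueError(
            f"full/sparse shape mismatch: {full.shape} vs {sparse.shape}"
        )
    inp = preprocess_window(sparse, window)
    target = preprocess_window(full, window) - inp
    return inp, target


def lr_schedule(lr_prev: float, decay: float = 0.1) -> float:
    """One step of the per-epoch exponential decay: lr * e^(-decay)."""
    if lr_prev <= 0:
        raise ValueError("lr_prev must be > 0")
    return lr_prev * float(np.exp(-decay))


def _stack_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2 and not isinstance(pairs[0], tuple):
        x, y = pairs
    else:
        xs, ys = zip(*pairs)
        x, y = np.stack(xs), np.stack(ys)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if y.ndim == 3:
        y = y[..., None]
    if x.shape != y.shape:
        raise ValueError("input/target stacks must have the same shape")
    return x, y


def _eval_loss(net: DualFrameUNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total = 0.0
    for lo in range(0, x.shape[0], batch):
        pred, _ = net.forward(x[lo : lo + batch])
        diff = pred - y[lo : lo + batch]
        total += float(np.sum(diff.astype(np.float64) ** 2))
    return total / y.size


def train_residual(
    model: DualFrameUNet,
    train_pairs,
    val_pairs,
    tc: TrainConfig = TrainConfig(),
    n_views: int | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train the residual network with MSE loss and Adam.

    The learning rate starts at ``tc.lr0`` and is multiplied by
    ``e^(-tc.lr_decay)`` after every epoch. Per-epoch train and validation
    losses are recorded and the weights of the epoch with the smallest
    validation loss are returned. Fully deterministic given ``tc.seed``.
    """
    xt, yt = _stack_pairs(train_pairs)
    xv, yv = _stack_pairs(val_pairs)
    if xt.shape[0] < 1 or xv.shape[0] < 1:
        raise ValueError("need at least one training and one validation pair")
    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.params)
    history = {"train": [], "val": [], "lr": []}
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    lr = tc.lr0
    n = xt.shape[0]
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, tc.batch_size):
            sel = order[lo : lo + tc.batch_size]
            xb, yb = xt[sel], yt[sel]
            pred, cache = model.forward(xb, want_cache=True)
            diff = pred - yb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            grads = model.backward((2.0 / diff.size) * diff, cache)
            opt.step(model.params, grads, lr)
            epoch_loss += loss
            n_batches += 1
        val_loss = _eval_loss(model, xv, yv, tc.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        history["train"].append(epoch_loss / max(n_batches, 1))
        history["val"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        if verbose:
            print(f"epoch {epoch}: train {history['train'][-1]:.3e} "
                  f"val {val_loss:.3e} lr {lr:.2e}")
        lr = lr_schedule(lr, tc.lr_decay)
    model.load_state_dict(best_state)
    return TrainedModel(
        net=model,
        train_config=tc,
        best_epoch=best_epoch,
        history=history,
        n_views=n_views,
    )


def predict(
    model: TrainedModel | DualFrameUNet,
    sparse_image: np.ndarray,
    n_views: int | None = None,
) -> np.ndarray:
    """Artifact-corrected image: input + predicted residual, clipped to [0,1].

    ``sparse_image`` must already be windowed/normalized to [0, 1]. If the
    image's view count is given and differs from the subset the model was
    trained for, a warning is emitted (models are subset-specific).
    """
    net = model.net if isinstance(model, TrainedModel) else model
    trained_views = model.n_views if isinstance(model, TrainedModel) else None
    if n_views is not None and trained_views is not None and n_views != trained_views:
        warnings.warn(
            f"model was trained for {trained_views}-view images but got "
            f"{n_views}-view input; correction quality is subset-specific",
            stacklevel=2,
        )
    x = np.asarray(sparse_image, dtype=np.float64)
    residual, _ = net.forward(x)
    res = residual.astype(np.float64)
    if x.ndim == 2:
        res = res[0, ..., 0]
    elif x.ndim == 3:
        res = res[..., 0]
    return np.clip(x + res, 0.0, 1.0)


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Checkpoint: weights as ``.npz`` plus a JSON sidecar with config,
    subset, best epoch and the loss history."""
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.net.params)
    sidecar = {
        "kind": "dual_frame_unet",
        "unet_config": asdict(model.config),
        "train_config": asdict(model.train_config),
        "best_epoch": model.best_epoch,
        "history": model.history,
        "n_views": model.n_views,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = UNetConfig(**meta["unet_config"])
    net = DualFrameUNet(cfg, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return TrainedModel(
        net=net,
        train_config=TrainConfig(**meta["train_config"]),
        best_epoch=meta["best_epoch"],
        history=meta["history"],
        n_views=meta["n_views"],
    )
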