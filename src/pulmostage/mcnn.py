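"""Multilayer CNN stage classifier (M-CNN).

Architecture: ``n_blocks`` repetitions of [3×3 convolution (same padding) →
ReLU → 2×2 max-pool], then flatten → dropout → fully-connected → ReLU →
fully-connected → softmax over the stage classes.  The default configuration
is six blocks on a 256×256×8 input (the 8 slab slices enter as channels of a
2D convolution), dropout 0.2, a 4096-unit hidden layer, batch size 10 and a
learning rate stepped down by a factor of 10 every 10 epochs.

Training minimizes the mean categorical cross-entropy by minibatch SGD with
momentum, with optional early stopping on validation loss.  Everything is
NumPy: convolutions run as im2col + GEMM, pooling and dropout use
deterministic tie-breaks and seeded generators, so a fixed seed reproduces
training bit for bit.

Inputs are standardized with mean/std statistics computed once from the
training set and stored on the model, so prediction applies the identical
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MCNNConfig",
    "TrainingHistory",
    "MCNN",
    "relu",
    "softmax",
    "cross_entropy",
    "lr_schedule",
    "build_mcnn",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class MCNNConfig:
    input_shape: tuple[int, int, int] = (256, 256, 8)  # (height, width, depth)
    n_blocks: int = 6
    kernel_size: int = 3
    channel_progression: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    dropout_rate: float = 0.2
    fc_units: int = 4096
    n_classes: int = 9
    lr0: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 10
    epochs: int = 30
    batch_size: int = 10
    early_stopping_patience: int = 10
    momentum: float = 0.9
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if len(self.channel_progression) < self.n_blocks:
            raise ValueError("channel_progression must list one width per block")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.kernel_size != 3:
            raise ValueError("only 3x3 kernels are supported")
        h, w, _ = self.input_shape
        for b in range(self.n_blocks):
            if h < 2 or w < 2:
                raise ValueError(
                    f"spatial size collapses below 1x1 at block {b + 1}: a "
                    f"{self.input_shape[0]}x{self.input_shape[1]} input supports "
                    f"at most {b} pooling stages; reduce n_blocks or enlarge the input"
                )
            h, w = h // 2, w // 2

    @property
    def spatial_after_pooling(self) -> tuple[int, int]:
        h, w, _ = self.input_shape
        for _ in range(self.n_blocks):
            h, w = h // 2, w // 2
        return h, w


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "train_accuracy": self.train_accuracy,
            "val_accuracy": self.val_accuracy,
            "learning_rate": self.learning_rate,
        })


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def relu(y: np.ndarray | float) -> np.ndarray | float:
    """Elementwise max(0, y)."""
    return np.maximum(0, y)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(indicator: np.ndarray, predicted: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy −Σ_c z_c log p_c over a batch.

    ``indicator`` is one-hot (or {0,1}) per class; ``predicted`` must be rows
    of probabilities summing to 1 within 1e−6 (entries clamped to [eps, 1]).
    """
    z = np.atleast_2d(np.asarray(indicator, dtype=np.float64))
    p = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    if z.shape != p.shape:
        raise ValueError(f"shape mismatch {z.shape} vs {p.shape}")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("predicted rows must be probability vectors summing to 1")
    p = np.clip(p, eps, 1.0)
    return float(-(z * np.log(p)).sum(axis=1).mean())


def lr_schedule(epoch: int, lr0: float, decay_factor: float = 10.0,
                decay_every: int = 10) -> float:
    """Stepped decay: lr0 · factor^(−⌊epoch / every⌋)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return float(lr0 * decay_factor ** (-(epoch // decay_every)))


# ---------------------------------------------------------------------------
# Layers (functional, with explicit caches)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) → (N, H, W, C, 3, 3) sliding 3x3 windows, zero-padded."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, h, w, c, 3, 3), (s[0], s[2], s[3], s[1], s[2], s[3]))


def _conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution. x (N,C,H,W), weight (F,C,3,3) → (N,F,H,W).

    Large feature maps use nine shifted GEMMs (half the copying of im2col);
    small ones use im2col + tensordot, which has less per-call overhead.
    """
    n, c, h, w = x.shape
    if h * w >= 256:
        xp = np.pad(x.transpose(0, 2, 3, 1), ((0, 0), (1, 1), (1, 1), (0, 0)))
        wl = weight.transpose(2, 3, 1, 0)  # (3,3,C,F)
        out = np.empty((n, h, w, weight.shape[0]), dtype=x.dtype)
        out[:] = bias
        for dy in range(3):
            for dx in range(3):
                np.add(out, xp[:, dy:dy + h, dx:dx + w, :] @ wl[dy, dx], out=out)
    else:
        win = _im2col3(x)
        out = np.tensordot(win, weight, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,F)
        out += bias
    return np.moveaxis(out, -1, 1)


def _conv3x3_backward(x: np.ndarray, weight: np.ndarray, d_out: np.ndarray):
    """Gradients of _conv3x3. d_out (N,F,H,W) → (dx, dw, db)."""
    win = _im2col3(x)  # (N,H,W,C,3,3)
    d_moved = np.moveaxis(d_out, 1, -1)  # (N,H,W,F)
    dw = np.tensordot(d_moved, win, axes=([0, 1, 2], [0, 1, 2]))  # (F,C,3,3)
    db = d_moved.sum(axis=(0, 1, 2))
    # dx: full correlation of d_out with spatially flipped kernels
    w_flip = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,3,3)
    dx = _conv3x3(d_out, w_flip, np.zeros(w_flip.shape[0], dtype=weight.dtype))
    return dx, dw, db


def _maxpool2(x: np.ndarray):
    """2x2 stride-2 max pooling with first-max tie-break. Returns (out, argmax)."""
    n, c, h, w = x.shape
    r = x[:, :, : h - h % 2, : w - w % 2]
    r = r.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    am = r.argmax(axis=-1)
    out = np.take_along_axis(r, am[..., None], axis=-1)[..., 0]
    return out, am


def _maxpool2_backward(d_out: np.ndarray, am: np.ndarray, in_shape) -> np.ndarray:
    n, c, h, w = in_shape
    scattered = np.zeros((n, c, h // 2, w // 2, 4), dtype=d_out.dtype)
    np.put_along_axis(scattered, am[..., None], d_out[..., None], axis=-1)
    scattered = scattered.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(in_shape, dtype=d_out.dtype)
    dx[:, :, : h - h % 2, : w - w % 2] = scattered.reshape(n, c, (h // 2) * 2, (w // 2) * 2)
    return dx


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MCNN:
    """The network: parameter store plus forward/backward passes."""

    def __init__(self, config: MCNNConfig, class_names: Sequence[str] | None = None):
        self.config = config
        self.class_names = (list(class_names) if class_names is not None
                            else [str(i) for i in range(config.n_classes)])
        if len(self.class_names) != config.n_classes:
            raise ValueError("class_names length must equal n_classes")
        self.dtype = np.dtype(config.dtype)
        self.input_mean = 0.0
        self.input_std = 1.0
        self._init_params()

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        h, w, c_in = cfg.input_shape
        self.conv_w, self.conv_b = [], []
        c_prev = c_in
        for b in range(cfg.n_blocks):
            c_out = cfg.channel_progression[b]
            fan_in = c_prev * 9
            wgt = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_prev, 3, 3))
            self.conv_w.append(wgt.astype(self.dtype))
            self.conv_b.append(np.zeros(c_out, dtype=self.dtype))
            c_prev = c_out
            h, w = h // 2, w // 2
        flat = h * w * c_prev
        self.fc1_w = rng.normal(0.0, np.sqrt(2.0 / flat),
                                size=(flat, cfg.fc_units)).astype(self.dtype)
        self.fc1_b = np.zeros(cfg.fc_units, dtype=self.dtype)
        # small final-layer init so an untrained model is near-uniform softmax
        self.fc2_w = rng.normal(0.0, 1e-3,
                                size=(cfg.fc_units, cfg.n_classes)).astype(self.dtype)
        self.fc2_b = np.zeros(cfg.n_classes, dtype=self.dtype)

    # -- bookkeeping ---------------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.fc1_w, self.fc1_b,
                self.fc2_w, self.fc2_b]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        nb = self.config.n_blocks
        self.conv_w = [p.copy() for p in params[:nb]]
        self.conv_b = [p.copy() for p in params[nb:2 * nb]]
        self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b = (p.copy() for p in params[2 * nb:])

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters))

    # -- passes --------------------------------------------------------------
    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.input_mean) / self.input_std).astype(self.dtype)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Class probabilities for a batch (N, C, H, W). ``cache`` (a dict)
        collects intermediates for :meth:`backward` when supplied."""
        cfg = self.config
        a = self._standardize(x)
        caches = []
        for b in range(cfg.n_blocks):
            z = _conv3x3(a, self.conv_w[b], self.conv_b[b])
            r = np.maximum(0, z)
            p, am = _maxpool2(r)
            caches.append((a, z, am, r.shape))
            a = p
        flat = a.reshape(a.shape[0], -1)
        if train and cfg.dropout_rate > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = (rng.random(flat.shape) >= cfg.dropout_rate)
            flat = flat * keep / (1.0 - cfg.dropout_rate)
        else:
            keep = None
        h1 = flat @ self.fc1_w + self.fc1_b
        r1 = np.maximum(0, h1)
        logits = r1 @ self.fc2_w + self.fc2_b
        probs = softmax(logits)
        if cache is not None:
            cache.update(blocks=caches, flat=flat, keep=keep, h1=h1, r1=r1,
                         pooled_shape=a.shape, probs=probs)
        return probs

    def backward(self, cache: dict, y_onehot: np.ndarray) -> list[np.ndarray]:
        """Gradients of the mean cross-entropy w.r.t. :attr:`parameters`."""
        cfg = self.config
        n = y_onehot.shape[0]
        d_logits = ((cache["probs"] - y_onehot) / n).astype(self.dtype)
        d_fc2_w = cache["r1"].T @ d_logits
        d_fc2_b = d_logits.sum(axis=0)
        d_r1 = d_logits @ self.fc2_w.T
        d_h1 = d_r1 * (cache["h1"] > 0)
        d_fc1_w = cache["flat"].T @ d_h1
        d_fc1_b = d_h1.sum(axis=0)
        d_flat = d_h1 @ self.fc1_w.T
        if cache["keep"] is not None:
            d_flat = d_flat * cache["keep"] / (1.0 - cfg.dropout_rate)
        d_a = d_flat.reshape(cache["pooled_shape"])
        d_conv_w, d_conv_b = [None] * cfg.n_blocks, [None] * cfg.n_blocks
        for b in reversed(range(cfg.n_blocks)):
            a_in, z, am, r_shape = cache["blocks"][b]
            d_r = _maxpool2_backward(d_a, am, r_shape)
            d_z = d_r * (z > 0)
            d_a, d_conv_w[b], d_conv_b[b] = _conv3x3_backward(a_in, self.conv_w[b], d_z)
        return [*d_conv_w, *d_conv_b, d_fc1_w, d_fc1_b, d_fc2_w, d_fc2_b]


def build_mcnn(config: MCNNConfig,
               class_names: Sequence[str] | None = None) -> MCNN:
    """Instantiate the network with seeded He-normal initialization."""
    return MCNN(config, class_names=class_names)


def save_model(model: MCNN, path) -> None:
    """Single-file checkpoint (.npz) with the config and class names embedded."""
    import json
    from dataclasses import asdict

    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters)}
    meta = {"config": asdict(model.config), "class_names": model.class_names,
            "input_mean": model.input_mean, "input_std": model.input_std}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> MCNN:
    """Restore a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg_dict = meta["config"]
        for key in ("input_shape", "channel_progression"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = MCNN(MCNNConfig(**cfg_dict), class_names=meta["class_names"])
        model.input_mean = float(meta["input_mean"])
        model.input_std = float(meta["input_std"])
        n = len(model.parameters)
        model.set_parameters([data[f"param_{i}"] for i in range(n)])
    return model


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _one_hot(y: np.ndarray, m: int) -> np.ndarray:
    out = np.zeros((len(y), m))
    out[np.arange(len(y)), y] = 1.0
    return out


def _evaluate(model: MCNN, x: np.ndarray, y: np.ndarray,
              batch_size: int = 50) -> tuple[float, float]:
    losses, correct = [], 0
    m = model.config.n_classes
    for i in range(0, len(x), batch_size):
        probs = model.forward(x[i:i + batch_size])
        yb = y[i:i + batch_size]
        losses.append(cross_entropy(_one_hot(yb, m), probs) * len(yb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), float(correct / len(x))


def train(model: MCNN, train_data: tuple[np.ndarray, np.ndarray],
          config: MCNNConfig | None = None,
          validation_data: tuple[np.ndarray, np.ndarray] | None = None
          ) -> tuple[MCNN, TrainingHistory]:
    """SGD-with-momentum training loop.

    ``train_data`` is ``(X, y)`` with X of shape (N, C, H, W) and integer
    labels y.  The learning rate follows :func:`lr_schedule` per epoch.  With
    validation data, early stopping restores the best-validation-loss weights
    after ``early_stopping_patience`` epochs without improvement.
    Fully reproducible for a fixed config seed.
    """
    cfg = config or model.config
    x, y = train_data
    x = np.asarray(x)
    y = np.asarray(y, dtype=np.int64)
    present = np.unique(y)
    if validation_data is not None and len(present) < cfg.n_classes:
        missing = sorted(set(range(cfg.n_classes)) - set(present.tolist()))
        raise ValueError(f"training split has empty classes {missing}")

    # input standardization from the training set only
    model.input_mean = float(x.mean())
    model.input_std = float(x.std() + 1e-8)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 0x7261)))
    velocity = [np.zeros_like(p) for p in model.parameters]
    history = TrainingHistory()
    best_val, best_params, since_best = np.inf, None, 0
    m = cfg.n_classes

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg.lr0, cfg.lr_decay_factor, cfg.lr_decay_every)
        order = rng.permutation(len(x))
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            cache: dict = {}
            probs = model.forward(xb, train=True, rng=rng, cache=cache)
            onehot = _one_hot(yb, m)
            epoch_loss += cross_entropy(onehot, probs) * len(idx)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            grads = model.backward(cache, onehot)
            params = model.parameters
            for v, p, g in zip(velocity, params, grads):
                v *= cfg.momentum
                v -= lr * g.astype(p.dtype)
                p += v

        history.learning_rate.append(lr)
        history.train_loss.append(epoch_loss / len(x))
        history.train_accuracy.append(epoch_correct / len(x))
        if validation_data is not None:
            vl, va = _evaluate(model, np.asarray(validation_data[0]),
                               np.asarray(validation_data[1], dtype=np.int64))
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
            if vl < best_val - 1e-12:
                best_val, since_best = vl, 0
                best_params = [p.copy() for p in model.parameters]
            else:
                since_best += 1
                if since_best >= cfg.early_stopping_patience:
                    break
        else:
            history.val_loss.append(np.nan)
            history.val_accuracy.append(np.nan)

    if best_params is not None:
        model.set_parameters(best_params)
    return model, history


def predict(model: MCNN, image: np.ndarray) -> tuple[np.ndarray, str]:
    """Probability vector and argmax class name for one input.

    Accepts (C, H, W) as the network sees it, or an (H, W, depth) volume /
    (H, W) slice, which is moved into channel-first layout first.
    """
    cfg = model.config
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[..., None]
    if x.ndim != 3:
        raise ValueError("predict expects a single image/volume")
    h, w, c_in = cfg.input_shape
    if x.shape == (h, w, c_in):
        x = np.moveaxis(x, -1, 0)
    elif x.shape != (c_in, h, w):
        raise ValueError(
            f"input shape {x.shape} matches neither (H,W,depth)={(h, w, c_in)} "
            f"nor (depth,H,W)={(c_in, h, w)}"
        )
    probs = model.forward(x[None])[0]
    return probs, model.class_names[int(probs.argmax())]
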