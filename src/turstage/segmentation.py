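"""U-net semantic segmentation of uterus and tumor on grayscale slices.

Encoder–decoder with skip connections: the contracting path applies, per
resolution level, two 3x3 convolutions (each followed by a ReLU) and a 2x2
max pool, doubling the channel count; the expansive path upsamples with a
learned 2x2 up-convolution that halves the channels, concatenates the
matching encoder feature map, and applies two further 3x3 convolutions; a
final 1x1 convolution produces the three class scores (background, uterus,
tumor).  Convolutions are same-padded so the output grid matches the input
grid exactly — a deliberate deviation from the classic unpadded variant
that removes all crop bookkeeping (the predictions are full-size overlays
either way).

Training minimizes pixel-wise 3-class cross-entropy with Adam and early
stopping on validation loss; everything (init, shuffling, augmentation) is
driven by a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, Conv1x1, DoubleConv, MaxPool2, Param, UpConv2, softmax_cross_entropy
from .errors import ConfigurationError, ShapeMismatchError

N_CLASSES = 3


@dataclass(frozen=True)
class UnetConfig:
    depth: int = 4
    base_channels: int = 16
    in_size: int = 128
    learning_rate: float = 0.0003
    max_epochs: int = 300
    patience: int = 20          # 0 disables early stopping
    batch_size: int = 4
    seed: int = 0
    per_sequence: bool = True   # one model per MRI sequence kind
    augment_flip: bool = False
    class_weights: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        if self.in_size % (1 << self.depth) != 0:
            raise ConfigurationError(
                f"in_size {self.in_size} not divisible by 2^depth = {1 << self.depth}"
            )
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.max_epochs < 1:
            raise ConfigurationError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class UNet:
    """The wired encoder–decoder; built via :func:`build_unet`."""

    def __init__(self, config: UnetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base = config.depth, config.base_channels
        chans = [base * (1 << i) for i in range(d + 1)]
        self.enc = []
        c_in = 1
        for c in chans[:-1]:
            self.enc.append(DoubleConv(c_in, c, rng))
            c_in = c
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = DoubleConv(chans[-2], chans[-1], rng)
        self.ups = [UpConv2(chans[i + 1], chans[i], rng) for i in reversed(range(d))]
        self.dec = [DoubleConv(2 * chans[i], chans[i], rng) for i in reversed(range(d))]
        self._skip_chans = list(reversed(chans[:-1]))
        self.head = Conv1x1(base, N_CLASSES, rng)

    def params(self) -> list[Param]:
        out = []
        for block in (*self.enc, self.bottleneck, *self.ups, *self.dec, self.head):
            out.extend(block.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []  # collected shallowest level first
        for up, dec, c in reversed(list(zip(self.ups, self.dec, self._skip_chans))):
            d = dec.backward(d)
            dskips.append(np.ascontiguousarray(d[:, :c]))
            d = up.backward(np.ascontiguousarray(d[:, c:]))
        d = self.bottleneck.backward(d)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            d = pool.backward(d) + dskip
            d = block.backward(d)

    # -- weights as flat state ------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ConfigurationError("checkpoint does not match the architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ConfigurationError("checkpoint array shape mismatch")
            p.value[...] = a


def build_unet(config: UnetConfig) -> UNet:
    """Construct a randomly initialized U-net from its configuration.

    The parameter count is a deterministic function of (depth, base_channels);
    identical seeds give identical initial weights.
    """
    return UNet(config)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image standardization to zero mean, unit variance."""
    x = np.asarray(image, dtype=np.float32)
    return (x - x.mean()) / (x.std() + 1e-6)


def _stack(pairs, config: UnetConfig, what: str):
    if not pairs:
        raise ConfigurationError(f"{what} set is empty")
    xs, ys = [], []
    for i, (img, mask) in enumerate(pairs):
        img = np.asarray(img)
        mask = np.asarray(mask)
        if img.shape != mask.shape:
            raise ShapeMismatchError(
                f"{what} pair {i}: image {img.shape} vs mask {mask.shape}"
            )
        if img.shape != (config.in_size, config.in_size):
            raise ShapeMismatchError(
                f"{what} pair {i}: expected {config.in_size}x{config.in_size}, got {img.shape}"
            )
        xs.append(normalize_image(img))
        ys.append(mask.astype(np.int64))
    return np.stack(xs)[:, None], np.stack(ys)


def _epoch_loss(model: UNet, x: np.ndarray, y: np.ndarray,
                weights: np.ndarray | None, batch: int) -> float:
    total, npix = 0.0, 0
    for s in range(0, len(x), batch):
        logits = model.forward(x[s:s + batch], train=False)
        loss, _ = softmax_cross_entropy(logits, y[s:s + batch], weights)
        n = logits.shape[0] * logits.shape[2] * logits.shape[3]
        total += loss * n
        npix += n
    return total / npix


def train(model: UNet, train_set, val_set,
          config: UnetConfig | None = None) -> tuple[UNet, TrainingHistory]:
    """Fit the U-net on (image, mask) pairs; returns best-validation weights.

    Stops after ``max_epochs`` or once validation loss has not improved for
    ``patience`` consecutive epochs (``patience=0`` disables early stopping).
    """
    config = config or model.config
    xt, yt = _stack(train_set, config, "train")
    xv, yv = _stack(val_set, config, "validation")
    weights = (np.asarray(config.class_weights, dtype=np.float32)
               if config.class_weights is not None else None)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params(), config.learning_rate)
    history = TrainingHistory()
    best_val, best_state, since_best = np.inf, model.state(), 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xt))
        ep_loss, nb = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            xb, yb = xt[idx], yt[idx]
            if config.augment_flip:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy(); yb = yb.copy()
                xb[flip] = xb[flip, :, :, ::-1]
                yb[flip] = yb[flip, :, ::-1]
            logits = model.forward(xb, train=True)
            loss, grad = softmax_cross_entropy(logits, yb, weights)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            ep_loss += loss; nb += 1
        history.train_loss.append(ep_loss / nb)
        vloss = _epoch_loss(model, xv, yv, weights, config.batch_size)
        history.val_loss.append(vloss)
        history.stopped_epoch = epoch
        if vloss < best_val - 1e-7:
            best_val, best_state, since_best = vloss, model.state(), 0
            history.best_epoch = epoch
        else:
            since_best += 1
            if config.patience > 0 and since_best >= config.patience:
                break
    model.load_state(best_state)
    return model, history


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax segmentation; ties resolve to the lower class index."""
    image = np.asarray(image)
    size = model.config.in_size
    if image.shape != (size, size):
        raise ShapeMismatchError(f"expected {size}x{size} image, got {image.shape}")
    logits = model.forward(normalize_image(image)[None, None], train=False)
    return logits[0].argmax(axis=0).astype(np.uint8)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to size x size (for images whose scale differs)."""
    from scipy.ndimage import zoom

    r = np.asarray(image, dtype=np.float64)
    return zoom(r, (size / r.shape[0], size / r.shape[1]), order=1)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor resize preserving the label codes."""
    from scipy.ndimage import zoom

    m = np.asarray(mask)
    return zoom(m, (size / m.shape[0], size / m.shape[1]), order=0).astype(m.dtype)


def save_checkpoint(model: UNet, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz",
             **{f"p{i}": a for i, a in enumerate(model.state())})
    (directory / "config.json").write_text(json.dumps(asdict(model.config), indent=1))


def load_checkpoint(directory: Path) -> UNet:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    if cfg.get("class_weights") is not None:
        cfg["class_weights"] = tuple(cfg["class_weights"])
    model = build_unet(UnetConfig(**cfg))
    with np.load(directory / "weights.npz") as z:
        model.load_state([z[f"p{i}"] for i in range(len(z.files))])
    return model
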