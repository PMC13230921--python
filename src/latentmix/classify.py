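"""Image classifiers under the study's training protocol.

Two compact from-scratch architectures sit behind one contract:

* ``transformer`` — patch embedding, learned positions, two pre-norm
  single-head self-attention blocks with MLPs, mean-pooled head;
* ``conv_residual`` — strided convolutional stages with identity residual
  blocks and a global-average-pool linear head.

Training minimises softmax cross-entropy with AdamW and a linear
learning-rate decay to zero, applying a random resized crop and random
horizontal flip to each training image each epoch. Inference applies no
augmentation and is deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .data_model import ImageRecord
from .errors import ValidationError
from .nn import AdamW, Conv2d, Dense, LayerNorm, Module, Parameter, Tensor
from .vae_core import TrainingTrace


@dataclass
class ClassifierConfig:
    arch: str = "transformer"  # transformer | conv_residual
    image_side: int = 64
    patch_size: int = 8
    embed_dim: int = 32
    n_blocks: int = 2
    conv_channels: tuple[int, ...] = (8, 16, 32)
    epochs: int = 30
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    crop_scale: tuple[float, float] = (0.7, 1.0)
    hflip_prob: float = 0.5
    ema_decay: float = 0.0  # 0 disables; >0 averages weights over training
    tail_avg_frac: float = 0.0  # 0 disables; else Polyak-average last frac of steps
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ("transformer", "conv_residual"):
            raise ValidationError(f"unknown arch {self.arch!r}")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.image_side % self.patch_size != 0:
            raise ValidationError("patch_size must divide image_side")


@dataclass
class PredictionSet:
    """Per-record class scores with the audit fields evaluation needs."""

    record_ids: list[str]
    true_labels: list[str]
    scores: np.ndarray  # (n, n_classes), rows sum to 1
    classes: tuple[str, ...]
    positive_class: str

    def __post_init__(self):
        rows = np.asarray(self.scores).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValidationError("score rows must sum to 1")

    def positive_scores(self) -> np.ndarray:
        return self.scores[:, self.classes.index(self.positive_class)]

    def binary_truth(self) -> np.ndarray:
        return np.array([1 if t == self.positive_class else 0 for t in self.true_labels])


def _resize_bilinear(image: np.ndarray, side: int) -> np.ndarray:
    """Separable bilinear resize of an HxWxC array (fast path for augmentation)."""
    h, w = image.shape[:2]
    if (h, w) == (side, side):
        return image
    ys = np.clip((np.arange(side) + 0.5) * h / side - 0.5, 0, h - 1)
    xs = np.clip((np.arange(side) + 0.5) * w / side - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None, None]
    wx = (xs - x0)[None, :, None]
    top = image[y0][:, x0] * (1 - wx) + image[y0][:, x1] * wx
    bot = image[y1][:, x0] * (1 - wx) + image[y1][:, x1] * wx
    return top * (1 - wy) + bot * wy


def augment_image(image: np.ndarray, config: ClassifierConfig, seed: int) -> np.ndarray:
    """Seeded random resized crop to ``image_side`` then horizontal flip."""
    rng = np.random.default_rng(seed)
    side = image.shape[0]
    lo, hi = config.crop_scale
    scale = rng.uniform(lo, hi)
    crop = max(1, int(round(np.sqrt(scale) * side)))
    y0 = int(rng.integers(0, side - crop + 1))
    x0 = int(rng.integers(0, side - crop + 1))
    out = image[y0 : y0 + crop, x0 : x0 + crop]
    out = _resize_bilinear(out, config.image_side)
    if rng.uniform() < config.hflip_prob:
        out = out[:, ::-1]
    return np.clip(np.ascontiguousarray(out, dtype=np.float64), 0.0, 1.0)


class _TransformerNet(Module):
    def __init__(self, config: ClassifierConfig, n_classes: int, rng: np.random.Generator):
        p, d = config.patch_size, config.embed_dim
        self.p = p
        self.n_tokens = (config.image_side // p) ** 2
        self.embed = Dense(p * p * 3, d, rng)
        self.pos = Parameter(0.02 * rng.standard_normal((self.n_tokens, d)))
        self.blocks = []
        for _ in range(config.n_blocks):
            blk = Module()
            blk.ln1 = LayerNorm(d)
            blk.wq, blk.wk, blk.wv, blk.wo = (Dense(d, d, rng) for _ in range(4))
            blk.ln2 = LayerNorm(d)
            blk.fc1 = Dense(d, 2 * d, rng)
            blk.fc2 = Dense(2 * d, d, rng)
            self.blocks.append(blk)
        self.ln_out = LayerNorm(d)
        self.head = Dense(d, n_classes, rng)
        self.scale = 1.0 / np.sqrt(d)

    def forward(self, x: Tensor) -> Tensor:
        b, s, _, _ = x.shape
        p = self.p
        nh = s // p
        tokens = (
            x.reshape(b, nh, p, nh, p, 3)
            .swapaxes(2, 3)
            .reshape(b, self.n_tokens, p * p * 3)
        )
        h = self.embed(tokens) + self.pos
        for blk in self.blocks:
            hn = blk.ln1(h)
            q, k, v = blk.wq(hn), blk.wk(hn), blk.wv(hn)
            attn = (q @ k.swapaxes(1, 2) * self.scale).softmax(axis=-1)
            h = h + blk.wo(attn @ v)
            hn = blk.ln2(h)
            h = h + blk.fc2(blk.fc1(hn).relu())
        pooled = self.ln_out(h.mean(axis=1))
        return self.head(pooled)


class _ConvResidualNet(Module):
    def __init__(self, config: ClassifierConfig, n_classes: int, rng: np.random.Generator):
        chans = (3,) + tuple(config.conv_channels)
        self.downs = [
            Conv2d(chans[i], chans[i + 1], rng, stride=2, pad=1) for i in range(len(config.conv_channels))
        ]
        self.res_a = [Conv2d(c, c, rng, stride=1, pad=1) for c in config.conv_channels]
        self.res_b = [Conv2d(c, c, rng, stride=1, pad=1) for c in config.conv_channels]
        self.head = Dense(config.conv_channels[-1], n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for down, ra, rb in zip(self.downs, self.res_a, self.res_b):
            h = down(h).relu()
            h = (h + rb(ra(h).relu())).relu()  # identity residual block
        pooled = h.mean(axis=(1, 2))
        return self.head(pooled)


class Classifier:
    """Trained model plus its label ordering and config."""

    def __init__(self, config: ClassifierConfig, classes: tuple[str, ...]):
        self.config = config
        self.classes = classes
        rng = np.random.default_rng(config.seed)
        if config.arch == "transformer":
            self.net: Module = _TransformerNet(config, len(classes), rng)
        else:
            self.net = _ConvResidualNet(config, len(classes), rng)

    def logits(self, images: np.ndarray) -> np.ndarray:
        return self.net.forward(Tensor(images)).data

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for a in self.net.state_arrays():
            h.update(a.tobytes())
        return h.hexdigest()


def train_classifier(
    train_records: list[ImageRecord], config: ClassifierConfig
) -> tuple[Classifier, TrainingTrace]:
    """Seeded supervised training; deterministic given (seed, config, data)."""
    classes = tuple(sorted({r.label for r in train_records}))
    if len(classes) < 2:
        raise ValidationError("training requires at least 2 classes")
    for r in train_records:
        if r.image.shape[0] != config.image_side:
            raise ValidationError("record image side does not match config.image_side")
    model = Classifier(config, classes)
    y = np.array([classes.index(r.label) for r in train_records])
    n = len(train_records)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    opt = AdamW(
        model.net.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        total_steps=config.epochs * steps_per_epoch,
    )
    rng = np.random.default_rng(config.seed + 1)
    trace = TrainingTrace()
    ema = [p.data.copy() for p in model.net.parameters()] if config.ema_decay > 0 else None
    total_steps = config.epochs * steps_per_epoch
    # uniform average of the last fraction of steps; window scales with
    # training length so pools of different size are treated alike
    tail_start = int(np.ceil(total_steps * (1 - config.tail_avg_frac)))
    tail_sum = (
        [np.zeros_like(p.data) for p in model.net.parameters()]
        if config.tail_avg_frac > 0
        else None
    )
    tail_count = 0
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = np.stack(
                [
                    augment_image(
                        train_records[i].image, config, int(rng.integers(0, 2**31 - 1))
                    )
                    for i in idx
                ]
            )
            logits = model.net.forward(Tensor(batch))
            loss = logits.cross_entropy(y[idx])
            model.net.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                d = config.ema_decay
                for e, p in zip(ema, model.net.parameters()):
                    e *= d
                    e += (1 - d) * p.data
            step += 1
            if tail_sum is not None and step >= tail_start:
                for t, p in zip(tail_sum, model.net.parameters()):
                    t += p.data
                tail_count += 1
            ep_loss += float(loss.data)
            ep_correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
            n_batches += 1
        trace.append(total=ep_loss / n_batches, accuracy=ep_correct / n)
    if ema is not None and config.epochs > 0:
        model.net.load_state_arrays(ema)
    if tail_sum is not None and tail_count > 0:
        model.net.load_state_arrays([t / tail_count for t in tail_sum])
    return model, trace


def predict_scores(
    model: Classifier, records: list[ImageRecord], positive_class: str | None = None
) -> PredictionSet:
    """Softmax class scores without augmentation; deterministic.

    The default positive class for binary problems is ``x_linked`` when
    present, otherwise the last class in sorted order; it is recorded in the
    returned set so every downstream report states the polarity.
    """
    for r in records:
        if r.image.shape[0] != model.config.image_side:
            raise ValidationError("record image side does not match the trained model")
    images = np.stack([r.image for r in records])
    logits = []
    for start in range(0, len(records), 64):
        logits.append(model.logits(images[start : start + 64]))
    logits = np.concatenate(logits, axis=0).astype(np.float64)
    shifted = logits - logits.max(axis=1, keepdims=True)
    scores = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
    if positive_class is None:
        positive_class = "x_linked" if "x_linked" in model.classes else model.classes[-1]
    return PredictionSet(
        record_ids=[r.record_id for r in records],
        true_labels=[r.label for r in records],
        scores=scores,
        classes=model.classes,
        positive_class=positive_class,
    )
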