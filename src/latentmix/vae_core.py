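"""Compact convolutional VAE and a DCGAN baseline generator.

The VAE maps images to a flat Gaussian latent (mean and log-variance per
dimension) through a strided-convolution encoder, and decodes through
nearest-neighbour upsampling + convolution. Training maximises the ELBO:
pixel-wise mean squared reconstruction error plus ``beta`` times the closed-
form KL divergence to the standard-normal prior.

Both the VAE and the GAN implement a common codec-style plug-in contract
(``encode`` / ``decode`` / ``latent_dim``) so that alternative backbones —
including pretrained ones — can be swapped in behind the expansion module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data_model import Cohort, ImageRecord
from .errors import StateError, TrainingError, ValidationError
from .nn import AdamW, Conv2d, Dense, Module, Parameter, Tensor

LOGVAR_CLAMP = 20.0  # numeric safety bound on log sigma^2


@dataclass
class VAEConfig:
    latent_dim: int = 128
    image_side: int = 64
    channels: tuple[int, ...] = (8, 16, 32)
    kl_weight: float = 1e-4
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValidationError("latent_dim must be >= 2")
        if self.image_side % (2 ** len(self.channels)) != 0:
            raise ValidationError("image_side must be divisible by 2^levels")


@dataclass
class LatentCode:
    """Encoder output: posterior mean and log-variance, optional sampled z."""

    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValidationError("latent code must be finite")

    @property
    def dim(self) -> int:
        return int(self.mu.shape[-1])


@dataclass
class TrainingTrace:
    epochs: list[dict[str, float]] = field(default_factory=list)

    def append(self, **terms: float) -> None:
        if not all(np.isfinite(v) for v in terms.values()):
            raise TrainingError(f"non-finite loss at epoch {len(self.epochs)}: {terms}")
        self.epochs.append({k: float(v) for k, v in terms.items()})

    def __len__(self) -> int:
        return len(self.epochs)

    def totals(self, key: str = "total") -> list[float]:
        return [e[key] for e in self.epochs]


def _stack_images(records_or_images) -> np.ndarray:
    imgs = []
    for item in records_or_images:
        imgs.append(item.image if isinstance(item, ImageRecord) else np.asarray(item))
    return np.stack(imgs)


class ConvVAE(Module):
    """Strided-conv encoder, upsample-conv decoder, flat Gaussian latent."""

    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        side = config.image_side
        chans = (3,) + tuple(config.channels)
        self.enc_layers = [
            Conv2d(chans[i], chans[i + 1], rng, stride=2, pad=1) for i in range(len(config.channels))
        ]
        self.bottom_side = side // (2 ** len(config.channels))
        flat = self.bottom_side**2 * chans[-1]
        self.fc_mu = Dense(flat, config.latent_dim, rng)
        self.fc_logvar = Dense(flat, config.latent_dim, rng)
        self.fc_dec = Dense(config.latent_dim, flat, rng)
        # decoder: conv after each of the first upsamples, then a final
        # upsample straight into the output conv (keeps the full-resolution
        # stage to a single convolution)
        rev = tuple(reversed(chans[1:]))
        self.dec_layers = [
            Conv2d(rev[i], rev[i + 1], rng, stride=1, pad=1) for i in range(len(rev) - 1)
        ]
        self.out_conv = Conv2d(rev[-1], 3, rng, stride=1, pad=1)
        self.trained = False

    # -- differentiable paths (used by training) -----------------------------

    def encode_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for layer in self.enc_layers:
            h = layer(h).relu()
        b = h.shape[0]
        h = h.reshape(b, -1)
        return self.fc_mu(h), self.fc_logvar(h)

    def decode_t(self, z: Tensor) -> Tensor:
        b = z.shape[0]
        c_bottom = self.config.channels[-1]
        h = self.fc_dec(z).relu().reshape(b, self.bottom_side, self.bottom_side, c_bottom)
        for layer in self.dec_layers:
            h = layer(h.upsample2x()).relu()
        return self.out_conv(h.upsample2x()).sigmoid()

    # -- codec contract ------------------------------------------------------

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def _require_trained(self):
        if not self.trained:
            raise StateError("model must be trained before encoding/decoding")

    def encode(self, image: np.ndarray | ImageRecord) -> LatentCode:
        """Posterior (mu, log sigma^2) of one image; deterministic given weights."""
        self._require_trained()
        img = image.image if isinstance(image, ImageRecord) else np.asarray(image)
        if img.shape[0] != self.config.image_side:
            raise ValidationError(
                f"image side {img.shape[0]} != configured {self.config.image_side}"
            )
        mu, logvar = self.encode_t(Tensor(img[None]))
        return LatentCode(mu.data[0].copy(), np.clip(logvar.data[0], -LOGVAR_CLAMP, LOGVAR_CLAMP))

    def encode_batch(self, records_or_images) -> tuple[np.ndarray, np.ndarray]:
        self._require_trained()
        x = _stack_images(records_or_images)
        mu, logvar = self.encode_t(Tensor(x))
        return mu.data.copy(), np.clip(logvar.data, -LOGVAR_CLAMP, LOGVAR_CLAMP)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode one latent vector to an image in [0, 1]; deterministic."""
        self._require_trained()
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 1 or z.shape[0] != self.config.latent_dim:
            raise ValidationError(f"z must have length {self.config.latent_dim}")
        return self.decode_t(Tensor(z[None])).data[0].copy()

    def decode_batch(self, z: np.ndarray) -> np.ndarray:
        self._require_trained()
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.config.latent_dim:
            raise ValidationError(f"z must be (n, {self.config.latent_dim})")
        return self.decode_t(Tensor(z)).data.copy()

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"w{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps(
                    {"format": "latentmix-vae-v1", "config": asdict(self.config), "trained": self.trained}
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConvVAE":
        with np.load(path) as blob:
            meta = json.loads(bytes(blob["__meta__"]).decode())
            cfg = meta["config"]
            cfg["channels"] = tuple(cfg["channels"])
            model = cls(VAEConfig(**cfg))
            model.load_state_arrays([blob[f"w{i}"] for i in range(len(model.parameters()))])
            model.trained = bool(meta["trained"])
        return model


def reparameterize(code: LatentCode, seed: int) -> LatentCode:
    """Draw z = mu + exp(logvar/2) * eps with a seeded standard-normal eps."""
    rng = np.random.default_rng(seed)
    logvar = np.clip(code.logvar, -LOGVAR_CLAMP, LOGVAR_CLAMP)
    eps = rng.standard_normal(code.mu.shape)
    return LatentCode(code.mu, code.logvar, z=code.mu + np.exp(0.5 * logvar) * eps)


def kl_closed_form(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ) = 1/2 sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    logvar = np.clip(logvar, -LOGVAR_CLAMP, LOGVAR_CLAMP)
    return float(0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar))


def elbo_loss(
    image: np.ndarray, reconstruction: np.ndarray, code: LatentCode, beta: float
) -> tuple[float, float, float]:
    """(reconstruction MSE, KL term, total = recon + beta * KL)."""
    image = np.asarray(image)
    reconstruction = np.asarray(reconstruction)
    if image.shape != reconstruction.shape:
        raise ValidationError("image and reconstruction shapes differ")
    if not (np.all(np.isfinite(image)) and np.all(np.isfinite(reconstruction))):
        raise ValidationError("non-finite inputs to elbo_loss")
    recon = float(np.mean((image - reconstruction) ** 2))
    kl = kl_closed_form(code.mu, code.logvar)
    return recon, kl, recon + beta * kl


def train_vae(cohort: Cohort | list[ImageRecord], config: VAEConfig) -> tuple[ConvVAE, TrainingTrace]:
    """Seeded ELBO optimisation of a fresh ConvVAE on the cohort's real images."""
    records = list(cohort.records if isinstance(cohort, Cohort) else cohort)
    if any(r.is_synthetic for r in records):
        raise ValidationError("train_vae accepts only real records")
    if len(records) < 2:
        raise ValidationError("need at least 2 training images")
    x_all = _stack_images(records)
    model = ConvVAE(config)
    model.trained = True  # weights are defined from init; flag gates the codec API
    opt = AdamW(model.parameters(), lr=config.learning_rate, weight_decay=0.0)
    rng = np.random.default_rng(config.seed + 1)
    trace = TrainingTrace()
    n = x_all.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep_recon = ep_kl = ep_total = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Tensor(x_all[idx])
            mu, logvar = model.encode_t(xb)
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
            recon = model.decode_t(z)
            mse = ((recon - xb) ** 2.0).mean()
            kl = ((mu**2.0 + logvar.exp() - 1.0 - logvar).sum() * 0.5) * (1.0 / len(idx))
            loss = mse + config.kl_weight * kl
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_recon += float(mse.data)
            ep_kl += float(kl.data)
            ep_total += float(loss.data)
            n_batches += 1
        trace.append(
            recon=ep_recon / n_batches, kl=ep_kl / n_batches, total=ep_total / n_batches
        )
    return model, trace


# ---------------------------------------------------------------------------
# DCGAN baseline
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    gan_latent_dim: int = 100
    output_side: int = 64
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 2e-4
    seed: int = 0

    def __post_init__(self):
        if self.gan_latent_dim < 1:
            raise ValidationError("gan_latent_dim must be >= 1")


def _gan_geometry(side: int) -> tuple[int, int]:
    """(start_side, n_upsamples) with start side in [4, 7]."""
    k = 0
    s = side
    while s % 2 == 0 and s // 2 >= 4:
        s //= 2
        k += 1
    if not (4 <= s <= 7):
        raise ValidationError(f"unsupported GAN output side {side}")
    return s, k


class DCGANGenerator(Module):
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        self.start_side, self.n_up = _gan_geometry(config.output_side)
        widths = [max(8, 64 // (2**i)) for i in range(self.n_up + 1)]
        self.widths = widths
        self.fc = Dense(config.gan_latent_dim, self.start_side**2 * widths[0], rng)
        self.convs = [Conv2d(widths[i], widths[i + 1], rng, stride=1, pad=1) for i in range(self.n_up)]
        self.out_conv = Conv2d(widths[-1], 3, rng, stride=1, pad=1)

    def forward(self, z: Tensor) -> Tensor:
        b = z.shape[0]
        h = self.fc(z).relu().reshape(b, self.start_side, self.start_side, self.widths[0])
        for conv in self.convs:
            h = conv(h.upsample2x()).relu()
        return self.out_conv(h).sigmoid()


class DCGANDiscriminator(Module):
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        _, n_down = _gan_geometry(config.output_side)
        widths = [3] + [min(64, 16 * (2**i)) for i in range(n_down)]
        self.convs = [
            Conv2d(widths[i], widths[i + 1], rng, stride=2, pad=1) for i in range(n_down)
        ]
        bottom = config.output_side // (2**n_down)
        self.fc = Dense(bottom**2 * widths[-1], 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.fc(h.reshape(h.shape[0], -1))


def train_dcgan(
    cohort: Cohort | list[ImageRecord], config: GeneratorConfig
) -> tuple[DCGANGenerator, TrainingTrace]:
    """Alternating BCE updates of generator and discriminator; seeded."""
    records = list(cohort.records if isinstance(cohort, Cohort) else cohort)
    if len(records) < 2:
        raise ValidationError("need at least 2 real training images")
    x_all = _stack_images(records)
    if x_all.shape[1] != config.output_side:
        raise ValidationError("image side does not match GeneratorConfig.output_side")
    rng = np.random.default_rng(config.seed)
    gen = DCGANGenerator(config, rng)
    disc = DCGANDiscriminator(config, rng)
    g_opt = AdamW(gen.parameters(), lr=config.learning_rate, betas=(0.5, 0.999), weight_decay=0.0)
    d_opt = AdamW(disc.parameters(), lr=config.learning_rate, betas=(0.5, 0.999), weight_decay=0.0)
    trace = TrainingTrace()
    n = x_all.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_loss_sum = g_loss_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            real = Tensor(x_all[idx])
            b = len(idx)
            z = Tensor(rng.standard_normal((b, config.gan_latent_dim)))
            fake = gen.forward(z)
            # discriminator step (fake detached by re-wrapping the array)
            d_real = disc.forward(real).bce_with_logits(np.ones((b, 1)))
            d_fake = disc.forward(Tensor(fake.data)).bce_with_logits(np.zeros((b, 1)))
            d_loss = d_real + d_fake
            disc.zero_grad()
            d_loss.backward()
            d_opt.step()
            # generator step
            g_loss = disc.forward(fake).bce_with_logits(np.ones((b, 1)))
            gen.zero_grad()
            disc.zero_grad()
            g_loss.backward()
            g_opt.step()
            if not (np.isfinite(d_loss.data) and np.isfinite(g_loss.data)):
                raise TrainingError(f"GAN diverged at epoch {epoch}")
            d_loss_sum += float(d_loss.data)
            g_loss_sum += float(g_loss.data)
            n_batches += 1
        trace.append(d_loss=d_loss_sum / n_batches, g_loss=g_loss_sum / n_batches)
    return gen, trace


def sample_dcgan(generator: DCGANGenerator, n: int, seed: int) -> np.ndarray:
    """n images from seeded z ~ N(0, I); shape (n, side, side, 3), values in [0, 1]."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, generator.config.gan_latent_dim))
    out = []
    for start in range(0, n, 32):
        out.append(generator.forward(Tensor(z[start : start + 32])).data)
    return np.concatenate(out, axis=0) if out else np.zeros((0, generator.config.output_side, generator.config.output_side, 3))
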