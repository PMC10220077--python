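"""Restoration models: autoencoder, U-Net, and a pix2pix-style conditional GAN.

All three map a min-max-normalized corrupted image in [0, 1] to a restored
image in [0, 1] (sigmoid output); :func:`correct_image` rescales onto
[0, 255].  The autoencoder and U-Net train with mean squared error.  The
conditional GAN couples a U-Net generator with a 4-layer PatchGAN
discriminator that sees the (condition, candidate) image pair, and the
generator objective adds an L1 fidelity term weighted by lambda = 100:

    G* = arg min_G max_D  E[log D(x, y)] + E[log(1 - D(x, G(x, z)))]
                          + lambda * E|y - G(x, z)|

Generator stochasticity z is realized as dropout active during training.
Networks are optimized with Adam (learning rate 0.0002, batch size 1 at
paper scale) and are built on the package's numpy autograd engine, so
training is exactly reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .dataset import DatasetSplit, denormalize_output, normalize_input
from .nn import autograd as ag
from .nn.autograd import Tensor
from .types import ImageGrid, InvalidConfigError, ShapeError

__all__ = [
    "AESpec", "UNetSpec", "CGANSpec", "TrainingConfig",
    "Autoencoder", "UNet", "PatchDiscriminator",
    "build_autoencoder", "build_unet", "build_discriminator",
    "cgan_adversarial_loss", "cgan_generator_objective",
    "train", "correct_image", "TrainedModel", "load_checkpoint",
]

_EPS = 1e-7  # probability clamp before logs


@dataclass
class AESpec:
    """Stacked convolutional autoencoder: Conv-ReLU-MaxPool encoder stacks
    mirrored by Upsample-Conv-ReLU decoder stacks, channels doubling per stack."""

    n_stacks: int = 4
    first_channels: int = 32
    filter_size: int = 2
    pool_size: int = 2


@dataclass
class UNetSpec:
    """Symmetric encoder/decoder with concatenation skips at each depth."""

    depth: int = 4
    first_channels: int = 64
    filter_size: int = 3
    dropout_p: float = 0.0       # >0 only when used as the CGAN generator
    use_batchnorm: bool = False  # Conv-BatchNorm-ReLU modules (CGAN generator)


@dataclass
class CGANSpec:
    """U-Net generator + 4-convolution PatchGAN discriminator."""

    generator: UNetSpec = field(
        default_factory=lambda: UNetSpec(dropout_p=0.5, use_batchnorm=True))
    disc_first_channels: int = 64
    lambda_l1: float = 100.0


@dataclass
class TrainingConfig:
    learning_rate: float = 2e-4
    batch_size: int = 1
    epochs: int = 100
    seed: int = 0
    image_size: int = 256
    #: optional global gradient-norm ceiling; stabilizes small-batch training
    clip_grad_norm: float | None = None

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be > 0")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise InvalidConfigError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# architectures


class Autoencoder(nn.Module):
    def __init__(self, spec: AESpec, image_size: int, rng: np.random.Generator):
        if spec.pool_size != 2:
            raise InvalidConfigError("only pool_size = 2 is supported")
        if spec.n_stacks < 1:
            raise InvalidConfigError("n_stacks must be >= 1")
        if image_size % (spec.pool_size ** spec.n_stacks) != 0:
            raise InvalidConfigError(
                f"image_size {image_size} not divisible by "
                f"{spec.pool_size}^{spec.n_stacks}"
            )
        self.spec = spec
        self.image_size = image_size
        self.bottleneck_size = image_size // (spec.pool_size ** spec.n_stacks)
        k = spec.filter_size
        channels = [spec.first_channels * 2 ** i for i in range(spec.n_stacks)]
        self.encoder = []
        cin = 1
        for ch in channels:
            self.encoder.append(nn.Conv2d(cin, ch, k, rng))
            cin = ch
        # decoder mirrors the encoder: deepest channels back down, halving
        self.decoder = []
        cin = channels[-1]
        for ch in reversed(channels[:-1]) if spec.n_stacks > 1 else []:
            self.decoder.append(nn.Conv2d(cin, ch, k, rng))
            cin = ch
        self.decoder.append(nn.Conv2d(cin, spec.first_channels, k, rng))
        self.head = nn.Conv2d(spec.first_channels, 1, k, rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = x
        for conv in self.encoder:
            h = ag.maxpool2x2(ag.relu(conv(h)))
        for conv in self.decoder:
            h = ag.relu(conv(ag.upsample2x(h)))
        return ag.sigmoid(self.head(h))

    __call__ = forward


class UNet(nn.Module):
    def __init__(self, spec: UNetSpec, image_size: int, rng: np.random.Generator):
        if spec.depth < 1:
            raise InvalidConfigError("depth must be >= 1")
        if image_size % (2 ** spec.depth) != 0:
            raise InvalidConfigError(
                f"image_size {image_size} not divisible by 2^{spec.depth}"
            )
        self.spec = spec
        self.image_size = image_size
        k = spec.filter_size
        ch = [spec.first_channels * 2 ** i for i in range(spec.depth + 1)]
        bn = (lambda c: nn.BatchNorm2d(c)) if spec.use_batchnorm else (lambda c: None)
        self.enc1 = []  # first conv of each encoder level
        self.enc2 = []  # second conv
        self.enc1_bn, self.enc2_bn = [], []
        cin = 1
        for d in range(spec.depth):
            self.enc1.append(nn.Conv2d(cin, ch[d], k, rng))
            self.enc2.append(nn.Conv2d(ch[d], ch[d], k, rng))
            self.enc1_bn.append(bn(ch[d]))
            self.enc2_bn.append(bn(ch[d]))
            cin = ch[d]
        self.bott1 = nn.Conv2d(ch[spec.depth - 1], ch[spec.depth], k, rng)
        self.bott2 = nn.Conv2d(ch[spec.depth], ch[spec.depth], k, rng)
        self.bott1_bn, self.bott2_bn = bn(ch[spec.depth]), bn(ch[spec.depth])
        self.up = []     # channel-halving conv after upsampling
        self.dec1 = []   # conv after skip concatenation
        self.dec2 = []
        self.up_bn, self.dec1_bn, self.dec2_bn = [], [], []
        for d in reversed(range(spec.depth)):
            self.up.append(nn.Conv2d(ch[d + 1], ch[d], k, rng))
            self.dec1.append(nn.Conv2d(2 * ch[d], ch[d], k, rng))
            self.dec2.append(nn.Conv2d(ch[d], ch[d], k, rng))
            self.up_bn.append(bn(ch[d]))
            self.dec1_bn.append(bn(ch[d]))
            self.dec2_bn.append(bn(ch[d]))
        self.head = nn.Conv2d(spec.first_channels, 1, 1, rng, pad=0)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    @staticmethod
    def _block(h: Tensor, conv, norm, training: bool) -> Tensor:
        h = conv(h)
        if norm is not None:
            h = norm(h, training)
        return ag.relu(h)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        skips = []
        h = x
        for c1, c2, b1, b2 in zip(self.enc1, self.enc2, self.enc1_bn, self.enc2_bn):
            h = self._block(self._block(h, c1, b1, training), c2, b2, training)
            skips.append(h)
            h = ag.maxpool2x2(h)
        h = self._block(h, self.bott1, self.bott1_bn, training)
        h = self._block(h, self.bott2, self.bott2_bn, training)
        if self.spec.dropout_p > 0:
            h = ag.dropout(h, self.spec.dropout_p, self._dropout_rng, training)
        for i, (up, c1, c2) in enumerate(zip(self.up, self.dec1, self.dec2)):
            h = self._block(ag.upsample2x(h), up, self.up_bn[i], training)
            h = ag.concat(skips[-(i + 1)], h, axis=1)
            h = self._block(h, c1, self.dec1_bn[i], training)
            h = self._block(h, c2, self.dec2_bn[i], training)
            # dropout in the two deepest decoder levels (pix2pix convention)
            if self.spec.dropout_p > 0 and i < 2:
                h = ag.dropout(h, self.spec.dropout_p, self._dropout_rng, training)
        return ag.sigmoid(self.head(h))

    __call__ = forward


class PatchDiscriminator(nn.Module):
    """4 stride-2 convolutions (Conv-BatchNorm-LeakyReLU; no norm on the
    first) followed by a 1-channel projection + sigmoid: a patch map whose
    spatial extent is input_size / 16."""

    def __init__(self, first_channels: int, image_size: int, rng: np.random.Generator):
        if image_size % 16 != 0:
            raise InvalidConfigError("discriminator needs image_size divisible by 16")
        ch = [first_channels * 2 ** i for i in range(4)]
        self.convs = []
        self.norms = []
        cin = 2  # condition + candidate, concatenated on channels
        for i, c in enumerate(ch):
            self.convs.append(nn.Conv2d(cin, c, 4, rng, stride=2, pad=1))
            self.norms.append(None if i == 0 else nn.BatchNorm2d(c))
            cin = c
        self.norm_layers = [n for n in self.norms if n is not None]  # for params
        self.head = nn.Conv2d(cin, 1, 3, rng)

    def forward(self, condition: Tensor, candidate: Tensor,
                training: bool = False) -> Tensor:
        h = ag.concat(condition, candidate, axis=1)
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h, training)
            h = ag.leaky_relu(h, 0.2)
        return ag.sigmoid(self.head(h))

    __call__ = forward


def build_autoencoder(spec: AESpec, image_size: int, seed: int = 0) -> Autoencoder:
    return Autoencoder(spec, image_size, np.random.default_rng(seed))


def build_unet(spec: UNetSpec, image_size: int, seed: int = 0) -> UNet:
    return UNet(spec, image_size, np.random.default_rng(seed))


def build_discriminator(spec: CGANSpec, image_size: int, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec.disc_first_channels, image_size,
                              np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# losses


def _as_prob_array(p) -> np.ndarray:
    arr = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("discriminator outputs must lie in [0, 1]")
    return np.clip(arr, _EPS, 1.0 - _EPS)


def cgan_adversarial_loss(d_real, d_fake) -> float:
    """Minimax GAN value  E[log D(x,y)] + E[log(1 - D(x,G(x,z)))].

    Averages over all patches and batch entries; always <= 0, approaching 0
    from below at the discriminator optimum.
    """
    real = _as_prob_array(d_real)
    fake = _as_prob_array(d_fake)
    return float(np.mean(np.log(real)) + np.mean(np.log(1.0 - fake)))


def cgan_generator_objective(adv_term: float, g_output, target,
                             lambda_l1: float = 100.0) -> float:
    """Generator objective: adversarial term + lambda * mean |G(x) - y|."""
    g = g_output.pixels if isinstance(g_output, ImageGrid) else np.asarray(g_output)
    t = target.pixels if isinstance(target, ImageGrid) else np.asarray(target)
    if g.shape != t.shape:
        raise ShapeError(f"shape mismatch: {g.shape} vs {t.shape}")
    return float(adv_term + lambda_l1 * np.mean(np.abs(g - t)))


def _graph_log_mean(p: Tensor) -> Tensor:
    return ag.mean(ag.log(ag.clip(p, _EPS, 1.0 - _EPS)))


def _graph_log_mean_inv(p: Tensor) -> Tensor:
    one_minus = ag.sub(Tensor(np.ones_like(p.data)), p)
    return ag.mean(ag.log(ag.clip(one_minus, _EPS, 1.0 - _EPS)))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    kind: str
    model: nn.Module
    config: TrainingConfig
    spec: AESpec | UNetSpec | CGANSpec
    history: pd.DataFrame
    discriminator: PatchDiscriminator | None = None

    def save(self, path: str | Path) -> Path:
        """Write an .npz checkpoint with the weights and a config snapshot."""
        path = Path(path)
        arrays = {f"model.{k}": v for k, v in self.model.state_arrays().items()}
        if self.discriminator is not None:
            arrays.update({f"disc.{k}": v for k, v in
                           self.discriminator.state_arrays().items()})
        np.savez(path, **arrays)
        meta = {
            "kind": self.kind,
            "config": asdict(self.config),
            "spec": _spec_to_dict(self.spec),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(path.with_suffix(".history.csv"), index=False)
        return path


def _spec_to_dict(spec) -> dict:
    d = asdict(spec)
    d["__class__"] = type(spec).__name__
    return d


def _spec_from_dict(d: dict):
    d = dict(d)
    cls = {"AESpec": AESpec, "UNetSpec": UNetSpec, "CGANSpec": CGANSpec}[d.pop("__class__")]
    if cls is CGANSpec:
        d["generator"] = UNetSpec(**{k: v for k, v in d["generator"].items()})
    return cls(**d)


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = TrainingConfig(**meta["config"])
    spec = _spec_from_dict(meta["spec"])
    kind = meta["kind"]
    if kind == "ae":
        model = build_autoencoder(spec, config.image_size, seed=config.seed)
    elif kind == "unet":
        model = build_unet(spec, config.image_size, seed=config.seed)
    elif kind == "cgan":
        model = build_unet(spec.generator, config.image_size, seed=config.seed)
    else:
        raise InvalidConfigError(f"unknown model kind {kind!r}")
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        arrays = dict(data)
    model.load_state_arrays(
        {k[len("model."):]: v for k, v in arrays.items() if k.startswith("model.")})
    disc = None
    if any(k.startswith("disc.") for k in arrays):
        disc = build_discriminator(spec, config.image_size, seed=config.seed)
        disc.load_state_arrays(
            {k[len("disc."):]: v for k, v in arrays.items() if k.startswith("disc.")})
    hist_path = path.with_suffix(".history.csv")
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return TrainedModel(kind=kind, model=model, config=config, spec=spec,
                        history=history, discriminator=disc)


def _prepare_batches(samples, batch_size: int):
    """Per-image min-max normalize and stack into NCHW float32 batches."""
    xs, ys = [], []
    for s in samples:
        xs.append(normalize_input(s.corrupted).pixels.astype(np.float32))
        ys.append(normalize_input(s.clean).pixels.astype(np.float32))
    batches = []
    for i in range(0, len(xs), batch_size):
        x = np.stack(xs[i:i + batch_size])[:, None, :, :]
        y = np.stack(ys[i:i + batch_size])[:, None, :, :]
        batches.append((x, y))
    return batches


def train(model_kind: str, split: DatasetSplit, config: TrainingConfig,
          spec: AESpec | UNetSpec | CGANSpec | None = None,
          log_fn=None) -> TrainedModel:
    """Train one restoration model on the split's training subset.

    Inputs and targets are min-max normalized per image.  Returns the model
    with a per-epoch loss history (reconstruction MSE for ae/unet;
    discriminator loss, generator adversarial term and L1 component for the
    conditional GAN).  Fully deterministic for a fixed seed.
    """
    config.validate()
    if not split.train:
        raise InvalidConfigError("training subset is empty")
    shape = split.train[0].clean.shape
    if shape[0] != shape[1] or shape[0] != config.image_size:
        raise InvalidConfigError(
            f"config.image_size={config.image_size} does not match data shape {shape}"
        )
    if model_kind == "ae":
        spec = spec or AESpec()
        model = build_autoencoder(spec, config.image_size, seed=config.seed)
        return _train_recon("ae", model, split, config, spec, log_fn)
    if model_kind == "unet":
        spec = spec or UNetSpec()
        model = build_unet(spec, config.image_size, seed=config.seed)
        return _train_recon("unet", model, split, config, spec, log_fn)
    if model_kind == "cgan":
        spec = spec or CGANSpec()
        return _train_cgan(split, config, spec, log_fn)
    raise InvalidConfigError(f"unknown model kind {model_kind!r}")


def _clip_grad_norm(params, max_norm: float | None) -> None:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    if max_norm is None:
        return
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _check_finite(value: float, what: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite {what} encountered; aborting training")


def _train_recon(kind: str, model, split, config, spec, log_fn) -> TrainedModel:
    opt = nn.Adam(model.parameters(), lr=config.learning_rate, betas=(0.9, 0.999))
    rng = np.random.default_rng(config.seed + 1)
    batches = _prepare_batches(split.train, config.batch_size)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(batches))
        losses = []
        for bi in order:
            x, y = batches[bi]
            opt.zero_grad()
            pred = model.forward(Tensor(x), training=True)
            diff = ag.sub(pred, Tensor(y))
            loss = ag.mean(ag.mul(diff, diff))
            _check_finite(loss.item(), "reconstruction loss")
            loss.backward()
            _clip_grad_norm(opt.params, config.clip_grad_norm)
            opt.step()
            losses.append(loss.item())
        rows.append({"epoch": epoch, "loss": float(np.mean(losses))})
        if log_fn:
            log_fn(f"[{kind}] epoch {epoch}: mse={rows[-1]['loss']:.6f}")
    return TrainedModel(kind=kind, model=model, config=config, spec=spec,
                        history=pd.DataFrame(rows))


def _train_cgan(split, config, spec: CGANSpec, log_fn) -> TrainedModel:
    gen = build_unet(spec.generator, config.image_size, seed=config.seed)
    disc = build_discriminator(spec, config.image_size, seed=config.seed + 1)
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate, betas=(0.5, 0.999))
    opt_d = nn.Adam(disc.parameters(), lr=config.learning_rate, betas=(0.5, 0.999))
    rng = np.random.default_rng(config.seed + 2)
    batches = _prepare_batches(split.train, config.batch_size)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(batches))
        d_losses, g_adv, g_l1 = [], [], []
        for bi in order:
            x, y = batches[bi]
            xt, yt = Tensor(x), Tensor(y)

            fake = gen.forward(xt, training=True)

            # discriminator step: maximize log D(x,y) + log(1 - D(x, G(x)))
            opt_d.zero_grad()
            gen.zero_grad()
            d_real = disc.forward(xt, yt, training=True)
            d_fake = disc.forward(xt, fake.detach(), training=True)
            loss_d = ag.neg(ag.add(_graph_log_mean(d_real), _graph_log_mean_inv(d_fake)))
            _check_finite(loss_d.item(), "discriminator loss")
            loss_d.backward()
            _clip_grad_norm(opt_d.params, config.clip_grad_norm)
            opt_d.step()

            # generator step: non-saturating adversarial term + lambda * L1
            opt_g.zero_grad()
            disc.zero_grad()
            d_fake_for_g = disc.forward(xt, fake, training=True)
            adv = ag.neg(_graph_log_mean(d_fake_for_g))
            l1 = ag.mean(ag.absolute(ag.sub(fake, yt)))
            loss_g = ag.add(adv, ag.mul(l1, spec.lambda_l1))
            _check_finite(loss_g.item(), "generator loss")
            loss_g.backward()
            _clip_grad_norm(opt_g.params, config.clip_grad_norm)
            opt_g.step()

            d_losses.append(loss_d.item())
            g_adv.append(adv.item())
            g_l1.append(l1.item())
        rows.append({
            "epoch": epoch,
            "loss_d": float(np.mean(d_losses)),
            "loss_g_adv": float(np.mean(g_adv)),
            "loss_g_l1": float(np.mean(g_l1)),
            "loss_g": float(np.mean(g_adv) + spec.lambda_l1 * np.mean(g_l1)),
        })
        if log_fn:
            r = rows[-1]
            log_fn(f"[cgan] epoch {epoch}: d={r['loss_d']:.4f} "
                   f"adv={r['loss_g_adv']:.4f} l1={r['loss_g_l1']:.6f}")
    return TrainedModel(kind="cgan", model=gen, config=config, spec=spec,
                        history=pd.DataFrame(rows), discriminator=disc)


def correct_image(trained: TrainedModel, corrupted: ImageGrid) -> ImageGrid:
    """Restore one [0, 1]-normalized corrupted image; output on [0, 255].

    Runs the network in eval mode (dropout off, batch-norm running stats)
    with no gradient bookkeeping.
    """
    px = corrupted.pixels
    if px.min() < -1e-6 or px.max() > 1 + 1e-6:
        raise ValueError("correct_image expects an input normalized to [0, 1]")
    if px.shape[0] != trained.config.image_size or px.shape[1] != trained.config.image_size:
        raise ShapeError(
            f"model expects {trained.config.image_size}^2 images, got {px.shape}"
        )
    with nn.no_grad():
        out = trained.model.forward(Tensor(px[None, None].astype(np.float32)),
                                    training=False)
    restored = ImageGrid(out.data[0, 0].astype(np.float64), pe_axis=corrupted.pe_axis)
    return denormalize_output(restored)
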