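"""Conditional-GAN training.

The discriminator minimizes the binary cross-entropy of the conditional GAN
objective

    L_cGAN(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x)))]

while the generator uses the non-saturating form -E[log D(x, G(x))] plus an
L1 reconstruction term, both weighted 1 by default.  Optimization is Adam at
learning rate 1e-4 with betas (0.5, 0.999) for both networks, batch size 4,
one discriminator update per generator update.  Dropout defaults to 0, so
the implicit noise input is disabled and a trained generator in eval mode is
a deterministic function.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import InvalidParameterError, ShapeError
from .io import substream, substream_seed
from .models import GanModel, build_gan, load_checkpoint, save_checkpoint
from .preprocess import PerfusionDataset, SliceSample

PROB_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 100          # 50 when fine-tuning on a second domain
    batch_size: int = 4
    l1_weight: float = 1.0
    adv_weight: float = 1.0
    seed: int = 0
    map_type: str = "tmax"
    variant: str = "pix2pix"
    base_channels: int = 64
    n_levels: int = 6
    temporal_channels: tuple[int, ...] | None = None
    dropout_rate: float = 0.0
    checkpoint_every: int = 0  # epochs; 0 = only final

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.l1_weight + 1, self.adv_weight + 1) <= 0 or self.epochs < 0:
            raise InvalidParameterError("training hyperparameters must be positive")


@dataclass
class TrainState:
    epoch: int = 0
    history: list[dict] = field(default_factory=list)  # per-epoch loss means
    val_l1: list[float] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)
    seed: int = 0


def adversarial_objective(d_real: nn.Tensor, d_fake: nn.Tensor, eps: float = PROB_EPS):
    """Binary cross-entropy losses of the conditional GAN.

    Returns ``(d_loss, g_adv_loss)``: the discriminator term
    -mean log D(x,y) - mean log(1 - D(x,G(x))) and the non-saturating
    generator term -mean log D(x,G(x)).  Probabilities are clamped away from
    {0, 1} for finiteness.
    """
    for t in (d_real, d_fake):
        if np.any(t.data < 0) or np.any(t.data > 1):
            raise InvalidParameterError("discriminator outputs must be probabilities in [0, 1]")
    dr = d_real.clamp(eps, 1.0 - eps)
    df = d_fake.clamp(eps, 1.0 - eps)
    one = nn.Tensor(np.ones_like(df.data))
    d_loss = -(dr.log().mean()) + (-((one - df).log().mean()))
    g_loss = -(df.log().mean())
    return d_loss, g_loss


def reconstruction_loss(generated: nn.Tensor, target: nn.Tensor) -> nn.Tensor:
    """Mean absolute (L1) deviation from the target slice."""
    if generated.data.shape != target.data.shape:
        raise ShapeError("generated and target slices must have equal shape")
    return (generated - target).abs().mean()


def _as_batch(samples: list[SliceSample], variant: str):
    """Stack samples: generator input (variant layout), discriminator source
    channels (frames as channels for both variants), and target maps."""
    src = np.stack([s.source for s in samples]).astype(np.float32)      # (N, 80, h, w)
    tgt = np.stack([s.target for s in samples]).astype(np.float32)[:, None]  # (N, 1, h, w)
    if variant == "temp_pix2pix":
        gen_in = np.moveaxis(src, 1, -1)[:, None]                       # (N, 1, h, w, 80)
    else:
        gen_in = src
    return nn.Tensor(gen_in), nn.Tensor(src), nn.Tensor(tgt)


def generate(model: GanModel, samples: list[SliceSample], batch_size: int = 1) -> np.ndarray:
    """Run the generator in eval mode over samples; returns (N, h, w).

    Batch size 1 keeps inference strictly per-sample: batch normalization in
    eval mode uses the statistics of the slice being generated (pix2pix
    convention), so each output depends only on its own input.
    """
    model.eval()
    outs = []
    for lo in range(0, len(samples), batch_size):
        gen_in, _, _ = _as_batch(samples[lo : lo + batch_size], model.variant)
        outs.append(model.generator(gen_in).data[:, 0])
    model.train()
    return np.concatenate(outs, axis=0)


def train_step(
    batch: list[SliceSample],
    model: GanModel,
    opt_g: nn.Adam,
    opt_d: nn.Adam,
    cfg: TrainConfig,
) -> dict[str, float]:
    """One discriminator update on (real, fake) pairs, then one generator
    update on the adversarial + L1 objective."""
    gen_in, src_channels, target = _as_batch(batch, model.variant)

    # one generator forward; its graph is reused for the generator update
    fake = model.generator(gen_in)

    # -- discriminator ------------------------------------------------------
    d_real = model.discriminator(src_channels, target)
    d_fake = model.discriminator(src_channels, fake.detach())
    d_loss, _ = adversarial_objective(d_real, d_fake)
    opt_d.zero_grad()
    model.discriminator.zero_grad()
    d_loss.backward()
    opt_d.step()

    # -- generator ----------------------------------------------------------
    d_fake2 = model.discriminator(src_channels, fake)
    _, g_adv = adversarial_objective(d_real.detach(), d_fake2)
    l1 = reconstruction_loss(fake, target)
    g_loss = cfg.adv_weight * g_adv + cfg.l1_weight * l1
    opt_g.zero_grad()
    model.generator.zero_grad()
    model.discriminator.zero_grad()  # conditioning path gradients are discarded
    g_loss.backward()
    opt_g.step()

    losses = {
        "d": float(d_loss.data), "g_adv": float(g_adv.data),
        "g_l1": float(l1.data), "g": float(g_loss.data),
    }
    if not all(math.isfinite(v) for v in losses.values()):
        raise FloatingPointError(f"non-finite loss encountered: {losses}")
    return losses


def validation_l1(model: GanModel, samples: list[SliceSample]) -> float:
    if not samples:
        return float("nan")
    preds = generate(model, samples)
    targets = np.stack([s.target for s in samples])
    return float(np.mean(np.abs(preds - targets)))


def _make_optimizers(model: GanModel, cfg: TrainConfig) -> tuple[nn.Adam, nn.Adam]:
    betas = (cfg.adam_beta1, cfg.adam_beta2)
    return (
        nn.Adam(model.generator.parameters(), lr=cfg.lr, betas=betas),
        nn.Adam(model.discriminator.parameters(), lr=cfg.lr, betas=betas),
    )


def train(
    dataset: PerfusionDataset,
    cfg: TrainConfig,
    model: GanModel | None = None,
    log_path: str | Path | None = None,
    checkpoint_dir: str | Path | None = None,
) -> tuple[GanModel, TrainState]:
    """Full training loop: seeded shuffling, per-epoch validation L1,
    optional line-delimited log records and periodic checkpoints."""
    if not dataset.train:
        raise InvalidParameterError("training split is empty")
    h, w = dataset.train[0].target.shape
    if model is None:
        model = build_gan(
            variant=cfg.variant, image_size=(h, w), n_levels=cfg.n_levels,
            base_channels=cfg.base_channels, in_frames=dataset.train[0].source.shape[0],
            dropout_rate=cfg.dropout_rate, temporal_channels=cfg.temporal_channels,
            seed=substream_seed(cfg.seed, "init"),
        )
    opt_g, opt_d = _make_optimizers(model, cfg)
    shuffle_rng = substream(cfg.seed, "shuffle")
    state = TrainState(seed=cfg.seed)
    state.val_l1.append(validation_l1(model, dataset.val))
    log_f = open(log_path, "a") if log_path else None
    model.train()
    try:
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(len(dataset.train))
            sums: dict[str, float] = {}
            n_batches = 0
            for lo in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
                batch = [dataset.train[i] for i in order[lo : lo + cfg.batch_size]]
                losses = train_step(batch, model, opt_g, opt_d, cfg)
                for k, v in losses.items():
                    sums[k] = sums.get(k, 0.0) + v
                n_batches += 1
            record = {k: v / max(n_batches, 1) for k, v in sums.items()}
            record["epoch"] = epoch
            record["val_l1"] = validation_l1(model, dataset.val)
            state.history.append(record)
            state.val_l1.append(record["val_l1"])
            state.epoch = epoch + 1
            if log_f:
                log_f.write(json.dumps(record) + "\n")
                log_f.flush()
            if checkpoint_dir and cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
                p = save_checkpoint(model, Path(checkpoint_dir) / f"epoch{epoch + 1:03d}.npz")
                state.checkpoints.append(str(p))
    finally:
        if log_f:
            log_f.close()
    if checkpoint_dir:
        p = save_checkpoint(model, Path(checkpoint_dir) / "final.npz")
        state.checkpoints.append(str(p))
    return model, state


def fine_tune(
    pretrained: GanModel | str | Path,
    dataset: PerfusionDataset,
    cfg: TrainConfig,
    **kwargs,
) -> tuple[GanModel, TrainState]:
    """Transfer protocol: load all pretrained weights, reset the optimizer
    state, and continue training on the new domain (default budget 50 epochs
    set by the caller's config)."""
    if isinstance(pretrained, (str, Path)):
        model = load_checkpoint(pretrained)
    else:
        # round-trip through a state dict so the caller's model is untouched
        model = build_gan(
            variant=pretrained.gen_cfg.variant, image_size=pretrained.gen_cfg.image_size,
            n_levels=pretrained.gen_cfg.n_levels, base_channels=pretrained.gen_cfg.base_channels,
            in_frames=pretrained.gen_cfg.in_frames, dropout_rate=pretrained.gen_cfg.dropout_rate,
            temporal_channels=pretrained.gen_cfg.temporal.channels if pretrained.gen_cfg.temporal else None,
        )
        model.generator.load_state_dict(pretrained.generator.state_dict())
        model.discriminator.load_state_dict(pretrained.discriminator.state_dict())
    if model.variant != cfg.variant:
        raise InvalidParameterError("fine-tune variant must match the pretrained model")
    return train(dataset, cfg, model=model, **kwargs)
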