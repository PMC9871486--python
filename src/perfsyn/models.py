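"""Generator and discriminator architectures.

Two generator variants translate one DSC slice sequence into one perfusion
map slice:

* ``pix2pix`` — the 80 time points enter a 2D U-Net as input channels, so
  the network sees time only as an unordered channel stack.
* ``temp_pix2pix`` — the sequence keeps an explicit time axis and is first
  collapsed by six strided 3D convolutions (kernel 4, stride 2, padding 1 on
  the time axis: 80 -> 40 -> 20 -> 10 -> 5 -> 2 -> 1) before the resulting
  feature image enters the same U-Net (early fusion).

The discriminator is a PatchGAN: strided conv blocks ending in a sigmoid
patch-probability grid, conditioned on the source frames stacked as
channels next to the (real or generated) map slice.

All convolutions use kernel 4 / stride 2; weights are initialized
normal(0, 0.02).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import IncompatibleCheckpointError, ShapeError

VARIANTS = ("pix2pix", "temp_pix2pix")


@dataclass(frozen=True)
class TemporalEncoderConfig:
    n_stages: int = 6
    time_kernel: int = 4
    time_stride: int = 2
    spatial_kernel: int = 3          # stride 1, padding preserves spatial dims
    channels: tuple[int, ...] = (8, 16, 32, 64, 64, 64)
    in_frames: int = 80
    leaky_slope: float = 0.2

    def time_schedule(self) -> list[int]:
        t = self.in_frames
        sched = []
        for _ in range(self.n_stages):
            t = (t + 2 * 1 - self.time_kernel) // self.time_stride + 1
            sched.append(t)
        return sched

    def __post_init__(self):
        if len(self.channels) != self.n_stages:
            raise ShapeError("temporal channel plan length must equal n_stages")
        if self.time_schedule()[-1] != 1:
            raise ShapeError(
                f"time schedule {self.time_schedule()} does not reach 1 from {self.in_frames} frames"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    variant: str = "pix2pix"
    n_levels: int = 6
    base_channels: int = 64
    in_frames: int = 80
    image_size: tuple[int, int] = (128, 128)
    dropout_rate: float = 0.0
    leaky_slope: float = 0.2
    temporal: TemporalEncoderConfig | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ShapeError(f"unknown variant {self.variant!r}")
        div = 2 ** self.n_levels
        h, w = self.image_size
        if h % div or w % div:
            raise ShapeError(
                f"image size {self.image_size} must be divisible by 2^{self.n_levels} = {div}"
            )
        if self.variant == "temp_pix2pix" and self.temporal is None:
            object.__setattr__(self, "temporal", TemporalEncoderConfig(in_frames=self.in_frames))


@dataclass(frozen=True)
class DiscriminatorConfig:
    n_conv_blocks: int = 3
    base_channels: int = 64
    in_channels: int = 81  # source frames + one map channel
    leaky_slope: float = 0.2


def _ladder(base: int, n: int) -> list[int]:
    # canonical pix2pix width ladder 64,128,256,512,512,512 scaled by base/64
    return [base * min(2 ** i, 8) for i in range(n)]


class UNetGenerator(nn.Module):
    """2D encoder-decoder with skip connections and a tanh output."""

    def __init__(self, in_channels: int, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = _ladder(cfg.base_channels, cfg.n_levels)
        self.downs: list[nn.Module] = []
        self.down_norms: list[nn.Module | None] = []
        c_prev = in_channels
        for i, c in enumerate(chans):
            self.downs.append(nn.Conv2d(c_prev, c, rng=rng))
            # no batch-norm on the outermost layer or the bottleneck
            use_bn = 0 < i < cfg.n_levels - 1
            self.down_norms.append(nn.BatchNorm(c, rng=rng) if use_bn else None)
            c_prev = c
        self.ups: list[nn.Module] = []
        self.up_norms: list[nn.Module | None] = []
        for i in reversed(range(1, cfg.n_levels)):
            c_in = chans[i] if i == cfg.n_levels - 1 else chans[i] * 2
            self.ups.append(nn.ConvTranspose2d(c_in, chans[i - 1], rng=rng))
            self.up_norms.append(nn.BatchNorm(chans[i - 1], rng=rng))
        self.final = nn.ConvTranspose2d(chans[0] * 2, 1, rng=rng)
        self.dropout = nn.Dropout(cfg.dropout_rate, rng=rng) if cfg.dropout_rate > 0 else None
        self.lrelu = nn.LeakyReLU(cfg.leaky_slope)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        for conv, norm in zip(self.downs, self.down_norms):
            x = conv(x)
            if norm is not None:
                x = norm(x)
            x = self.lrelu(x)
            skips.append(x)
        for idx, (up, norm) in enumerate(zip(self.ups, self.up_norms)):
            x = up(x if idx == 0 else nn.concat([x, skips[-1 - idx]], axis=1))
            x = norm(x)
            if self.dropout is not None:
                x = self.dropout(x)
            x = x.relu()
        return self.final(nn.concat([x, skips[0]], axis=1)).tanh()


class TemporalEncoder(nn.Module):
    """Six strided 3D convolutions collapsing the time axis of
    (N, 1, H, W, T) input to length 1; spatial extent untouched."""

    def __init__(self, cfg: TemporalEncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        k, p = cfg.spatial_kernel, cfg.spatial_kernel // 2
        self.convs: list[nn.Module] = []
        self.norms: list[nn.Module] = []
        c_prev = 1
        for c in cfg.channels:
            self.convs.append(
                nn.Conv3d(
                    c_prev, c,
                    kernel=(cfg.time_kernel, k, k),
                    stride=(cfg.time_stride, 1, 1),
                    padding=(1, p, p),
                    rng=rng,
                )
            )
            self.norms.append(nn.BatchNorm(c, rng=rng))
            c_prev = c
        self.lrelu = nn.LeakyReLU(cfg.leaky_slope)

    @property
    def out_channels(self) -> int:
        return self.cfg.channels[-1]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.data.ndim != 5 or x.data.shape[-1] != self.cfg.in_frames:
            raise ShapeError(
                f"temporal encoder expects (N, 1, H, W, {self.cfg.in_frames}), got {x.data.shape}"
            )
        # time-leading layout internally; restore (..., T) at the exit
        x = x.moveaxis(-1, 2)
        for conv, norm in zip(self.convs, self.norms):
            x = self.lrelu(norm(conv(x)))
        return x.moveaxis(2, -1)


class TempPix2PixGenerator(nn.Module):
    """Early fusion: temporal encoder, squeeze the collapsed time axis,
    then the 2D U-Net."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = TemporalEncoder(cfg.temporal, rng)
        self.unet = UNetGenerator(self.encoder.out_channels, cfg, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        z = self.encoder(x)
        n, c, h, w, t = z.data.shape
        if t != 1:
            raise ShapeError(f"temporal path left {t} frames, expected 1")
        return self.unet(z.reshape(n, c, h, w))


class PatchDiscriminator(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        mods: list[nn.Module] = []
        c_prev = cfg.in_channels
        c = cfg.base_channels
        for _ in range(cfg.n_conv_blocks):
            mods += [nn.Conv2d(c_prev, c, rng=rng), nn.BatchNorm(c, rng=rng), nn.LeakyReLU(cfg.leaky_slope)]
            c_prev, c = c, min(c * 2, cfg.base_channels * 8)
        mods += [nn.Conv2d(c_prev, 1, rng=rng), nn.Sigmoid()]
        self.net = nn.Sequential(*mods)

    def forward(self, source_channels: nn.Tensor, map_slice: nn.Tensor) -> nn.Tensor:
        return self.net(nn.concat([source_channels, map_slice], axis=1))


def build_pix2pix_generator(cfg: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    if cfg.variant != "pix2pix":
        raise ShapeError("config variant must be 'pix2pix'")
    return UNetGenerator(cfg.in_frames, cfg, np.random.default_rng(seed))


def build_temporal_encoder(cfg: TemporalEncoderConfig, seed: int = 0) -> TemporalEncoder:
    return TemporalEncoder(cfg, np.random.default_rng(seed))


def build_temp_pix2pix_generator(cfg: GeneratorConfig, seed: int = 0) -> TempPix2PixGenerator:
    if cfg.variant != "temp_pix2pix":
        raise ShapeError("config variant must be 'temp_pix2pix'")
    return TempPix2PixGenerator(cfg, np.random.default_rng(seed))


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(cfg, np.random.default_rng(seed))


@dataclass
class GanModel:
    generator: nn.Module
    discriminator: PatchDiscriminator
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig

    @property
    def variant(self) -> str:
        return self.gen_cfg.variant

    def train(self, mode: bool = True):
        self.generator.train(mode)
        self.discriminator.train(mode)
        return self

    def eval(self):
        return self.train(False)


def build_gan(
    variant: str = "pix2pix",
    image_size: tuple[int, int] = (128, 128),
    n_levels: int = 6,
    base_channels: int = 64,
    in_frames: int = 80,
    dropout_rate: float = 0.0,
    temporal_channels: tuple[int, ...] | None = None,
    seed: int = 0,
) -> GanModel:
    temporal = None
    if variant == "temp_pix2pix":
        temporal = TemporalEncoderConfig(
            in_frames=in_frames,
            channels=temporal_channels or TemporalEncoderConfig.__dataclass_fields__["channels"].default,
        )
    gen_cfg = GeneratorConfig(
        variant=variant, n_levels=n_levels, base_channels=base_channels,
        in_frames=in_frames, image_size=image_size, dropout_rate=dropout_rate,
        temporal=temporal,
    )
    disc_cfg = DiscriminatorConfig(in_channels=in_frames + 1, base_channels=base_channels)
    builder = build_pix2pix_generator if variant == "pix2pix" else build_temp_pix2pix_generator
    gen = builder(gen_cfg, seed=seed)
    disc = build_discriminator(disc_cfg, seed=seed + 1)
    return GanModel(generator=gen, discriminator=disc, gen_cfg=gen_cfg, disc_cfg=disc_cfg)


def _cfg_to_json(model: GanModel) -> str:
    g = asdict(model.gen_cfg)
    if g["temporal"] is not None:
        g["temporal"]["channels"] = list(g["temporal"]["channels"])
    g["image_size"] = list(g["image_size"])
    return json.dumps({"generator": g, "discriminator": asdict(model.disc_cfg)})


def _cfg_from_json(text: str) -> tuple[GeneratorConfig, DiscriminatorConfig]:
    d = json.loads(text)
    g = d["generator"]
    if g["temporal"] is not None:
        g["temporal"]["channels"] = tuple(g["temporal"]["channels"])
        g["temporal"] = TemporalEncoderConfig(**g["temporal"])
    g["image_size"] = tuple(g["image_size"])
    return GeneratorConfig(**g), DiscriminatorConfig(**d["discriminator"])


def save_checkpoint(model: GanModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"g/{k}": v for k, v in model.generator.state_dict().items()}
    arrays.update({f"d/{k}": v for k, v in model.discriminator.state_dict().items()})
    np.savez_compressed(path, __config__=np.frombuffer(_cfg_to_json(model).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path, expect: GanModel | None = None) -> GanModel:
    """Rebuild a model from a checkpoint; if ``expect`` is given its
    architecture must match, otherwise an incompatible-checkpoint error."""
    with np.load(Path(path)) as data:
        cfg_text = bytes(data["__config__"]).decode()
        gen_cfg, disc_cfg = _cfg_from_json(cfg_text)
        if expect is not None and (gen_cfg != expect.gen_cfg or disc_cfg != expect.disc_cfg):
            raise IncompatibleCheckpointError(
                "checkpoint architecture does not match the model configuration"
            )
        model = expect or build_gan(
            variant=gen_cfg.variant, image_size=gen_cfg.image_size, n_levels=gen_cfg.n_levels,
            base_channels=gen_cfg.base_channels, in_frames=gen_cfg.in_frames,
            dropout_rate=gen_cfg.dropout_rate,
            temporal_channels=gen_cfg.temporal.channels if gen_cfg.temporal else None,
        )
        g_state = {k[2:]: data[k] for k in data.files if k.startswith("g/")}
        d_state = {k[2:]: data[k] for k in data.files if k.startswith("d/")}
    model.generator.load_state_dict(g_state)
    model.discriminator.load_state_dict(d_state)
    return model
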