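"""The four inpainting network architectures and their configurations.

All four are shape-preserving maps from a single-channel strip to a
single-channel strip, trained to replace detector-gap pixels with plausible
scattering signal:

* :class:`Autoencoder` -- a symmetric convolutional encoder-decoder without
  skip connections; the encoder halves the spatial dimensions per stage via
  max-pooling, the decoder doubles them with transposed convolutions.
* :class:`TUNet` -- a tunable U-Net parameterized by depth, initial channel
  count and channel growth rate, with two 3x3 conv + ReLU per block and
  channel-wise concatenation skip connections.
* :class:`PartialConvUNet` -- the same U topology with every convolution
  replaced by a mask-renormalized partial convolution; the valid-pixel mask
  travels alongside the features and its holes shrink layer by layer, so
  this model is not a blind inpainter.
* :class:`MSDNet` -- a mixed-scale dense network: every layer sees the
  input and all previous layer outputs, scale diversity comes from cycling
  integer dilations instead of pooling, and the parameter count stays two
  to three orders of magnitude below a U-Net's.

No normalization layers and no output activation anywhere: targets live in
[0, 1] but outputs are linear and only clamped at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam  # noqa: F401  (re-export convenience)
from .nn import Conv2d, ConvTranspose2x2, Module, PartialConv2d, Tensor
from .nn import functional as F

__all__ = [
    "AutoencoderConfig",
    "TUNetConfig",
    "PartialConvConfig",
    "MSDNetConfig",
    "Autoencoder",
    "TUNet",
    "PartialConvUNet",
    "MSDNet",
    "build_autoencoder",
    "build_tunet",
    "build_partialconv_unet",
    "build_msdnet",
    "build_model",
    "count_parameters",
    "channel_schedule",
]


# ---------------------------------------------------------------------------
# configurations

@dataclass(frozen=True)
class AutoencoderConfig:
    depth: int = 2
    base_channels: int = 32

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


@dataclass(frozen=True)
class TUNetConfig:
    depth: int = 4
    base_channels: int = 64
    growth_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1 or self.growth_rate < 1.0:
            raise ValueError("base_channels must be >= 1 and growth_rate >= 1")


@dataclass(frozen=True)
class PartialConvConfig:
    depth: int = 5
    base_channels: int = 32
    growth_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1 or self.growth_rate < 1.0:
            raise ValueError("base_channels must be >= 1 and growth_rate >= 1")


@dataclass(frozen=True)
class MSDNetConfig:
    num_layers: int = 200
    max_dilation: int = 15
    width: int = 1

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.max_dilation < 1 or self.width < 1:
            raise ValueError("num_layers, max_dilation and width must be >= 1")


def channel_schedule(base: int, growth: float, depth: int) -> tuple[int, ...]:
    """Per-level channel counts ``round(base * growth^level)``.

    Rounding is half away from zero so fractional growth rates (1.5, 2.5)
    give stable, reproducible schedules.
    """
    return tuple(int(np.floor(base * growth**d + 0.5)) for d in range(depth))


# ---------------------------------------------------------------------------
# architectures

class Autoencoder(Module):
    """Symmetric conv/max-pool encoder and transposed-conv decoder.

    The latent representation is a spatial feature map (no dense
    bottleneck); encoder and decoder share no skip connections, so the two
    halves can operate independently.
    """

    def __init__(self, config: AutoencoderConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        ch = [config.base_channels * 2**d for d in range(config.depth)]
        self.enc = []
        c_in = 1
        for c in ch:
            self.enc.append(Conv2d(c_in, c, 3, rng))
            c_in = c
        self.dec_up = []
        self.dec_conv = []
        for d in range(config.depth - 1, -1, -1):
            c_out = ch[d - 1] if d > 0 else config.base_channels
            self.dec_up.append(ConvTranspose2x2(c_in, c_out, rng))
            self.dec_conv.append(Conv2d(c_out, c_out, 3, rng))
            c_in = c_out
        self.head = Conv2d(c_in, 1, 1, rng)

    def _check(self, x: Tensor) -> None:
        H, W = x.data.shape[2:]
        f = 2**self.config.depth
        if H % f or W % f:
            raise ValueError(f"input dims {H}x{W} must be divisible by {f}")

    def encode(self, x: Tensor) -> Tensor:
        self._check(x)
        h = x
        for conv in self.enc:
            h = F.maxpool2x2(F.relu(conv(h)))
        return h

    def __call__(self, x: Tensor) -> Tensor:
        h = self.encode(x)
        for up, conv in zip(self.dec_up, self.dec_conv):
            h = F.relu(conv(up(h)))
        return self.head(h)


class TUNet(Module):
    """Tunable U-Net: depth resolution levels, two 3x3 conv + ReLU per
    block, channel growth per level, concatenation skips, 1x1 output head."""

    def __init__(self, config: TUNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        ch = channel_schedule(config.base_channels, config.growth_rate, config.depth)
        self.channels = ch
        self.enc_blocks = []
        c_in = 1
        for c in ch:
            self.enc_blocks.append([Conv2d(c_in, c, 3, rng), Conv2d(c, c, 3, rng)])
            c_in = c
        self.ups = []
        self.dec_blocks = []
        for d in range(config.depth - 2, -1, -1):
            self.ups.append(ConvTranspose2x2(ch[d + 1], ch[d], rng))
            self.dec_blocks.append(
                [Conv2d(2 * ch[d], ch[d], 3, rng), Conv2d(ch[d], ch[d], 3, rng)]
            )
        self.head = Conv2d(ch[0], 1, 1, rng)

    def _check(self, x: Tensor) -> None:
        H, W = x.data.shape[2:]
        f = 2 ** (self.config.depth - 1)
        if H % f or W % f:
            raise ValueError(f"input dims {H}x{W} must be divisible by {f}")

    def __call__(self, x: Tensor) -> Tensor:
        self._check(x)
        skips = []
        h = x
        for d, block in enumerate(self.enc_blocks):
            for conv in block:
                h = F.relu(conv(h))
            if d < self.config.depth - 1:
                skips.append(h)
                h = F.maxpool2x2(h)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = F.concat([skip, up(h)])
            for conv in block:
                h = F.relu(conv(h))
        return self.head(h)


class PartialConvUNet(Module):
    """U-Net whose convolutions are partial convolutions with a mask stream.

    Forward takes the strip and its valid-pixel mask (1 = known data); the
    mask is max-pooled down the encoder, nearest-upsampled in the decoder,
    merged with the skip mask at each concatenation, and its valid region
    grows monotonically through the layers.
    """

    def __init__(self, config: PartialConvConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        ch = channel_schedule(config.base_channels, config.growth_rate, config.depth)
        self.channels = ch
        self.enc_blocks = []
        c_in = 1
        for c in ch:
            self.enc_blocks.append(
                [PartialConv2d(c_in, c, 3, rng), PartialConv2d(c, c, 3, rng)]
            )
            c_in = c
        self.ups = []
        self.dec_blocks = []
        for d in range(config.depth - 2, -1, -1):
            self.ups.append(ConvTranspose2x2(ch[d + 1], ch[d], rng))
            self.dec_blocks.append(
                [PartialConv2d(2 * ch[d], ch[d], 3, rng), PartialConv2d(ch[d], ch[d], 3, rng)]
            )
        self.head = Conv2d(ch[0], 1, 1, rng)

    def _check(self, x: Tensor) -> None:
        H, W = x.data.shape[2:]
        f = 2 ** (self.config.depth - 1)
        if H % f or W % f:
            raise ValueError(f"input dims {H}x{W} must be divisible by {f}")

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        if mask is None:
            raise ValueError(
                "PartialConvUNet is not a blind inpainter: forward requires the "
                "valid-pixel mask"
            )
        self._check(x)
        m = np.asarray(mask, dtype=x.data.dtype)
        if m.ndim == 2:
            m = np.broadcast_to(m, x.data.shape[:1] + (1,) + m.shape).copy()
        skips = []
        h = x
        for d, block in enumerate(self.enc_blocks):
            for conv in block:
                h, m = conv(h, m)
                h = F.relu(h)
            if d < self.config.depth - 1:
                skips.append((h, m))
                h = F.maxpool2x2(h)
                m = F.maxpool2x2_array(m)
        for up, block, (skip_h, skip_m) in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = F.concat([skip_h, up(h)])
            m = np.maximum(F.upsample2x_array(m), skip_m)
            for conv in block:
                h, m = conv(h, m)
                h = F.relu(h)
        return self.head(h)


class MSDNet(Module):
    """Mixed-scale dense network with cycled dilations.

    Layer ``i`` (1-based) convolves the concatenation of the input and all
    previous layer outputs with a 3x3 kernel of dilation
    ``((i - 1) mod max_dilation) + 1``, followed by ReLU.  The output is a
    1x1 convolution (with bias) over the input plus every layer's channels.
    With width 1 and a single input/output channel the trainable-parameter
    count is exactly ``4.5 d^2 + 6.5 d + 2`` for ``d`` layers.

    The head is initialized as a near-pass-through of the input channel
    (weight one on the input, small random weights on the layer channels),
    so the untrained network is essentially the identity map and
    optimization starts from reproducing the known pixels, learning only
    the gap corrections, while gradient still reaches every layer from the
    first backward pass.
    """

    def __init__(self, config: MSDNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        w = config.width
        self.layers = []
        self.dilations = []
        for i in range(1, config.num_layers + 1):
            dil = (i - 1) % config.max_dilation + 1
            self.dilations.append(dil)
            self.layers.append(Conv2d(1 + (i - 1) * w, w, 3, rng, dilation=dil))
        self.head = Conv2d(1 + config.num_layers * w, 1, 1, rng)
        self.head.weight.data[:] = rng.normal(
            0.0, 0.01, size=self.head.weight.data.shape
        ).astype(np.float32)
        self.head.weight.data[0, 0, 0, 0] = 1.0

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        cat = x
        for layer in self.layers:
            h = F.relu(layer(cat))
            feats.append(h)
            cat = F.concat(feats)
        return self.head(cat)


# ---------------------------------------------------------------------------
# builders

def build_autoencoder(config: AutoencoderConfig | None = None, seed: int = 0) -> Autoencoder:
    return Autoencoder(config or AutoencoderConfig(), seed)


def build_tunet(config: TUNetConfig | None = None, seed: int = 0) -> TUNet:
    return TUNet(config or TUNetConfig(), seed)


def build_partialconv_unet(
    config: PartialConvConfig | None = None, seed: int = 0
) -> PartialConvUNet:
    return PartialConvUNet(config or PartialConvConfig(), seed)


def build_msdnet(config: MSDNetConfig | None = None, seed: int = 0) -> MSDNet:
    return MSDNet(config or MSDNetConfig(), seed)


_BUILDERS = {
    "autoencoder": (build_autoencoder, AutoencoderConfig),
    "tunet": (build_tunet, TUNetConfig),
    "pconv": (build_partialconv_unet, PartialConvConfig),
    "msdnet": (build_msdnet, MSDNetConfig),
}


def build_model(name: str, seed: int = 0, **config_kwargs) -> Module:
    """Build a network by name ('autoencoder', 'tunet', 'pconv', 'msdnet')."""
    try:
        builder, cfg_cls = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose one of {sorted(_BUILDERS)}"
        ) from None
    return builder(cfg_cls(**config_kwargs), seed)


def count_parameters(net: Module) -> int:
    """Total number of trainable scalars in a network."""
    return net.num_parameters()


def model_name(net: Module) -> str:
    for name, (_, cfg_cls) in _BUILDERS.items():
        if isinstance(getattr(net, "config", None), cfg_cls):
            return name
    raise ValueError(f"not a registered inpainting model: {type(net).__name__}")


def save_checkpoint(path, net: Module) -> None:
    """Serialize weights with the architecture config embedded for reload."""
    import json

    from dataclasses import asdict

    arrays = {f"param_{i}": p.data for i, p in enumerate(net.parameters())}
    meta = json.dumps({"model": model_name(net), "config": asdict(net.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Module:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = build_model(meta["model"], **meta["config"])
        state = [data[f"param_{i}"] for i in range(len(net.parameters()))]
    net.load_state_dict(state)
    return net
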