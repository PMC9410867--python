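"""Attention-augmented residual 3D U-Net for voxel-level lesion segmentation.

The architecture is an encoder--decoder with residual convolution blocks.
Two attention mechanisms refine the decoder:

* **Channel fusion attention** acts on each skip connection. The encoder
  feature map F_e and the upsampled decoder feature map F_d (same C x L x W x H
  shape) are each reduced to a per-channel statistic by global average
  pooling; the two length-C statistics are concatenated into one length-2C
  sequence, a 1D convolution with odd kernel n slides across it (capturing
  local cross-channel interaction between the two feature hierarchies without
  dimensionality reduction), and a sigmoid turns the result into 2C gates in
  (0,1). The first C gates rescale F_e channel-wise, the last C rescale F_d.
  By default one shared 1D convolution produces both gate sets; an unshared
  two-convolution variant is available via ``shared_channel_conv=False``.

* **Grouped spatial attention** acts after the skip fusion. The C channels
  are split into G contiguous groups of C/G; each group is projected to a
  single channel by its own 1x1x1 convolution, passed through its own 7x7x7
  convolution (padding 3) and a sigmoid to give a per-voxel gate map in (0,1)
  of shape 1 x L x W x H, which rescales every channel of that group. Groups
  have independent weights so each gate map can attend to a different
  semantic sub-feature; G=1 recovers plain ungrouped spatial attention.

Both mechanisms are purely multiplicative with gates strictly inside (0,1),
so they preserve shapes and signs and strictly shrink magnitudes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm3d,
    Conv1d,
    Conv3d,
    ConvTranspose3d,
    Layer,
    MaxPool3d,
    Param,
    ReLU,
    Sigmoid,
    global_average_pool,
)

__all__ = [
    "ModelConfig",
    "ChannelFusionAttention",
    "SpatialGroupAttention",
    "ResidualConvBlock",
    "DecoderBlock",
    "AttentionResUNet3D",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    base_channels : channel width of the first encoder stage; stage k has
        ``base_channels * 2**k`` channels.
    n_encoders / n_decoders : stage counts (defaults 4 and 3, i.e. three
        2x downsamplings, so cubic inputs must be divisible by 8).
    channel_kernel : odd kernel size n of the skip-connection channel
        attention's 1D convolution.
    spatial_groups : group count G of the grouped spatial attention; must
        divide every decoder-stage channel count.
    use_channel_attention / use_spatial_attention : ablation toggles that
        replace the respective module by the identity.
    shared_channel_conv : one shared 1D convolution for both channel gate
        sets (default) versus two separate convolutions.
    seed : weight-initialisation seed.
    """

    base_channels: int = 32
    n_encoders: int = 4
    n_decoders: int = 3
    channel_kernel: int = 5
    spatial_groups: int = 4
    use_channel_attention: bool = True
    use_spatial_attention: bool = True
    shared_channel_conv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_kernel % 2 == 0:
            raise ValueError(f"channel_kernel must be odd, got {self.channel_kernel}")
        if self.spatial_groups < 1:
            raise ValueError("spatial_groups must be >= 1")
        if self.n_decoders != self.n_encoders - 1:
            raise ValueError("n_decoders must equal n_encoders - 1")
        if self.use_spatial_attention:
            for k in range(self.n_decoders):
                c = self.base_channels * 2**k
                if c % self.spatial_groups:
                    raise ValueError(
                        f"spatial_groups={self.spatial_groups} does not divide the "
                        f"decoder-stage channel count {c}"
                    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class ChannelFusionAttention(Layer):
    """Channel-wise gating of a skip-connection feature pair."""

    def __init__(self, channels: int, kernel: int, shared: bool = True, rng=None) -> None:
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.shared = shared
        self.conv_e = Conv1d(kernel, rng=rng)
        self.conv_d = self.conv_e if shared else Conv1d(kernel, rng=rng)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        p = self.conv_e.params()
        if not self.shared:
            p = p + self.conv_d.params()
        return p

    def forward(
        self, f_e: np.ndarray, f_d: np.ndarray, training: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        if f_e.shape != f_d.shape:
            raise ValueError(f"skip-pair shape mismatch: {f_e.shape} vs {f_d.shape}")
        c = f_e.shape[1]
        s = np.concatenate([global_average_pool(f_e), global_average_pool(f_d)], axis=1)
        from .layers import sigmoid

        a_e = sigmoid(self.conv_e.forward(s, training))
        a_d = a_e if self.shared else sigmoid(self.conv_d.forward(s, training))
        m_e = a_e[:, :c]
        m_d = a_d[:, c:]
        ge = m_e[:, :, None, None, None]
        gd = m_d[:, :, None, None, None]
        out_e = f_e * ge
        out_d = f_d * gd
        if training:
            self._cache = (f_e, f_d, a_e, a_d, ge, gd)
        return out_e, out_d

    def backward(self, d_out_e: np.ndarray, d_out_d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        assert self._cache is not None
        f_e, f_d, a_e, a_d, ge, gd = self._cache
        c = f_e.shape[1]
        spatial = f_e.shape[2] * f_e.shape[3] * f_e.shape[4]
        d_fe = d_out_e * ge
        d_fd = d_out_d * gd
        d_me = (d_out_e * f_e).sum(axis=(2, 3, 4))
        d_md = (d_out_d * f_d).sum(axis=(2, 3, 4))
        # route gate grads through sigmoid then the 1D conv(s) back to the stats
        if self.shared:
            d_a = np.zeros_like(a_e)
            d_a[:, :c] = d_me
            d_a[:, c:] = d_md
            d_s = self.conv_e.backward(d_a * a_e * (1 - a_e))
        else:
            d_ae = np.zeros_like(a_e)
            d_ae[:, :c] = d_me
            d_ad = np.zeros_like(a_d)
            d_ad[:, c:] = d_md
            d_s = self.conv_e.backward(d_ae * a_e * (1 - a_e))
            d_s = d_s + self.conv_d.backward(d_ad * a_d * (1 - a_d))
        # GAP backward: broadcast / (L*W*H)
        d_fe += (d_s[:, :c] / spatial)[:, :, None, None, None]
        d_fd += (d_s[:, c:] / spatial)[:, :, None, None, None]
        return d_fe, d_fd


class SpatialGroupAttention(Layer):
    """Per-voxel gating learned independently for G channel groups."""

    def __init__(self, channels: int, groups: int, rng=None) -> None:
        rng = rng or np.random.default_rng()
        if channels % groups:
            raise ValueError(f"groups={groups} does not divide channels={channels}")
        self.channels, self.groups = channels, groups
        self.group_size = channels // groups
        self.proj = [Conv3d(self.group_size, 1, kernel=1, rng=rng) for _ in range(groups)]
        self.spatial = [Conv3d(1, 1, kernel=7, pad=3, rng=rng) for _ in range(groups)]
        self._cache: list | None = None

    def params(self) -> list[Param]:
        out: list[Param] = []
        for p, s in zip(self.proj, self.spatial):
            out.extend(p.params())
            out.extend(s.params())
        return out

    def forward(self, f: np.ndarray, training: bool = True) -> np.ndarray:
        if f.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {f.shape[1]}")
        from .layers import sigmoid

        out = np.empty_like(f)
        cache = []
        cg = self.group_size
        for g in range(self.groups):
            fg = f[:, g * cg : (g + 1) * cg]
            s = self.proj[g].forward(fg, training)
            m = sigmoid(self.spatial[g].forward(s, training))
            out[:, g * cg : (g + 1) * cg] = fg * m
            if training:
                cache.append((fg, m))
        if training:
            self._cache = cache
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        dx = np.empty_like(dy)
        cg = self.group_size
        for g in range(self.groups):
            fg, m = self._cache[g]
            dyg = dy[:, g * cg : (g + 1) * cg]
            d_m = (dyg * fg).sum(axis=1, keepdims=True)
            d_s = self.spatial[g].backward(d_m * m * (1 - m))
            dx[:, g * cg : (g + 1) * cg] = dyg * m + self.proj[g].backward(d_s)
        return dx


class ConvBNReLU(Layer):
    def __init__(self, c_in: int, c_out: int, rng=None) -> None:
        self.conv = Conv3d(c_in, c_out, kernel=3, rng=rng)
        self.bn = BatchNorm3d(c_out)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class ResidualConvBlock(Layer):
    """Two conv3-BN-ReLU layers plus an additive residual shortcut.

    The shortcut is the identity when channel counts match and a 1x1x1
    projection convolution otherwise.
    """

    def __init__(self, c_in: int, c_out: int, rng=None) -> None:
        self.layer1 = ConvBNReLU(c_in, c_out, rng=rng)
        self.layer2 = ConvBNReLU(c_out, c_out, rng=rng)
        self.proj = Conv3d(c_in, c_out, kernel=1, rng=rng) if c_in != c_out else None

    def params(self) -> list[Param]:
        p = self.layer1.params() + self.layer2.params()
        if self.proj is not None:
            p = p + self.proj.params()
        return p

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        main = self.layer2.forward(self.layer1.forward(x, training), training)
        short = x if self.proj is None else self.proj.forward(x, training)
        return main + short

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.layer1.backward(self.layer2.backward(dy))
        dx += dy if self.proj is None else self.proj.backward(dy)
        return dx


class DecoderBlock(Layer):
    """Upsample, gate the skip pair, fuse, spatially refine, residual-adapt.

    Order: transpose-conv upsampling of the deep features to the skip stage's
    shape and channel count; channel fusion attention on (encoder, upsampled)
    pair (identity if disabled); channel concatenation; a fusion conv block
    halving the channels; grouped spatial attention (identity if disabled);
    a final residual convolution block.
    """

    def __init__(self, c_deep: int, c_skip: int, cfg: ModelConfig, rng=None) -> None:
        self.up = ConvTranspose3d(c_deep, c_skip, rng=rng)
        self.channel_attn = (
            ChannelFusionAttention(c_skip, cfg.channel_kernel, cfg.shared_channel_conv, rng=rng)
            if cfg.use_channel_attention
            else None
        )
        self.fuse = ConvBNReLU(2 * c_skip, c_skip, rng=rng)
        self.spatial_attn = (
            SpatialGroupAttention(c_skip, cfg.spatial_groups, rng=rng)
            if cfg.use_spatial_attention
            else None
        )
        self.out_block = ResidualConvBlock(c_skip, c_skip, rng=rng)
        self.c_skip = c_skip

    def params(self) -> list[Param]:
        p = self.up.params()
        if self.channel_attn is not None:
            p = p + self.channel_attn.params()
        p = p + self.fuse.params()
        if self.spatial_attn is not None:
            p = p + self.spatial_attn.params()
        return p + self.out_block.params()

    def forward(self, f_e: np.ndarray, f_deep: np.ndarray, training: bool = True) -> np.ndarray:
        f_d = self.up.forward(f_deep, training)
        if f_d.shape[2:] != f_e.shape[2:]:
            raise ValueError(
                f"spatial mismatch after upsampling: {f_d.shape[2:]} vs skip {f_e.shape[2:]}"
            )
        if self.channel_attn is not None:
            f_e, f_d = self.channel_attn.forward(f_e, f_d, training)
        fused = self.fuse.forward(np.concatenate([f_e, f_d], axis=1), training)
        if self.spatial_attn is not None:
            fused = self.spatial_attn.forward(fused, training)
        return self.out_block.forward(fused, training)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d_fused = self.out_block.backward(dy)
        if self.spatial_attn is not None:
            d_fused = self.spatial_attn.backward(d_fused)
        d_cat = self.fuse.backward(d_fused)
        c = self.c_skip
        d_fe, d_fd = d_cat[:, :c], d_cat[:, c:]
        if self.channel_attn is not None:
            d_fe, d_fd = self.channel_attn.backward(d_fe, d_fd)
        d_deep = self.up.backward(np.ascontiguousarray(d_fd))
        return np.ascontiguousarray(d_fe), d_deep


class AttentionResUNet3D:
    """The full segmentation network (single-channel input and output).

    ``forward`` maps an (N, 1, L, W, H) normalized patch to an equally shaped
    voxel-probability map via a final 1x1x1 convolution and sigmoid; spatial
    dims must be divisible by ``2**(n_encoders - 1)``.
    """

    def __init__(self, config: ModelConfig | None = None) -> None:
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_channels * 2**k for k in range(cfg.n_encoders)]
        self.encoders = [
            ResidualConvBlock(1 if k == 0 else widths[k - 1], widths[k], rng=rng)
            for k in range(cfg.n_encoders)
        ]
        self.pools = [MaxPool3d() for _ in range(cfg.n_encoders - 1)]
        # decoders run deep -> shallow: skip stages n_encoders-2 .. 0
        self.decoders = [
            DecoderBlock(widths[k + 1], widths[k], cfg, rng=rng)
            for k in reversed(range(cfg.n_decoders))
        ]
        self.head = Conv3d(widths[0], 1, kernel=1, rng=rng)
        self.head_act = Sigmoid()

    def params(self) -> list[Param]:
        out: list[Param] = []
        for e in self.encoders:
            out.extend(e.params())
        for d in self.decoders:
            out.extend(d.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, L, W, H) input, got {x.shape}")
        stride = 2 ** (self.config.n_encoders - 1)
        if any(s % stride for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} must be divisible by {stride}")
        skips = []
        f = x
        for k, enc in enumerate(self.encoders):
            f = enc.forward(f, training)
            if k < len(self.pools):
                skips.append(f)
                f = self.pools[k].forward(f, training)
        for dec, skip in zip(self.decoders, reversed(skips)):
            f = dec.forward(skip, f, training)
        return self.head_act.forward(self.head.forward(f, training), training)

    def backward(self, d_prob: np.ndarray) -> None:
        d = self.head.backward(self.head_act.backward(d_prob))
        d_skips = []
        for dec in reversed(self.decoders):
            d_fe, d = dec.backward(d)
            d_skips.append(d_fe)
        d_skips.reverse()  # now ordered shallow -> deep matching encoder stages
        for k in reversed(range(len(self.encoders))):
            if k < len(self.pools):
                d = self.pools[k].backward(d)
                d = d + d_skips[len(self.pools) - 1 - k]
            d = self.encoders[k].backward(d)

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        i = 0
        for layer in self._bn_layers():
            state[f"bn_{i}_mean"] = layer.running_mean
            state[f"bn_{i}_var"] = layer.running_var
            i += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            val = np.asarray(state[f"param_{i}"])
            if val.shape != p.value.shape:
                raise ValueError(f"checkpoint shape mismatch at param {i}")
            p.value = val.astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)
        for i, layer in enumerate(self._bn_layers()):
            layer.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32)
            layer.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float32)

    def _bn_layers(self) -> list[BatchNorm3d]:
        out = []

        def visit(obj):
            if isinstance(obj, BatchNorm3d):
                out.append(obj)
            elif isinstance(obj, ConvBNReLU):
                visit(obj.bn)
            elif isinstance(obj, ResidualConvBlock):
                visit(obj.layer1)
                visit(obj.layer2)
            elif isinstance(obj, DecoderBlock):
                visit(obj.fuse)
                visit(obj.out_block)

        for e in self.encoders:
            visit(e)
        for d in self.decoders:
            visit(d)
        return out


def save_checkpoint(model: AttentionResUNet3D, path: str | Path) -> None:
    """Save weights plus the embedded ModelConfig (self-describing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, __config__=json.dumps(model.config.to_dict()), **model.state_dict())


def load_checkpoint(path: str | Path) -> AttentionResUNet3D:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        model = AttentionResUNet3D(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
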