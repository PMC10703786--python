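"""Three-path U-structure segmentation network (TPUNet).

Three independent encoding paths of increasing depth process the same
image. The shallow (inner) path keeps texture and small-target detail,
the deep (outer) path extracts abstract semantics. A shared decoder
starts from the outer path's deepest features; at each shallower level
the same-resolution skip features from every path that reaches that
level are fused by an attention-based feature fusion (AFF) block that
weights the competing inputs per channel (sigmoid gates) and per pixel
(softmax maps) simultaneously. Auxiliary deep-supervision heads emit a
full-resolution probability map at every decoder level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ArchConfig",
    "NetworkOutput",
    "ChannelAttention",
    "SpatialAttention2",
    "SpatialAttention3",
    "AFF2",
    "AFF3",
    "TPUNet",
    "count_parameters",
]


@dataclass(frozen=True)
class ArchConfig:
    """Structural hyperparameters of the network.

    ``path_depths`` must be strictly increasing and end at ``levels``;
    the default (2, 3, 4) gives one two-input and two three-input fusion
    stages in a four-level decoder. Channel width at level ``l`` is
    ``base_channels * 2**(l-1)``.
    """

    in_channels: int = 1
    base_channels: int = 32
    path_depths: tuple[int, ...] = (2, 3, 4)
    levels: int = 4
    channel_reduce: str = "linear"  # or "paired": shared kernel-2 reduction

    def __post_init__(self):
        if list(self.path_depths) != sorted(set(self.path_depths)):
            raise ValueError("path_depths must be strictly increasing")
        if max(self.path_depths) != self.levels:
            raise ValueError("deepest path must reach `levels`")
        if self.channel_reduce not in ("linear", "paired"):
            raise ValueError("channel_reduce must be 'linear' or 'paired'")

    def channels_at_level(self, level: int) -> int:
        return self.base_channels * 2 ** (level - 1)

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "base_channels": self.base_channels,
            "path_depths": list(self.path_depths),
            "levels": self.levels,
            "channel_reduce": self.channel_reduce,
        }

    @staticmethod
    def from_dict(d: dict) -> "ArchConfig":
        d = dict(d)
        d["path_depths"] = tuple(d["path_depths"])
        return ArchConfig(**d)


@dataclass
class NetworkOutput:
    """Final probability map plus one deep-supervision map per decoder level."""

    prediction: Tensor
    deepsup: list[Tensor] = field(default_factory=list)


class ChannelAttention(nn.Module):
    """Sigmoid channel gate from the pooled descriptors of two inputs.

    Both inputs are globally average-pooled to C-vectors; the two
    descriptors are reduced to one C-vector by a learned map and passed
    through a sigmoid, so each gate value is strictly in (0, 1). The
    fused channel output is ``alpha*A + (1-alpha)*B``.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduce: str = "linear"):
        super().__init__()
        self.channels = channels
        self.reduce = reduce
        if reduce == "linear":
            self.fc = nn.Linear(2 * channels, channels, rng)
        else:  # paired: one shared 2-tap kernel over (gap_A_c, gap_B_c) pairs
            self.kernel = nn.Parameter(rng.normal(0.0, 1.0, size=2).astype(np.float32))
            self.kbias = nn.Parameter(np.zeros(1, dtype=np.float32))

    def __call__(self, a: Tensor, b: Tensor) -> Tensor:
        if a.shape != b.shape:
            raise ValueError(f"channel attention needs equal shapes, got {a.shape} vs {b.shape}")
        ga = nn.global_avg_pool(a)  # (N, C)
        gb = nn.global_avg_pool(b)
        if self.reduce == "linear":
            z = self.fc(nn.concat([ga, gb], axis=1))
        else:
            pairs = nn.reshape(nn.stack([ga, gb], axis=2), (-1, 2))
            z = nn.reshape(nn.matmul(pairs, nn.reshape(self.kernel, (2, 1))), ga.shape) + self.kbias
        alpha = nn.sigmoid(z)
        n, c = alpha.shape
        return nn.reshape(alpha, (n, c, 1, 1))

    def fuse(self, a: Tensor, b: Tensor) -> Tensor:
        alpha = self(a, b)
        return alpha * a + (1.0 - alpha) * b


def _spatial_descriptor(x: Tensor) -> Tensor:
    """Channel-axis average + max pooling stacked into a 2-channel map."""
    return nn.concat([nn.channel_mean(x), nn.channel_max(x)], axis=1)


class SpatialAttention2(nn.Module):
    """Per-pixel softmax competition between two inputs.

    Each input is reduced to a 1-channel map by its own 1x1 convolution
    over the (channel-mean, channel-max) descriptor; a softmax across
    the two maps yields weights that sum to one at every pixel.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(2, 1, 1, rng, pad=0)
        self.conv2 = nn.Conv2d(2, 1, 1, rng, pad=0)

    def __call__(self, a: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
        if a.shape != b.shape:
            raise ValueError(f"spatial attention needs equal shapes, got {a.shape} vs {b.shape}")
        m1 = self.conv1(_spatial_descriptor(a))
        m2 = self.conv2(_spatial_descriptor(b))
        mx = Tensor(np.maximum(m1.data, m2.data))
        e1, e2 = nn.exp(m1 - mx), nn.exp(m2 - mx)
        denom = e1 + e2
        return e1 / denom, e2 / denom

    def fuse(self, a: Tensor, b: Tensor) -> Tensor:
        wa, wb = self(a, b)
        return wa * a + wb * b


class SpatialAttention3(nn.Module):
    """Three-way per-pixel softmax competition (three independent 1x1 convs)."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(2, 1, 1, rng, pad=0)
        self.conv2 = nn.Conv2d(2, 1, 1, rng, pad=0)
        self.conv3 = nn.Conv2d(2, 1, 1, rng, pad=0)

    def __call__(self, a: Tensor, b: Tensor, c: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        m1 = self.conv1(_spatial_descriptor(a))
        m2 = self.conv2(_spatial_descriptor(b))
        m3 = self.conv3(_spatial_descriptor(c))
        mx = Tensor(np.maximum(np.maximum(m1.data, m2.data), m3.data))
        e1, e2, e3 = nn.exp(m1 - mx), nn.exp(m2 - mx), nn.exp(m3 - mx)
        denom = e1 + e2 + e3
        return e1 / denom, e2 / denom, e3 / denom


class AFF2(nn.Module):
    """Attention-based fusion of two same-resolution feature maps:
    ``out = alpha*alpha'*A + (1-alpha)*beta'*B``."""

    def __init__(self, channels: int, rng: np.random.Generator, reduce: str = "linear"):
        super().__init__()
        self.channel = ChannelAttention(channels, rng, reduce)
        self.spatial = SpatialAttention2(rng)

    def weights(self, a: Tensor, b: Tensor):
        alpha = self.channel(a, b)
        ap, bp = self.spatial(a, b)
        return alpha, ap, bp

    def __call__(self, a: Tensor, b: Tensor) -> Tensor:
        alpha, ap, bp = self.weights(a, b)
        return (alpha * ap) * a + ((1.0 - alpha) * bp) * b


class AFF3(nn.Module):
    """Attention-based fusion of three feature maps:
    ``out = a(1-b)a'*A + b(1-g)b'*B + g(1-a)g'*C`` with channel gates
    from cyclic pairs (A,B) -> a, (B,C) -> b, (C,A) -> g."""

    def __init__(self, channels: int, rng: np.random.Generator, reduce: str = "linear"):
        super().__init__()
        self.ch_ab = ChannelAttention(channels, rng, reduce)
        self.ch_bc = ChannelAttention(channels, rng, reduce)
        self.ch_ca = ChannelAttention(channels, rng, reduce)
        self.spatial = SpatialAttention3(rng)

    def weights(self, a: Tensor, b: Tensor, c: Tensor):
        alpha = self.ch_ab(a, b)
        beta = self.ch_bc(b, c)
        gamma = self.ch_ca(c, a)
        ap, bp, cp = self.spatial(a, b, c)
        return alpha, beta, gamma, ap, bp, cp

    def __call__(self, a: Tensor, b: Tensor, c: Tensor) -> Tensor:
        alpha, beta, gamma, ap, bp, cp = self.weights(a, b, c)
        return (
            (alpha * (1.0 - beta) * ap) * a
            + (beta * (1.0 - gamma) * bp) * b
            + (gamma * (1.0 - alpha) * cp) * c
        )


class TPUNet(nn.Module):
    """The full three-path network; see the module docstring for the layout."""

    def __init__(self, config: ArchConfig = ArchConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config

        # encoding paths, inner (shallow) to outer (deep)
        self.paths = []
        for depth in cfg.path_depths:
            blocks = []
            for level in range(1, depth + 1):
                in_ch = cfg.in_channels if level == 1 else cfg.channels_at_level(level - 1)
                blocks.append(nn.ConvBlock(in_ch, cfg.channels_at_level(level), rng))
            self.paths.append(blocks)

        # decoder: one stage per level below the bottleneck
        self.fusers = []
        self.dec_blocks = []
        for level in range(cfg.levels - 1, 0, -1):
            n_in = sum(1 for d in cfg.path_depths if d >= level)
            ch = cfg.channels_at_level(level)
            if n_in == 2:
                self.fusers.append(AFF2(ch, rng, cfg.channel_reduce))
            elif n_in >= 3:
                self.fusers.append(AFF3(ch, rng, cfg.channel_reduce))
            else:
                self.fusers.append(None)
            self.dec_blocks.append(nn.ConvBlock(cfg.channels_at_level(level + 1) + ch, ch, rng))

        # deep-supervision heads: bottleneck + each decoder stage
        self.ds_heads = [
            nn.Conv2d(cfg.channels_at_level(level), 1, 3, rng)
            for level in range(cfg.levels, 0, -1)
        ]
        self.final_head = nn.Conv2d(cfg.base_channels, 1, 1, rng, pad=0)

    # ------------------------------------------------------------------
    def _encode(self, x: Tensor) -> list[list[Tensor]]:
        """Run every path; returns per-path lists of level-1..depth features."""
        all_feats = []
        for blocks in self.paths:
            feats = []
            h = x
            for i, block in enumerate(blocks):
                if i > 0:
                    h = nn.maxpool2x2(h)
                h = block(h)
                feats.append(h)
            all_feats.append(feats)
        return all_feats

    def __call__(self, x) -> NetworkOutput:
        x = nn.as_tensor(x)
        n, c, h, w = x.shape
        stride = 2 ** (self.config.levels - 1)
        if h % stride or w % stride:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by {stride} "
                f"(the network downsamples {self.config.levels - 1} times)"
            )
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channel(s), got {c}")

        feats = self._encode(x)
        cfg = self.config
        dec = feats[-1][-1]  # outer path, deepest level (bottleneck)
        ds_feats = [dec]
        for stage, level in enumerate(range(cfg.levels - 1, 0, -1)):
            sh, sw = h // 2 ** (level - 1), w // 2 ** (level - 1)
            up = nn.upsample_bilinear(dec, sh, sw)
            skips = [feats[i][level - 1] for i, d in enumerate(cfg.path_depths) if d >= level]
            fuser = self.fusers[stage]
            if fuser is None:
                skip = skips[0]
            elif isinstance(fuser, AFF2):
                skip = fuser(skips[-1], skips[-2])  # outer first, then middle
            else:
                skip = fuser(skips[-1], skips[-2], skips[-3])  # outer, middle, inner
            dec = self.dec_blocks[stage](nn.concat([up, skip], axis=1))
            ds_feats.append(dec)

        deepsup = [
            nn.sigmoid(nn.upsample_bilinear(head(f), h, w))
            for head, f in zip(self.ds_heads, ds_feats)
        ]
        prediction = nn.sigmoid(self.final_head(dec))
        return NetworkOutput(prediction=prediction, deepsup=deepsup)

    # ------------------------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Forward pass in eval mode; returns the (N,1,H,W) probability map."""
        was_training = self.training
        self.eval()
        out = self(Tensor(images)).prediction.data
        if was_training:
            self.train()
        return out


def count_parameters(config: ArchConfig = ArchConfig()) -> int:
    """Total trainable parameter count for a configuration."""
    model = TPUNet(config, seed=0)
    return sum(p.data.size for p in model.parameters())
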