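"""Inception-augmented U-Net segmentation network.

The encoder stacks inception blocks (parallel 1x1 / 3x3 / 5x5 branches,
channel-concatenated, with an optional residual add) at each resolution level,
compresses channels through a 1x1 "levelled bottleneck", and halves the
spatial size with 2x2 max pooling.  The decoder mirrors the ladder with
nearest-neighbor upsampling + 3x3 convolution, concatenating both the ordinary
skip connection and a "historic stamp" — a learned 1x1 projection of the same
cached encoder features — before inception fusion.  A 1x1 convolution with
sigmoid produces per-pixel foreground probabilities.  Every convolution is
followed by batch normalization, ReLU and dropout (rate 0.3 by default).

An optional pyramid-pooling block at the bottleneck average-pools at scales
{1, 2, 4}, projects each scale with a 1x1 convolution, upsamples and
concatenates, giving the bottleneck multi-scale spatial context.

Channel widths double per level from ``base_filters``; a 512-input, 4-level
configuration downsamples to a 32x32 bottleneck as in the full-scale design,
while the desk profile (64-input, 2 levels) bottoms out at 16x16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (BatchNorm2d, Conv2d, Dropout, Tensor, avgpool,
                       concat, maxpool2x2, upsample_nearest, upsample_nearest2x)

__all__ = ["NetConfig", "GraphSummary", "UIGONet", "build"]


@dataclass(frozen=True)
class NetConfig:
    input_size: int = 64
    levels: int = 2
    base_filters: int = 8
    inception_kernels: tuple[int, ...] = (1, 3, 5)
    inception_modules: int = 1
    bottleneck_ratio: float = 0.5
    dropout: float = 0.3
    use_residual: bool = True
    use_historic_stamp: bool = True
    use_pyramid_pool: bool = False
    out_channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.input_size & (self.input_size - 1):
            raise ValueError(f"input_size must be a power of 2, got {self.input_size}")
        size = self.input_size
        for level in range(self.levels):
            if size % 2 or size // 2 < 4:
                raise ValueError(
                    f"level {level} would shrink {size}x{size} below the 4-pixel "
                    f"minimum; reduce levels or enlarge input_size")
            size //= 2
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")
        if not 0.0 < self.bottleneck_ratio <= 1.0:
            raise ValueError(f"bottleneck_ratio must be in (0,1], got {self.bottleneck_ratio}")
        if any(k % 2 == 0 for k in self.inception_kernels):
            raise ValueError("inception kernels must be odd")
        if self.base_filters < len(self.inception_kernels):
            raise ValueError(
                f"base_filters={self.base_filters} cannot feed "
                f"{len(self.inception_kernels)} inception branches")

    def level_width(self, k: int) -> int:
        return self.base_filters * 2 ** k

    def compressed_width(self, k: int) -> int:
        return max(1, int(self.level_width(k) * self.bottleneck_ratio))


@dataclass
class GraphSummary:
    spatial_sizes: list[int]          # encoder spatial size per level, incl. bottom
    channel_counts: list[int]         # encoder stage output width per level, incl. bottom
    decoder_in_channels: list[int]    # concatenated decoder input per level (deep->shallow)
    bottleneck_size: int = 0
    total_params: int = 0
    output_shape: tuple = ()

    def as_dict(self) -> dict:
        return {"spatial_sizes": self.spatial_sizes,
                "channel_counts": self.channel_counts,
                "decoder_in_channels": self.decoder_in_channels,
                "bottleneck_size": self.bottleneck_size,
                "total_params": self.total_params,
                "output_shape": list(self.output_shape)}


class _ConvUnit:
    """Conv -> BatchNorm -> ReLU -> Dropout."""

    def __init__(self, cin, cout, k, dropout, rng):
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout)
        self.drop = Dropout(dropout)

    def __call__(self, x, training, rng):
        return self.drop(self.bn(self.conv(x), training).relu(), training, rng)

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


def _branch_widths(width: int, kernels: tuple[int, ...]) -> list[int]:
    """Split `width` across branches; the remainder goes to the 3x3 branch."""
    nb = len(kernels)
    base = width // nb
    widths = [base] * nb
    rem = width - base * nb
    target = kernels.index(3) if 3 in kernels else 0
    widths[target] += rem
    return widths


class _InceptionBranch:
    """One inception branch: a 1x1 unit, preceded for k > 1 by a 1x1 channel
    reduction (the classic inception economy measure) and followed by the
    k x k convolution unit."""

    def __init__(self, cin, bw, k, dropout, rng):
        if k == 1:
            self.units = [_ConvUnit(cin, bw, 1, dropout, rng)]
        else:
            self.units = [_ConvUnit(cin, bw, 1, dropout, rng),
                          _ConvUnit(bw, bw, k, dropout, rng)]

    def __call__(self, x, training, rng):
        for unit in self.units:
            x = unit(x, training, rng)
        return x

    def parameters(self):
        return [p for u in self.units for p in u.parameters()]


class _InceptionBlock:
    """Parallel multi-kernel branches, concatenated, optional residual add."""

    def __init__(self, cin, width, kernels, dropout, use_residual, rng):
        self.branches = [
            _InceptionBranch(cin, bw, k, dropout, rng)
            for k, bw in zip(kernels, _branch_widths(width, kernels))
        ]
        self.use_residual = use_residual
        self.project = None
        if use_residual and cin != width:
            self.project = _ConvUnit(cin, width, 1, dropout, rng)

    def __call__(self, x, training, rng):
        out = concat([b(x, training, rng) for b in self.branches], axis=1)
        if self.use_residual:
            res = self.project(x, training, rng) if self.project is not None else x
            out = out + res
        return out

    def parameters(self):
        params = [p for b in self.branches for p in b.parameters()]
        if self.project is not None:
            params += self.project.parameters()
        return params


class _PyramidPool:
    """Average pools at scales {1,2,4}, 1x1-projected, upsampled, concatenated,
    then fused back to `width` channels with a 1x1 convolution."""

    SCALES = (1, 2, 4)

    def __init__(self, width, dropout, rng):
        proj_w = max(1, width // len(self.SCALES))
        self.projections = [_ConvUnit(width, proj_w, 1, dropout, rng) for _ in self.SCALES]
        self.fuse = _ConvUnit(width + proj_w * len(self.SCALES), width, 1, dropout, rng)

    def __call__(self, x, training, rng):
        pieces = [x]
        for s, proj in zip(self.SCALES, self.projections):
            pooled = x if s == 1 else avgpool(x, s)
            projected = proj(pooled, training, rng)
            pieces.append(projected if s == 1 else upsample_nearest(projected, s))
        return self.fuse(concat(pieces, axis=1), training, rng)

    def parameters(self):
        return [p for u in self.projections for p in u.parameters()] + self.fuse.parameters()


class UIGONet:
    """The assembled network; use :func:`build` to construct it."""

    def __init__(self, config: NetConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        self.enc_stages: list[list[_InceptionBlock]] = []
        self.enc_bottlenecks: list[_ConvUnit] = []
        self.stamp_projections: list[_ConvUnit | None] = []
        cin = 1
        for k in range(c.levels):
            w = c.level_width(k)
            blocks = []
            for m in range(c.inception_modules):
                blocks.append(_InceptionBlock(cin if m == 0 else w, w,
                                              c.inception_kernels, c.dropout,
                                              c.use_residual, rng))
            self.enc_stages.append(blocks)
            self.enc_bottlenecks.append(_ConvUnit(w, c.compressed_width(k), 1, c.dropout, rng))
            cin = c.compressed_width(k)

        w_bottom = c.level_width(c.levels)
        self.bottom_blocks = []
        for m in range(c.inception_modules):
            self.bottom_blocks.append(_InceptionBlock(cin if m == 0 else w_bottom, w_bottom,
                                                      c.inception_kernels, c.dropout,
                                                      c.use_residual, rng))
        self.pyramid = _PyramidPool(w_bottom, c.dropout, rng) if c.use_pyramid_pool else None

        self.dec_upconvs: list[_ConvUnit] = []
        self.dec_stages: list[list[_InceptionBlock]] = []
        self.decoder_in_channels: list[int] = []
        cur = w_bottom
        for k in reversed(range(c.levels)):
            w = c.level_width(k)
            self.dec_upconvs.append(_ConvUnit(cur, w, 3, c.dropout, rng))
            if c.use_historic_stamp:
                self.stamp_projections.append(_ConvUnit(w, w, 1, c.dropout, rng))
                dec_in = 3 * w
            else:
                self.stamp_projections.append(None)
                dec_in = 2 * w
            self.decoder_in_channels.append(dec_in)
            blocks = []
            for m in range(c.inception_modules):
                blocks.append(_InceptionBlock(dec_in if m == 0 else w, w,
                                              c.inception_kernels, c.dropout,
                                              c.use_residual, rng))
            self.dec_stages.append(blocks)
            cur = w
        self.head = Conv2d(c.level_width(0), c.out_channels, 1, rng)

    # -- plumbing -------------------------------------------------------------
    def modules(self):
        for stage in self.enc_stages:
            yield from stage
        yield from self.enc_bottlenecks
        yield from self.bottom_blocks
        if self.pyramid is not None:
            yield self.pyramid
        yield from self.dec_upconvs
        for proj in self.stamp_projections:
            if proj is not None:
                yield proj
        for stage in self.dec_stages:
            yield from stage
        yield self.head

    def parameters(self):
        return [p for m in self.modules() for p in m.parameters()]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward --------------------------------------------------------------
    def forward(self, batch: np.ndarray | Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Probability maps for an (N, H, W) or (N, 1, H, W) batch.

        Evaluation mode (the default) uses running batch-norm statistics and
        disables dropout, so it is deterministic and mutates no state.
        """
        if training and rng is None:
            rng = np.random.default_rng(self.config.seed)
        if not isinstance(batch, Tensor):
            arr = np.asarray(batch, dtype=np.float64)
            if arr.ndim == 3:
                arr = arr[:, None, :, :]
            batch = Tensor(arr)
        size = self.config.input_size
        if batch.data.shape[-2:] != (size, size):
            raise ValueError(
                f"expected {size}x{size} input, got {batch.data.shape[-2]}x{batch.data.shape[-1]}")

        x = batch
        skips: list[Tensor] = []
        for blocks, bottleneck in zip(self.enc_stages, self.enc_bottlenecks):
            for block in blocks:
                x = block(x, training, rng)
            skips.append(x)
            x = maxpool2x2(bottleneck(x, training, rng))
        for block in self.bottom_blocks:
            x = block(x, training, rng)
        if self.pyramid is not None:
            x = self.pyramid(x, training, rng)

        for i, (upconv, blocks) in enumerate(zip(self.dec_upconvs, self.dec_stages)):
            skip = skips[-(i + 1)]
            x = upconv(upsample_nearest2x(x), training, rng)
            pieces = [x, skip]
            proj = self.stamp_projections[i]
            if proj is not None:
                pieces.append(proj(skip, training, rng))
            x = concat(pieces, axis=1)
            for block in blocks:
                x = block(x, training, rng)
        return self.head(x).sigmoid()

    def summary(self) -> GraphSummary:
        c = self.config
        spatial = [c.input_size // 2 ** k for k in range(c.levels + 1)]
        channels = [c.level_width(k) for k in range(c.levels + 1)]
        return GraphSummary(
            spatial_sizes=spatial,
            channel_counts=channels,
            decoder_in_channels=list(self.decoder_in_channels),
            bottleneck_size=spatial[-1],
            total_params=self.n_params(),
            output_shape=(c.out_channels, c.input_size, c.input_size),
        )


def build(config: NetConfig) -> tuple[UIGONet, GraphSummary]:
    """Construct the network and its graph summary."""
    net = UIGONet(config)
    return net, net.summary()
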