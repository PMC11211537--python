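"""Network architectures for joint GTV segmentation and T-stage prediction.

Three pieces, mirroring the multi-task design:

* :class:`SegNet3D` — a U-shaped encoder/decoder (eight encoder units,
  seven decoder units) producing a voxelwise tumor-probability map
  through a 1x1x1 convolution and sigmoid, plus feature taps from the
  bottom of the U (seventh and eighth encoder units, first decoder
  unit).
* :class:`Backbone3D` — a four-stage residual ("bottleneck transformer")
  classification backbone whose final three bottleneck blocks replace
  their spatial convolution with multi-head self-attention.
* :class:`FFAModule` — the feature-fusion-aware block: the segmentation
  taps are projected by 1x1x1 convolutions, resized to the backbone
  grid, concatenated with the backbone features and passed through a
  multi-head self-attention layer.  The ablated variant fuses by plain
  concatenation.

The segmentation probability map multiplies the input volume
(:func:`mask_apply`) to form the staging network's input, keeping the
whole model differentiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import (
    Conv3d,
    InstanceNorm3d,
    Linear,
    Module,
    MultiHeadSelfAttention3d,
    Tensor,
    concat,
    grad_scale,
    pool3d,
    resize_trilinear,
    upsample_nearest,
)

__all__ = [
    "NetConfig",
    "SegOutput",
    "StagePrediction",
    "ShapeConfigError",
    "SegNet3D",
    "Backbone3D",
    "FFAModule",
    "Classifier",
    "MultiTaskModel",
    "mask_apply",
    "seg_forward",
]

N_STAGES = 4
_AXES = ("slice", "row", "column")


class ShapeConfigError(ValueError):
    """Input grid incompatible with a downsampling schedule."""


def _auto_seg_pools(shape: tuple[int, int, int]) -> tuple[tuple[int, int, int], ...]:
    """Pooling factors after encoder units 1..7 (7 entries).

    In-plane axes are halved at the earliest units while they stay
    divisible by 2 and at least 6; the slice axis is halved at
    alternating units while divisible and at least 8.  Later units run
    at constant resolution, which keeps the deepest grid comfortably
    above a single voxel for anisotropic inputs.
    """
    d, h, w = shape
    pools = []
    slice_turn = False
    for _ in range(7):
        fh = 2 if (h % 2 == 0 and h >= 6) else 1
        fw = 2 if (w % 2 == 0 and w >= 6) else 1
        fd = 2 if (slice_turn and d % 2 == 0 and d >= 8) else 1
        slice_turn = not slice_turn
        pools.append((fd, fh, fw))
        d, h, w = d // fd, h // fh, w // fw
    return tuple(pools)


def _auto_backbone_pools(shape: tuple[int, int, int]) -> tuple[tuple[int, int, int], ...]:
    """Stem pool plus one transition pool per stage 2..4 (4 entries)."""
    d, h, w = shape
    pools = []
    for _ in range(4):
        fh = 2 if (h % 2 == 0 and h >= 4) else 1
        fw = 2 if (w % 2 == 0 and w >= 4) else 1
        fd = 2 if (d % 2 == 0 and d >= 4) else 1
        pools.append((fd, fh, fw))
        d, h, w = d // fd, h // fh, w // fw
    return tuple(pools)


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters.

    ``seg_pools`` (7 per-axis factor triples) and ``backbone_pools``
    (stem + 3 stage transitions) default to schedules derived from
    ``input_shape``; all factors must be 1 or 2 and must divide the
    running grid size.
    """

    input_shape: tuple[int, int, int] = (16, 64, 64)
    base_channels: int = 8
    channel_cap: int = 32
    seg_pools: tuple[tuple[int, int, int], ...] | None = None
    backbone_width: int = 8
    backbone_pools: tuple[tuple[int, int, int], ...] | None = None
    heads: int = 4
    attention: bool = True
    dropout: float = 0.0
    # backward-pass attenuation on the mask-multiply edge; 1.0 = untouched.
    # The staging loss back-propagates far larger gradients through the
    # multiplied probability map than the overlap loss produces, so without
    # attenuation it swamps segmentation learning in short runs.  The
    # feature taps are left untouched: their gradients are well-scaled and
    # they carry the cross-task feature shaping.
    cross_grad_scale: float = 0.05
    dtype: str = "float32"

    def resolved(self) -> "NetConfig":
        cfg = self
        if cfg.seg_pools is None:
            cfg = replace(cfg, seg_pools=_auto_seg_pools(cfg.input_shape))
        if cfg.backbone_pools is None:
            cfg = replace(cfg, backbone_pools=_auto_backbone_pools(cfg.input_shape))
        _validate_schedule(cfg.input_shape, cfg.seg_pools, "segmentation")
        _validate_schedule(cfg.input_shape, cfg.backbone_pools, "backbone")
        return cfg

    def fingerprint(self) -> str:
        cfg = self.resolved()
        return repr((cfg.input_shape, cfg.base_channels, cfg.channel_cap, cfg.seg_pools,
                     cfg.backbone_width, cfg.backbone_pools, cfg.heads, cfg.attention))

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _validate_schedule(shape, pools, label: str) -> None:
    sizes = list(shape)
    for step, factors in enumerate(pools):
        for ax, f in enumerate(factors):
            if f not in (1, 2):
                raise ShapeConfigError(f"{label} pool factor {f} at step {step} (must be 1 or 2)")
            if sizes[ax] % f:
                raise ShapeConfigError(
                    f"{label} schedule step {step}: {_AXES[ax]} axis of size {sizes[ax]} "
                    f"not divisible by {f}")
        sizes = [s // f for s, f in zip(sizes, factors)]


def _grid_after(shape, pools, n: int | None = None) -> tuple[int, int, int]:
    sizes = list(shape)
    for factors in (pools if n is None else pools[:n]):
        sizes = [s // f for s, f in zip(sizes, factors)]
    return tuple(sizes)


@dataclass
class SegOutput:
    """Voxelwise tumor probabilities plus bottom-of-U feature taps."""

    prob_map: Tensor          # (N, 1, D, H, W), values in [0, 1]
    tap_e7: Tensor            # seventh encoder unit output
    tap_e8: Tensor            # eighth (final) encoder unit output
    tap_d1: Tensor            # first decoder unit output


@dataclass
class StagePrediction:
    """Four-way T-stage probabilities (T1..T4)."""

    logits: Tensor            # (N, 4)
    probs: Tensor             # (N, 4), rows sum to 1

    def stage(self) -> np.ndarray:
        """Predicted stages as integers in 1..4."""
        return np.argmax(self.probs.data, axis=-1) + 1


class _ConvUnit(Module):
    def __init__(self, cin, cout, kernel, rng, dtype):
        self.conv = Conv3d(cin, cout, kernel, rng, dtype)
        self.norm = InstanceNorm3d(cout, dtype=dtype)

    def forward(self, x):
        return self.norm(self.conv(x)).relu()


def _split_pool(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    """Max pooling in-plane, average pooling along slices."""
    fd, fh, fw = factors
    if fh > 1 or fw > 1:
        x = pool3d(x, (1, fh, fw), "max")
    if fd > 1:
        x = pool3d(x, (fd, 1, 1), "avg")
    return x


class SegNet3D(Module):
    """U-shaped 3D segmentation network: 8 encoder and 7 decoder units."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        cfg = config.resolved()
        self.config = cfg
        dtype = cfg.np_dtype
        pools = cfg.seg_pools
        depth = np.cumsum([0] + [int(any(f > 1 for f in p)) for p in pools])
        ch = [min(cfg.base_channels * 2 ** int(d), cfg.channel_cap) for d in depth]  # 8 entries
        self.channels = ch
        enc = []
        cin = 1
        for i in range(8):
            enc.append(_ConvUnit(cin, ch[i], 3, rng, dtype))
            cin = ch[i]
        self.encoders = enc
        dec = []
        for j in range(7):
            lvl = 6 - j                     # encoder level joined by skip
            cin_dec = (ch[7] if j == 0 else ch[lvl + 1]) + ch[lvl]
            dec.append(_ConvUnit(cin_dec, ch[lvl], 3, rng, dtype))
        self.decoders = dec
        self.head = Conv3d(ch[0], 1, 1, rng, dtype)
        # prior-probability bias init: start the sigmoid near the rare-
        # foreground rate so early training is not dominated by background
        self.head.bias.data[:] = -2.0

    def forward(self, x: Tensor) -> SegOutput:
        cfg = self.config
        if tuple(x.shape[2:]) != cfg.input_shape:
            for ax, (got, want) in enumerate(zip(x.shape[2:], cfg.input_shape)):
                if got != want:
                    raise ShapeConfigError(
                        f"{_AXES[ax]} axis of size {got} does not match configured {want}")
        skips = []
        h = x
        for i in range(8):
            h = self.encoders[i](h)
            if i < 7:
                skips.append(h)
                h = _split_pool(h, cfg.seg_pools[i])
        tap_e7, tap_e8 = skips[6], h
        d1 = None
        for j in range(7):
            h = upsample_nearest(h, cfg.seg_pools[6 - j])
            h = self.decoders[j](concat([h, skips[6 - j]], axis=1))
            if j == 0:
                d1 = h
        prob = self.head(h).sigmoid()
        return SegOutput(prob_map=prob, tap_e7=tap_e7, tap_e8=tap_e8, tap_d1=d1)


def mask_apply(volume: Tensor, prob_map: Tensor) -> Tensor:
    """Multiply the image by the (soft) segmentation map, elementwise.

    Gradients flow through both factors, so staging errors can steer
    the segmentation output.
    """
    if volume.shape != prob_map.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs prob_map {prob_map.shape}")
    return volume * prob_map


class _BottleneckBlock(Module):
    """Residual bottleneck; spatial step is a 3x3x3 conv or MHSA."""

    def __init__(self, channels, rng, dtype, attention: MultiHeadSelfAttention3d | None):
        mid = max(channels // 2, 4)
        self.reduce = _ConvUnit(channels, mid, 1, rng, dtype)
        self.attn = attention
        self.spatial_conv = None if attention is not None else Conv3d(mid, mid, 3, rng, dtype)
        self.spatial_norm = InstanceNorm3d(mid, dtype=dtype)
        self.expand = Conv3d(mid, channels, 1, rng, dtype)
        self.expand_norm = InstanceNorm3d(channels, dtype=dtype)

    def forward(self, x):
        h = self.reduce(x)
        h = self.attn(h) if self.attn is not None else self.spatial_conv(h)
        h = self.spatial_norm(h).relu()
        h = self.expand_norm(self.expand(h))
        return (h + x).relu()


class Backbone3D(Module):
    """Four-stage residual hierarchy; stage 4 holds three MHSA blocks."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        cfg = config.resolved()
        self.config = cfg
        dtype = cfg.np_dtype
        w = cfg.backbone_width
        widths = [w, 2 * w, 4 * w, 4 * w]
        pools = cfg.backbone_pools
        grid = _grid_after(cfg.input_shape, pools)
        if min(grid) < 1:
            raise ShapeConfigError(f"input {cfg.input_shape} too small for backbone schedule")
        self.final_grid = grid
        self.out_channels = widths[-1]
        self.stem = _ConvUnit(1, widths[0], 3, rng, dtype)
        self.stem_pool = pools[0]
        transitions, stages = [], []
        cin = widths[0]
        for s in range(4):
            if s > 0:
                transitions.append(_ConvUnit(cin, widths[s], 1, rng, dtype))
                cin = widths[s]
            if s < 3:
                stages.append([_BottleneckBlock(cin, rng, dtype, None)])
            else:
                mid = max(cin // 2, 4)
                blocks = []
                for _ in range(3):
                    attn = (MultiHeadSelfAttention3d(mid, grid, cfg.heads, rng, dtype)
                            if cfg.attention else None)
                    blocks.append(_BottleneckBlock(cin, rng, dtype, attn))
                stages.append(blocks)
        self.transitions = transitions
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self._stage_pools = pools[1:]

    def forward(self, x: Tensor) -> Tensor:
        h = _split_pool(self.stem(x), self.stem_pool)
        for s, blocks in enumerate((self.stage1, self.stage2, self.stage3, self.stage4)):
            if s > 0:
                h = _split_pool(h, self._stage_pools[s - 1])
                h = self.transitions[s - 1](h)
            for block in blocks:
                h = block(h)
        return h


class FFAModule(Module):
    """Feature-fusion-aware block joining segmentation taps and backbone features.

    With ``attention=False`` this degrades to the ablation variant:
    projected taps and backbone features are concatenated and reduced by
    a pointwise convolution only.
    """

    def __init__(self, tap_channels: tuple[int, int, int], backbone_channels: int,
                 grid: tuple[int, int, int], heads: int, rng: np.random.Generator,
                 attention: bool = True, dtype=np.float32):
        proj_ch = max(backbone_channels // 2, 4)
        self.grid = tuple(grid)
        self.projections = [Conv3d(c, proj_ch, 1, rng, dtype) for c in tap_channels]
        self.reduce = _ConvUnit(3 * proj_ch + backbone_channels, backbone_channels, 1, rng, dtype)
        self.attn = (MultiHeadSelfAttention3d(backbone_channels, self.grid, heads, rng, dtype)
                     if attention else None)
        self.out_channels = backbone_channels

    def forward(self, taps: tuple[Tensor, Tensor, Tensor], backbone_feat: Tensor) -> Tensor:
        parts = []
        for proj, tap in zip(self.projections, taps):
            t = proj(tap)
            if tuple(t.shape[2:]) != self.grid:
                t = resize_trilinear(t, self.grid)
            parts.append(t)
        fused = self.reduce(concat(parts + [backbone_feat], axis=1))
        if self.attn is not None:
            fused = (self.attn(fused) + fused).relu()
        return fused


class Classifier(Module):
    """Global average pooling followed by an affine map to 4 stage logits."""

    def __init__(self, cin: int, rng: np.random.Generator, dropout: float = 0.0,
                 dtype=np.float32):
        self.fc = Linear(cin, N_STAGES, rng, dtype)
        self.fc.weight.data[:] = 0.0  # start from uniform stage probabilities
        self.dropout = dropout
        self._rng = np.random.default_rng(rng.integers(2 ** 31))
        self.training = False

    def forward(self, fused: Tensor) -> StagePrediction:
        pooled = fused.mean(axis=(2, 3, 4))
        if self.training and self.dropout > 0:
            keep = (self._rng.random(pooled.shape) >= self.dropout) / (1.0 - self.dropout)
            pooled = pooled * Tensor(keep.astype(pooled.dtype))
        logits = self.fc(pooled)
        return StagePrediction(logits=logits, probs=logits.softmax(axis=-1))


class MultiTaskModel(Module):
    """End-to-end multi-task model: segment, mask, stage.

    ``mode`` selects the architecture variant: ``"full"`` (default) uses
    the attention-based feature fusion; ``"wo_ffa"`` fuses by plain
    concatenation.  (The "separate" ablation is a *training* protocol on
    the full architecture, handled by the trainer.)
    """

    def __init__(self, config: NetConfig, seed: int = 0, mode: str = "full"):
        if mode not in ("full", "wo_ffa"):
            raise ValueError(f"unknown architecture mode {mode!r}")
        cfg = config.resolved()
        self.config = cfg
        self.mode = mode
        rng = np.random.default_rng(seed)
        dtype = cfg.np_dtype
        self.segnet = SegNet3D(cfg, rng)
        self.backbone = Backbone3D(cfg, rng)
        ch = self.segnet.channels
        self.ffa = FFAModule((ch[6], ch[7], ch[6]), self.backbone.out_channels,
                             self.backbone.final_grid, cfg.heads, rng,
                             attention=(mode == "full" and cfg.attention), dtype=dtype)
        self.classifier = Classifier(self.ffa.out_channels, rng, cfg.dropout, dtype)

    def train(self, flag: bool = True) -> None:
        self.classifier.training = flag

    def forward(self, x: Tensor) -> tuple[SegOutput, StagePrediction]:
        seg = self.segnet(x)
        s = self.config.cross_grad_scale
        taps = (seg.tap_e7, seg.tap_e8, seg.tap_d1)
        prob = seg.prob_map if s == 1.0 else grad_scale(seg.prob_map, s)
        masked = mask_apply(x, prob)
        feat = self.backbone(masked)
        fused = self.ffa(taps, feat)
        return seg, self.classifier(fused)

    def seg_parameters(self) -> list[Tensor]:
        return self.segnet.parameters()

    def cls_parameters(self) -> list[Tensor]:
        ids = {id(p) for p in self.segnet.parameters()}
        return [p for p in self.parameters() if id(p) not in ids]


def seg_forward(volume: np.ndarray, config: NetConfig,
                model: SegNet3D | None = None, seed: int = 0) -> SegOutput:
    """Run the segmentation network on a single unbatched volume.

    A fresh seeded network is built when ``model`` is not given; mainly
    a convenience for inspecting shapes and contracts.
    """
    if model is None:
        model = SegNet3D(config, np.random.default_rng(seed))
    x = Tensor(np.asarray(volume, dtype=model.config.np_dtype)[None, None])
    return model(x)
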