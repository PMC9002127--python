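"""U-shaped encoder-decoder detection network with four stride-4 heads.

The encoder is a stack of residual stages downsampling the input to 1/32;
the decoder upsamples back to 1/4 (bilinear x2, then a 3x3 refinement,
concatenation with the matching encoder skip, and a 1x1 channel fusion).
When ``use_mhsa`` is on, multi-head self-attention replaces the spatial
3x3 convolution in the last encoder bottleneck and in every decoder
block, giving the network a global receptive field for tracing long,
partially missing skull edges.  ``use_deformable`` requests deformable
convolutions in the last two encoder stages; no such operator is
available here, so the flag falls back to standard convolution with a
logged warning.

Four heads emit, at stride 4: the center heatmap (sigmoid), the
sub-pixel center offset (sigmoid, since offsets live in [0, 1)), the
ellipse semi-axes (softplus, strictly positive, in input pixels), and
the soft-stagewise-regression angle head (per-stage softmax bin
probabilities and tanh-squashed per-bin shifts eta, both per pixel, plus
per-image tanh-squashed stage scale modifiers Delta from globally pooled
bottleneck features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_cells, softmax, upsample2x
from .nn import MHSA, SGD, BatchNorm2d, Conv2d, Linear, Module
from .ssr import SSRConfig

__all__ = ["ModelConfig", "DetectionOutput", "EllipseNet", "build_model"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.  ``input_size`` must divide by 32."""

    input_size: tuple[int, int] = (96, 96)
    stride: int = 4
    base_channels: int = 16
    encoder_depth: int = 5
    use_mhsa: bool = True
    use_deformable: bool = False
    attention_heads: int = 4
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input size {self.input_size} must be divisible by 32")
        if self.stride != 4:
            raise ValueError("heads are defined at stride 4")

    @staticmethod
    def tiny(**overrides) -> "ModelConfig":
        """Desk-scale preset: <2M parameters, trains on one CPU."""
        return ModelConfig(**{"input_size": (96, 96), "base_channels": 24,
                              "attention_heads": 2, **overrides})

    @staticmethod
    def full(**overrides) -> "ModelConfig":
        """Full-scale preset (ResNet-50-class width, deformable stages
        requested).  Provided for completeness; not exercised at desk
        scale."""
        return ModelConfig(**{
            "input_size": (544, 800) if "input_size" not in overrides else overrides["input_size"],
            "base_channels": 64,
            "use_deformable": True,
            **{k: v for k, v in overrides.items() if k != "input_size"},
        })


@dataclass
class DetectionOutput:
    """The four head maps (stride 4) plus the per-image SSR Delta vector.

    During training the fields are autodiff Tensors; ``detach()`` yields
    a plain-numpy copy for inference-side decoding.
    """

    heatmap: Tensor  # (N, 1, Hg, Wg), values in (0, 1)
    offset: Tensor  # (N, 2, Hg, Wg), values in (0, 1)
    axes: Tensor  # (N, 2, Hg, Wg), strictly positive, input pixels
    ssr_probs: Tensor  # (N, sum(S_k), Hg, Wg), per-stage softmax-normalized
    ssr_eta: Tensor  # (N, sum(S_k), Hg, Wg), in (-1, 1)
    ssr_delta: Tensor  # (N, K), in (-1, 1)
    heatmap_logits: Tensor | None = None  # pre-sigmoid map for the stable focal loss

    def detach(self) -> "DetectionOutput":
        return DetectionOutput(*(Tensor(f.data.copy()) for f in (
            self.heatmap, self.offset, self.axes, self.ssr_probs, self.ssr_eta, self.ssr_delta)))


class _ResBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng, mhsa_heads: int = 0, max_hw: int = 64):
        super().__init__()
        if mhsa_heads:
            self.conv1 = MHSA(in_ch, heads=mhsa_heads, max_hw=max_hw, rng=rng)
            self.proj1 = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
        else:
            self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
            self.proj1 = None
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.skip = None
        if stride != 1 or in_ch != out_ch:
            self.skip = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.skip_bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(x)
        if self.proj1 is not None:
            y = self.proj1(y)
        y = self.bn1(y).relu()
        y = self.bn2(self.conv2(y))
        s = x if self.skip is None else self.skip_bn(self.skip(x))
        return (y + s).relu()


class _DecoderBlock(Module):
    """Bilinear x2 -> 3x3 refine (or MHSA) -> concat skip -> 1x1 fuse."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng, use_mhsa: bool,
                 heads: int, max_hw: int):
        super().__init__()
        if use_mhsa:
            self.refine = MHSA(in_ch, heads=heads, max_hw=max_hw, rng=rng)
        else:
            self.refine = Conv2d(in_ch, in_ch, 3, rng=rng)
        self.refine_bn = BatchNorm2d(in_ch)
        self.fuse = Conv2d(in_ch + skip_ch, out_ch, 1, rng=rng)
        self.fuse_bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = upsample2x(x)
        x = self.refine_bn(self.refine(x)).relu()
        x = concat([x, skip], axis=1)
        return self.fuse_bn(self.fuse(x)).relu()


class _Head(Module):
    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, rng, bias_init: float = 0.0):
        super().__init__()
        self.conv1 = Conv2d(in_ch, mid_ch, 3, rng=rng)
        self.conv2 = Conv2d(mid_ch, out_ch, 1, rng=rng)
        # small output scale at init: heads start near their bias value
        self.conv2.weight.data *= 0.01
        self.conv2.bias.data[:] = bias_init

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu())


class EllipseNet(Module):
    """The full detector; see the module docstring for the layout."""

    def __init__(self, cfg: ModelConfig | None = None, ssr_cfg: SSRConfig | None = None):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        self.ssr_cfg = ssr_cfg or SSRConfig()
        rng = np.random.default_rng(self.cfg.seed)
        self._dropout_rng = np.random.default_rng(self.cfg.seed + 1)
        c = self.cfg.base_channels
        max_hw = max(self.cfg.input_size) // 4
        if self.cfg.use_deformable:
            log.warning("deformable convolution operator unavailable; falling back to standard convolution")

        widths = [c, c, 2 * c, 4 * c, 4 * c][: self.cfg.encoder_depth]
        self.stem = Conv2d(1, widths[0], 3, stride=2, rng=rng)
        self.stem_bn = BatchNorm2d(widths[0])
        self.enc_blocks: list[Module] = []
        in_ch = widths[0]
        for i, w_ch in enumerate(widths[1:], start=1):
            last = i == len(widths) - 1
            self.enc_blocks.append(
                _ResBlock(in_ch, w_ch, stride=2, rng=rng,
                          mhsa_heads=self.cfg.attention_heads if (self.cfg.use_mhsa and last) else 0,
                          max_hw=max_hw)
            )
            in_ch = w_ch
        # decoder: stride 32 -> 16 -> 8 -> 4, fusing encoder skips
        skips = widths[-2::-1]  # channels of skip features, deepest first
        self.dec_blocks: list[Module] = []
        dec_in = widths[-1]
        self._n_dec = 3
        for i in range(self._n_dec):
            out_ch = max(skips[i], c)
            self.dec_blocks.append(
                _DecoderBlock(dec_in, skips[i], out_ch, rng=rng, use_mhsa=self.cfg.use_mhsa,
                              heads=self.cfg.attention_heads, max_hw=max_hw)
            )
            dec_in = out_ch

        s = self.ssr_cfg
        self.head_heat = _Head(dec_in, c, 1, rng, bias_init=-2.19)  # sigmoid ~ 0.1 at init
        self.head_offset = _Head(dec_in, c, 2, rng)
        self.head_axes = _Head(dec_in, c, 2, rng, bias_init=15.0)  # softplus ~ 15 px at init
        self.head_probs = _Head(dec_in, c, s.total_bins, rng)
        self.head_eta = _Head(dec_in, c, s.total_bins, rng)
        self.head_eta.conv2.weight.data[:] = 0.0  # eta starts at 0: unshifted bins
        self.delta_fc = Linear(widths[-1], s.n_stages, rng=rng)
        self.delta_fc.weight.data[:] = 0.0  # Delta starts at 0: nominal bin widths

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, images: np.ndarray | Tensor) -> DetectionOutput:
        """Run the network on an (N, 1, H, W) batch normalized to [0, 1]."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        x = self.stem_bn(self.stem(x)).relu()
        skips = [x]
        for blk in self.enc_blocks:
            x = blk(x)
            skips.append(x)
        bottleneck = x
        if self.training and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (self._dropout_rng.random(x.shape) < keep).astype(np.float32) / keep
            x = x * Tensor(mask)
        feats = x
        for i, blk in enumerate(self.dec_blocks):
            feats = blk(feats, skips[-(i + 2)])

        heat_logits = self.head_heat(feats)
        heat = heat_logits.sigmoid()
        offset = self.head_offset(feats).sigmoid()
        axes = self.head_axes(feats).softplus()
        raw_probs = self.head_probs(feats)
        probs = concat(
            [softmax(sl, axis=1) for sl in self._split_stages(raw_probs)], axis=1
        )
        eta = self.head_eta(feats).tanh()
        pooled = bottleneck.mean(axis=(2, 3))  # (N, C)
        # 0.999 keeps 1 + Delta strictly positive under float32 tanh saturation
        delta = self.delta_fc(pooled).tanh() * 0.999
        for name, t in (("heatmap", heat), ("offset", offset), ("axes", axes),
                        ("ssr_probs", probs), ("ssr_eta", eta), ("ssr_delta", delta)):
            if not np.all(np.isfinite(t.data)):
                raise FloatingPointError(f"non-finite activations in head '{name}'")
        return DetectionOutput(heat, offset, axes, probs, eta, delta, heatmap_logits=heat_logits)

    def _split_stages(self, t: Tensor) -> list[Tensor]:
        out = []
        start = 0
        for s_k in self.ssr_cfg.stages:
            out.append(t[:, start : start + s_k])
            start += s_k
        return out


def build_model(cfg: ModelConfig | None = None, ssr_cfg: SSRConfig | None = None) -> EllipseNet:
    """Construct the detector and log its parameter count."""
    model = EllipseNet(cfg, ssr_cfg)
    log.info("built EllipseNet with %d parameters", model.count_parameters())
    return model
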