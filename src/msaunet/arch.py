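"""Multi-spatial-attention U-Net architectures.

Building blocks:

* ``SSEAttention`` — channel squeeze / spatial excitation: a 1x1 convolution
  collapses channels to one, a sigmoid turns it into a per-pixel gate that
  multiplicatively recalibrates the input.
* ``MSSAAttention`` — multi-scale spatial attention: per pooling factor,
  average-pool -> conv -> sigmoid -> upsample yields one attention map per
  scale; these are concatenated with the sSE gate and fused by a final
  conv + sigmoid into the applied weights.
* ``MSFEF`` — parallel convolutions with different kernel sizes, fused by
  concatenation + 1x1 convolution.
* ``MSABlock`` — MSFEF (one branch bank in V1, two parallel banks fused in
  V2) followed by spatial attention, wrapped in a residual shortcut (1x1
  projection when channel counts differ).

``build_model`` assembles a U-Net whose deepest stages (filling upward from
the bottleneck) are replaced by MSA blocks; the decoder uses
conv -> batch-norm -> ReLU stacks with residual shortcuts and bilinear
upsampling; a final 1x1 convolution + sigmoid emits per-pixel foreground
probabilities. ``n_msa_blocks=0`` yields the improved-U-Net baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "SSEAttention", "MSSAAttention", "MSFEF", "MSABlock",
           "UNet", "build_model", "predict_mask", "sse_attention", "mssa_attention",
           "msfef", "msa_block", "zero_parameters"]


@dataclass(frozen=True)
class ModelConfig:
    version: str = "V1"                       # "V1" or "V2"
    n_msa_blocks: int | None = None           # default: 3 for V1, 2 for V2
    attention: str = "MSSA"                   # "sSE" or "MSSA"
    kernel_bank_a: tuple[int, ...] = (3, 5, 7)
    kernel_bank_b: tuple[int, ...] = (5, 7, 9)
    base_channels: int = 32
    depth: int = 4                            # encoder stages (pooling steps)
    mssa_pool_factors: tuple[int, ...] = (2, 4)
    output_threshold: float = 0.5
    in_channels: int = 1

    def __post_init__(self):
        if self.version not in ("V1", "V2"):
            raise ValueError(f"version must be 'V1' or 'V2', got {self.version!r}")
        if self.attention not in ("sSE", "MSSA"):
            raise ValueError(f"attention must be 'sSE' or 'MSSA', got {self.attention!r}")
        n = self.resolved_n_msa_blocks
        if not 0 <= n <= 4:
            raise ValueError(f"n_msa_blocks must be in [0, 4], got {n}")
        if n > self.depth:
            raise ValueError(f"n_msa_blocks={n} exceeds depth={self.depth}")
        for k in (*self.kernel_bank_a, *self.kernel_bank_b):
            if k % 2 == 0 or k < 3:
                raise ValueError(f"kernel sizes must be odd and >= 3, got {k}")
        if not 0.0 < self.output_threshold < 1.0:
            raise ValueError(f"output_threshold must be in (0,1), got {self.output_threshold}")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")

    @property
    def resolved_n_msa_blocks(self) -> int:
        if self.n_msa_blocks is not None:
            return self.n_msa_blocks
        return 3 if self.version == "V1" else 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_msa_blocks"] = self.resolved_n_msa_blocks
        for key in ("kernel_bank_a", "kernel_bank_b", "mssa_pool_factors"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("kernel_bank_a", "kernel_bank_b", "mssa_pool_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ConvBNReLU(nn.Module):
    def __init__(self, cin: int, cout: int, k: int, rng):
        super().__init__()
        # bias is redundant (and receives zero gradient) before batch norm
        self.conv = nn.Conv2d(cin, cout, k, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class DoubleConv(nn.Module):
    """conv-BN-ReLU x2 with a residual shortcut (1x1 projection on mismatch)."""

    def __init__(self, cin: int, cout: int, rng, residual: bool = True):
        super().__init__()
        self.block1 = ConvBNReLU(cin, cout, 3, rng)
        self.block2 = ConvBNReLU(cout, cout, 3, rng)
        self.residual = residual
        self.proj = None
        if residual and cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block2(self.block1(x))
        if not self.residual:
            return out
        shortcut = self.proj(x) if self.proj is not None else x
        return out + shortcut


class SSEAttention(nn.Module):
    """Channel squeeze + spatial excitation gate."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.squeeze = nn.Conv2d(channels, 1, 1, bias=True, rng=rng)

    def weights(self, x: Tensor) -> Tensor:
        return self.squeeze(x).sigmoid()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        w = self.weights(x)
        return w, x * w


class MSSAAttention(nn.Module):
    """Multi-scale spatial attention.

    Each pooling factor contributes avg-pool -> 3x3 conv -> sigmoid ->
    bilinear upsample; the per-scale maps are concatenated with the sSE gate
    and fused by a final 3x3 conv + sigmoid. Inputs whose spatial dims are
    not divisible by a pooling factor are zero-padded and the result cropped.
    """

    def __init__(self, channels: int, pool_factors: tuple[int, ...] = (2, 4), rng=None):
        super().__init__()
        self.pool_factors = tuple(pool_factors)
        self.sse = SSEAttention(channels, rng)
        self.scale_convs = [nn.Conv2d(channels, 1, 3, bias=True, rng=rng)
                            for _ in self.pool_factors]
        self.fuse = nn.Conv2d(1 + len(self.pool_factors), 1, 3, bias=True, rng=rng)

    def _scale_map(self, x: Tensor, factor: int, conv: nn.Conv2d) -> Tensor:
        _, _, h, w = x.shape
        if factor > h or factor > w:
            raise ValueError(f"pool factor {factor} exceeds spatial dims {(h, w)}")
        ph = (-h) % factor
        pw = (-w) % factor
        xp = nn.pad2d(x, (0, ph), (0, pw)) if (ph or pw) else x
        pooled = nn.avg_pool2d(xp, factor)
        att = conv(pooled).sigmoid()
        up = nn.upsample_bilinear(att, (h + ph, w + pw))
        return _slice_hw(up, h, w) if (ph or pw) else up

    def scale_maps(self, x: Tensor) -> list[Tensor]:
        """The per-scale attention maps plus the sSE gate (diagnostics/tests)."""
        maps = [self.sse.weights(x)]
        maps.extend(self._scale_map(x, f, c)
                    for f, c in zip(self.pool_factors, self.scale_convs))
        return maps

    def weights(self, x: Tensor) -> Tensor:
        fused = nn.concat(self.scale_maps(x), axis=1)
        return self.fuse(fused).sigmoid()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        w = self.weights(x)
        return w, x * w


def _slice_hw(x: Tensor, h: int, w: int) -> Tensor:
    data = x.data[:, :, :h, :w]

    def backward(g, out):
        gx = np.zeros(x.shape, dtype=g.dtype)
        gx[:, :, :h, :w] = g
        return (gx,)

    return Tensor._make(data, (x,), backward)


class MSFEF(nn.Module):
    """Multi-scale feature extraction and fusion."""

    def __init__(self, cin: int, cout: int, kernels: tuple[int, ...], rng):
        super().__init__()
        for k in kernels:
            if k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd, got {k}")
        self.kernels = tuple(kernels)
        self.branches = [ConvBNReLU(cin, cout, k, rng) for k in self.kernels]
        self.fuse = ConvBNReLU(len(self.kernels) * cout, cout, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(nn.concat([b(x) for b in self.branches], axis=1))


class MSABlock(nn.Module):
    """MSFEF (+ parallel second bank in V2) -> spatial attention -> residual add."""

    def __init__(self, cin: int, cout: int, cfg: ModelConfig, rng):
        super().__init__()
        self.version = cfg.version
        self.msfef_a = MSFEF(cin, cout, cfg.kernel_bank_a, rng)
        self.msfef_b = None
        self.branch_fuse = None
        if cfg.version == "V2":
            self.msfef_b = MSFEF(cin, cout, cfg.kernel_bank_b, rng)
            self.branch_fuse = ConvBNReLU(2 * cout, cout, 1, rng)
        if cfg.attention == "MSSA":
            self.attention = MSSAAttention(cout, cfg.mssa_pool_factors, rng)
        else:
            self.attention = SSEAttention(cout, rng)
        self.proj = None
        if cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feat = self.msfef_a(x)
        if self.msfef_b is not None:
            feat = self.branch_fuse(nn.concat([feat, self.msfef_b(x)], axis=1))
        _, recal = self.attention(feat)
        shortcut = self.proj(x) if self.proj is not None else x
        return recal + shortcut


class _DecoderStage(nn.Module):
    def __init__(self, cin: int, skip_channels: int, cout: int, rng):
        super().__init__()
        self.up = nn.UpsampleBilinear(2)
        self.reduce = ConvBNReLU(cin, cout, 3, rng)
        self.block = DoubleConv(cout + skip_channels, cout, rng, residual=True)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.reduce(self.up(x))
        return self.block(nn.concat([x, skip], axis=1))


class UNet(nn.Module):
    """Encoder-decoder with skip connections and optional MSA stages.

    MSA blocks occupy the deepest stages, filling upward from the bottleneck:
    slot 0 is the bottleneck, slot 1 the deepest encoder stage, and so on.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = cfg
        n_msa = cfg.resolved_n_msa_blocks
        depth = cfg.depth
        enc_channels = [cfg.base_channels * 2 ** i for i in range(depth)]
        bottleneck_channels = cfg.base_channels * 2 ** depth

        def make_stage(cin, cout, slot_from_bottom):
            if slot_from_bottom < n_msa:
                return MSABlock(cin, cout, cfg, rng)
            return DoubleConv(cin, cout, rng, residual=False)

        self.encoder = []
        cin = cfg.in_channels
        for i, cout in enumerate(enc_channels):
            slot = depth - i  # bottleneck is slot 0; deepest encoder stage slot 1
            self.encoder.append(make_stage(cin, cout, slot))
            cin = cout
        self.pool = nn.MaxPool2d(2)
        self.bottleneck = make_stage(enc_channels[-1], bottleneck_channels, 0)

        self.decoder = []
        cin = bottleneck_channels
        for cout in reversed(enc_channels):
            self.decoder.append(_DecoderStage(cin, cout, cout, rng))
            cin = cout
        self.head = nn.Conv2d(cin, 1, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        _, _, h, w = x.shape
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(f"spatial dims {(h, w)} must be divisible by {div}")
        skips = []
        for stage in self.encoder:
            x = stage(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for stage, skip in zip(self.decoder, reversed(skips)):
            x = stage(x, skip)
        return self.head(x).sigmoid()


def build_model(cfg: ModelConfig, seed: int = 0) -> UNet:
    """Instantiate a (seeded) segmentation network from its config."""
    return UNet(cfg, seed=seed)


def predict_mask(model: UNet, img: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold the model's probability map into a binary mask.

    ``img`` may be (H, W), (C, H, W) or (N, C, H, W); a single image returns
    an (H, W) mask, a batch an (N, H, W) stack.
    """
    threshold = model.config.output_threshold if threshold is None else threshold
    arr = np.asarray(img, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
        single = True
    elif arr.ndim != 4:
        raise ValueError(f"unsupported input shape {arr.shape}")
    model.eval()
    probs = model(Tensor(arr)).data[:, 0]
    masks = (probs >= threshold).astype(np.uint8)
    return masks[0] if single else masks


# ---------------------------------------------------------------------------
# functional wrappers (operation-level API used by tests and notebooks)
# ---------------------------------------------------------------------------

def sse_attention(x: Tensor | np.ndarray, module: SSEAttention | None = None,
                  seed: int = 0) -> tuple[Tensor, Tensor]:
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    module = module or SSEAttention(x.shape[1], np.random.default_rng(seed))
    return module(x)


def mssa_attention(x: Tensor | np.ndarray, pool_factors: tuple[int, ...] = (2, 4),
                   module: MSSAAttention | None = None, seed: int = 0) -> tuple[Tensor, Tensor]:
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    module = module or MSSAAttention(x.shape[1], pool_factors, np.random.default_rng(seed))
    return module(x)


def msfef(x: Tensor | np.ndarray, kernels: tuple[int, ...], out_channels: int,
          module: MSFEF | None = None, seed: int = 0) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    module = module or MSFEF(x.shape[1], out_channels, kernels, np.random.default_rng(seed))
    return module(x)


def msa_block(x: Tensor | np.ndarray, cfg: ModelConfig, out_channels: int | None = None,
              module: MSABlock | None = None, seed: int = 0) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    cout = out_channels or x.shape[1]
    module = module or MSABlock(x.shape[1], cout, cfg, np.random.default_rng(seed))
    return module(x)


def zero_parameters(module: nn.Module) -> None:
    """Zero every trainable parameter (used to verify the residual identity)."""
    for p in module.parameters():
        p.data = np.zeros_like(p.data)
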