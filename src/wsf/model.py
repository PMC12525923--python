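"""Wheat Stoma Former (WSF): hierarchical transformer for stomatal segmentation.

The network follows the SegFormer template: an overlapping patch embedding
(7x7 conv, stride 4, padding 3) feeds a four-stage Mix-Transformer encoder
producing a feature pyramid at 1/4, 1/8, 1/16 and 1/32 of the input
resolution with per-stage channel widths (64/128/320/512 in the full
preset). Between encoder and decoder sits the cross-layer feature pyramid
transformer (CFPT): an FPN-style lateral fusion, channel reconstruction
(CR) of all levels onto the 1/16 grid, cross-layer channel attention (CCA)
over channel tokens and cross-layer spatial attention (CSA) over spatial
tokens, redistributed back to the four levels as a residual refinement.
The all-MLP decoder projects each level to a common width, upsamples to
the 1/4 grid, fuses through parallel MLP branches and a classifier head,
and bilinearly upsamples the class scores to full resolution, giving an
(H, W, K) logit tensor.

Images enter as (H, W, 3) intensity arrays in [0, 255]; they are scaled to
[-1, 1] before the patch embedding. Input height and width must be
divisible by 32 so the resolution ladder is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, bilinear_resize, concat, conv2d, upsample_nearest

__all__ = [
    "WSFConfig", "WSFModel", "Encoder", "CFPT", "Decoder",
    "encoder_forward", "cfpt_forward", "decoder_forward", "predict_mask",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class WSFConfig:
    """Architecture hyperparameters.

    ``preset="paper"`` is the full-size configuration; ``preset="tiny"``
    is a desk-scale model (16/32/64/128 channels, depth 1 per stage,
    64-channel decoder) for CPU training and tests.
    """

    patch_kernel: int = 7
    patch_stride: int = 4
    patch_padding: int = 3
    stage_channels: tuple[int, ...] = (64, 128, 320, 512)
    stage_depths: tuple[int, ...] = (2, 2, 2, 2)
    num_heads: tuple[int, ...] = (1, 2, 5, 8)
    sr_ratios: tuple[int, ...] = (8, 4, 2, 1)
    mlp_ratio: int = 4
    decoder_channels: int = 256
    decoder_branches: int = 2
    num_classes: int = 3
    preset: str = "paper"

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.stage_depths) != 4:
            raise ValueError("the encoder has exactly four stages")
        if self.decoder_channels <= 0:
            raise ValueError("decoder_channels must be positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    @classmethod
    def tiny(cls, num_classes: int = 3) -> "WSFConfig":
        return cls(stage_channels=(16, 32, 64, 128), stage_depths=(1, 1, 1, 1),
                   num_heads=(1, 1, 2, 4), mlp_ratio=2, decoder_channels=64,
                   num_classes=num_classes, preset="tiny")

    @classmethod
    def paper(cls, num_classes: int = 3) -> "WSFConfig":
        return cls(num_classes=num_classes, preset="paper")

    @classmethod
    def from_preset(cls, name: str, num_classes: int = 3) -> "WSFConfig":
        if name == "tiny":
            return cls.tiny(num_classes)
        if name == "paper":
            return cls.paper(num_classes)
        raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

class OverlapPatchEmbed(nn.Module):
    def __init__(self, in_ch, out_ch, kernel, stride, padding, rng):
        self.proj = nn.Conv2d(in_ch, out_ch, kernel, rng, stride=stride, padding=padding)
        self.norm = nn.LayerNorm(out_ch)

    def forward(self, x: Tensor):
        x = self.proj(x)
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        return self.norm(tokens), h, w


class SpatialReductionAttention(nn.Module):
    """Self-attention whose keys/values come from sr x sr token merges."""

    def __init__(self, dim, heads, sr_ratio, rng):
        if dim % heads:
            raise ValueError("dim must divide evenly over heads")
        self.dim, self.heads, self.sr = dim, heads, sr_ratio
        self.q = nn.Linear(dim, dim, rng)
        self.kv = nn.Linear(dim, 2 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        if sr_ratio > 1:
            self.reduce = nn.Linear(sr_ratio * sr_ratio * dim, dim, rng)
            self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, ntok, c = x.shape
        hd, dh = self.heads, c // self.heads
        q = self.q(x).reshape(n, ntok, hd, dh).transpose(0, 2, 1, 3)
        src = x
        if self.sr > 1:
            r = self.sr
            src = (x.reshape(n, h // r, r, w // r, r, c)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(n, (h // r) * (w // r), r * r * c))
            src = self.norm(self.reduce(src))
        m = src.shape[1]
        kv = self.kv(src).reshape(n, m, 2, hd, dh).transpose(2, 0, 3, 1, 4)
        k, v = kv[0], kv[1]
        att = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, ntok, c)
        return self.proj(out)


class MixFFN(nn.Module):
    """MLP with a 3x3 depthwise convolution for positional mixing."""

    def __init__(self, dim, hidden, rng):
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.dw = nn.Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, ntok, _ = x.shape
        y = self.fc1(x)
        hid = y.shape[-1]
        y = y.transpose(0, 2, 1).reshape(n, hid, h, w)
        y = self.dw(y)
        y = y.reshape(n, hid, ntok).transpose(0, 2, 1)
        return self.fc2(y.gelu())


class TransformerBlock(nn.Module):
    def __init__(self, dim, heads, sr_ratio, mlp_ratio, rng):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = SpatialReductionAttention(dim, heads, sr_ratio, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn = MixFFN(dim, dim * mlp_ratio, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = x + self.attn(self.norm1(x), h, w)
        return x + self.ffn(self.norm2(x), h, w)


class Encoder(nn.Module):
    """Four-stage hierarchical encoder producing the 1/4..1/32 pyramid."""

    def __init__(self, config: WSFConfig, rng: np.random.Generator):
        self.config = config
        chans = config.stage_channels
        self.embeds = [
            OverlapPatchEmbed(3, chans[0], config.patch_kernel, config.patch_stride,
                              config.patch_padding, rng),
            OverlapPatchEmbed(chans[0], chans[1], 3, 2, 1, rng),
            OverlapPatchEmbed(chans[1], chans[2], 3, 2, 1, rng),
            OverlapPatchEmbed(chans[2], chans[3], 3, 2, 1, rng),
        ]
        self.blocks = [
            [TransformerBlock(chans[i], config.num_heads[i], config.sr_ratios[i],
                              config.mlp_ratio, rng)
             for _ in range(config.stage_depths[i])]
            for i in range(4)
        ]
        self.norms = [nn.LayerNorm(c) for c in chans]

    def forward(self, x: Tensor) -> list[Tensor]:
        n = x.shape[0]
        pyramid = []
        for embed, blocks, norm in zip(self.embeds, self.blocks, self.norms):
            tokens, h, w = embed(x)
            for blk in blocks:
                tokens = blk(tokens, h, w)
            tokens = norm(tokens)
            x = tokens.transpose(0, 2, 1).reshape(n, tokens.shape[-1], h, w)
            pyramid.append(x)
        return pyramid


# ---------------------------------------------------------------------------
# CFPT
# ---------------------------------------------------------------------------

def _avg_pool(x: Tensor, factor: int) -> Tensor:
    if factor == 1:
        return x
    n, c, h, w = x.shape
    return x.reshape(n, c, h // factor, factor, w // factor, factor).mean(axis=(3, 5))


class CrossLayerChannelAttention(nn.Module):
    """Channel tokens attend to each other using pooled global descriptors.

    Each channel's token feature is its (mean, std) over space, so the
    attention map is independent of input resolution; values are the full
    per-channel spatial maps.
    """

    def __init__(self, channels, heads, rng):
        self.heads = heads
        self.embed = nn.Linear(2, 16 * heads, rng)
        self.q = nn.Linear(16 * heads, 16 * heads, rng)
        self.k = nn.Linear(16 * heads, 16 * heads, rng)
        self.proj = nn.Linear(channels, channels, rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        mu = flat.mean(axis=-1, keepdims=True)
        var = ((flat - mu) ** 2.0).mean(axis=-1, keepdims=True)
        desc = concat([mu, (var + 1e-6) ** 0.5], axis=-1)      # (n, c, 2)
        e = self.embed(desc)
        hd, dh = self.heads, e.shape[-1] // self.heads
        q = self.q(e).reshape(n, c, hd, dh).transpose(0, 2, 1, 3)
        k = self.k(e).reshape(n, c, hd, dh).transpose(0, 2, 1, 3)
        att = ((q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)).softmax(axis=-1)
        v = flat.reshape(n, 1, c, h * w)
        out = (att @ v).mean(axis=1)                            # (n, c, h*w)
        out = out.transpose(0, 2, 1)
        out = self.proj(out).transpose(0, 2, 1)
        return out.reshape(n, c, h, w)


class CrossLayerSpatialAttention(nn.Module):
    """Spatial tokens (one per grid cell of the merged pyramid) attend
    across the concatenated cross-layer channel features."""

    def __init__(self, channels, heads, rng):
        if channels % heads:
            raise ValueError("channels must divide over heads")
        self.heads = heads
        self.norm = nn.LayerNorm(channels)
        self.qkv = nn.Linear(channels, 3 * channels, rng)
        self.proj = nn.Linear(channels, channels, rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        tokens = self.norm(tokens)
        hd, dh = self.heads, c // self.heads
        qkv = self.qkv(tokens).reshape(n, h * w, 3, hd, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = ((q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)).softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, h * w, c)
        out = self.proj(out)
        return out.transpose(0, 2, 1).reshape(n, c, h, w)


class CFPT(nn.Module):
    """Cross-layer feature pyramid transformer (residual refinement).

    Pipeline: per-level lateral 1x1 convs align channels, a top-down pass
    fuses levels; channel reconstruction (CR) pools/unpools every fused
    level onto the 1/16 grid where the maps are concatenated; CCA and CSA
    refine the merged stack; the four channel groups are redistributed to
    their native grids through zero-initialized output convolutions and
    added to the input pyramid, so a freshly built (or explicitly zeroed)
    CFPT is exactly the identity.
    """

    # CR grid: index of the pyramid level whose resolution hosts attention
    CR_LEVEL = 2

    def __init__(self, config: WSFConfig, rng: np.random.Generator):
        chans = config.stage_channels
        lat = chans[1]
        self.lat_convs = [nn.Conv2d(c, lat, 1, rng) for c in chans]
        self.cca = CrossLayerChannelAttention(4 * lat, heads=2, rng=rng)
        self.csa = CrossLayerSpatialAttention(4 * lat, heads=2, rng=rng)
        self.out_convs = [nn.Conv2d(lat, c, 1, rng, zero_init=True) for c in chans]
        self.lat = lat

    def zero_attention_projections(self) -> None:
        """Test hook: zero every projection feeding the residual path."""
        for conv in self.out_convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        for mod in (self.cca.proj, self.csa.proj):
            mod.weight.data[:] = 0.0
            mod.bias.data[:] = 0.0

    def forward(self, pyramid: list[Tensor]) -> list[Tensor]:
        if len(pyramid) != 4:
            raise ValueError(f"CFPT expects a 4-level pyramid, got {len(pyramid)}")
        lats = [conv(f) for conv, f in zip(self.lat_convs, pyramid)]
        # top-down lateral fusion
        fused = [None] * 4
        fused[3] = lats[3]
        for i in (2, 1, 0):
            up = bilinear_resize(fused[i + 1], lats[i].shape[2], lats[i].shape[3])
            fused[i] = lats[i] + up
        # CR: move every level to the 1/16 grid
        ref_h, ref_w = fused[self.CR_LEVEL].shape[2], fused[self.CR_LEVEL].shape[3]
        cr = [
            _avg_pool(fused[0], 4),
            _avg_pool(fused[1], 2),
            fused[2],
            upsample_nearest(fused[3], 2),
        ]
        merged = concat(cr, axis=1)
        merged = merged + self.cca(merged)
        merged = merged + self.csa(merged)
        # redistribute: split channel groups, restore native grids, residual
        out = []
        for i, f in enumerate(pyramid):
            chunk = merged[:, i * self.lat : (i + 1) * self.lat]
            h, w = f.shape[2], f.shape[3]
            if (chunk.shape[2], chunk.shape[3]) != (h, w):
                chunk = bilinear_resize(chunk, h, w)
            out.append(f + self.out_convs[i](chunk))
        return out


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

class Decoder(nn.Module):
    """All-MLP decoder: unify channels, upsample to 1/4, fuse, classify."""

    def __init__(self, config: WSFConfig, rng: np.random.Generator):
        dc = config.decoder_channels
        self.config = config
        self.unify = [nn.Conv2d(c, dc, 1, rng) for c in config.stage_channels]
        self.branches = [nn.Conv2d(4 * dc, dc, 1, rng) for _ in range(config.decoder_branches)]
        self.fuse = nn.Conv2d(config.decoder_branches * dc, dc, 1, rng)
        self.classifier = nn.Conv2d(dc, config.num_classes, 1, rng)

    def forward(self, pyramid: list[Tensor], out_hw: tuple[int, int]) -> Tensor:
        for f, c in zip(pyramid, self.config.stage_channels):
            if f.shape[1] != c:
                raise ValueError(f"pyramid channels {f.shape[1]} != config {c}")
        h4, w4 = pyramid[0].shape[2], pyramid[0].shape[3]
        aligned = [bilinear_resize(conv(f), h4, w4) for conv, f in zip(self.unify, pyramid)]
        stack = concat(aligned, axis=1)
        branched = concat([br(stack).gelu() for br in self.branches], axis=1)
        fusedmap = self.fuse(branched).gelu()
        logits = self.classifier(fusedmap)
        return bilinear_resize(logits, out_hw[0], out_hw[1])


# ---------------------------------------------------------------------------
# full model + functional API
# ---------------------------------------------------------------------------

def _to_batch(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected (H, W, 3) or (N, H, W, 3) image array")
    return arr.transpose(0, 3, 1, 2) / 127.5 - 1.0


class WSFModel(nn.Module):
    """Encoder -> CFPT -> decoder, end to end."""

    def __init__(self, config: WSFConfig | None = None, seed: int = 0):
        self.config = config or WSFConfig()
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(self.config, rng)
        self.cfpt = CFPT(self.config, rng)
        self.decoder = Decoder(self.config, rng)

    def forward(self, images: np.ndarray | Tensor) -> Tensor:
        """Images (N, H, W, 3) in [0, 255] -> logits Tensor (N, K, H, W)."""
        if isinstance(images, Tensor):
            x = images
        else:
            x = Tensor(_to_batch(images))
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input {h}x{w} not divisible by 32; pad or crop first")
        pyramid = self.encoder(x)
        pyramid = self.cfpt(pyramid)
        return self.decoder(pyramid, (h, w))

    def predict_logits(self, image: np.ndarray) -> np.ndarray:
        """Single (H, W, 3) image -> (H, W, K) logit map."""
        out = self.forward(image[None] if image.ndim == 3 else image)
        return out.data[0].transpose(1, 2, 0)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Single image -> (H, W) label mask."""
        return predict_mask(self.predict_logits(image))


def encoder_forward(image: np.ndarray, config: WSFConfig, seed: int = 0,
                    model: WSFModel | None = None) -> list[np.ndarray]:
    """Run the encoder alone; returns the four feature maps as arrays."""
    model = model or WSFModel(config, seed=seed)
    x = Tensor(_to_batch(image))
    if x.shape[2] % 32 or x.shape[3] % 32:
        raise ValueError(f"input {x.shape[2]}x{x.shape[3]} not divisible by 32")
    return [f.data for f in model.encoder(x)]


def cfpt_forward(pyramid: list[np.ndarray], config: WSFConfig, seed: int = 0,
                 model: WSFModel | None = None) -> list[np.ndarray]:
    model = model or WSFModel(config, seed=seed)
    return [f.data for f in model.cfpt([Tensor(p) for p in pyramid])]


def decoder_forward(pyramid: list[np.ndarray], config: WSFConfig,
                    out_hw: tuple[int, int], seed: int = 0,
                    model: WSFModel | None = None) -> np.ndarray:
    """Returns the (H, W, K) logit map for a single-sample pyramid."""
    model = model or WSFModel(config, seed=seed)
    out = model.decoder([Tensor(p) for p in pyramid], out_hw)
    return out.data[0].transpose(1, 2, 0)


def predict_mask(logits: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the trailing class axis; ties -> lowest index."""
    logits = np.asarray(logits)
    if np.isnan(logits).any():
        raise ValueError("logits contain NaN")
    return np.argmax(logits, axis=-1).astype(np.uint8)


def save_checkpoint(model: WSFModel, path) -> None:
    """Serialize parameters plus the embedded config (npz)."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8).copy()
    np.savez(path, **state)


def load_checkpoint(path) -> WSFModel:
    data = np.load(path)
    cfg_raw = json.loads(bytes(data["__config__"]).decode())
    cfg_raw = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg_raw.items()}
    model = WSFModel(WSFConfig(**cfg_raw))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
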