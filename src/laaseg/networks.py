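"""The three trainable components: a ConvNeXt U-shape segmentation network,
a mask-reconstruction auto-encoder (same encoder family, no skips), and a
latent-space discriminator.

Layout of the encoder: a 4x4 stride-4 stem followed by four stages of
ConvNeXt blocks with layer-norm + 2x2 stride-2 downsamplers between stages;
all normalization in the encoder/decoder is layer normalization.  For an
input of side L the bottleneck latent is (dims[-1], L/32, L/32).

Explicit backward passes route gradients through skips and residuals; the
segmentation encoder additionally accepts an extra gradient injected at the
latent (from the adversarial and contrastive alignment terms).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import nn
from .config import NetworkConfig


class ConvNeXtBlock(nn.Module):
    """dw 7x7 conv -> LN (channel) -> 1x1 to 4*dim -> GELU -> 1x1 to dim,
    with a residual connection around the whole branch."""

    def __init__(self, dim: int, rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.dim = dim
        self.dwconv = nn.DepthwiseConv2d(dim, 7, rng=rng, dtype=dtype)
        self.norm = nn.LayerNormChannels(dim, dtype=dtype)
        self.pwconv1 = nn.Conv2d(dim, 4 * dim, 1, rng=rng, dtype=dtype)
        self.act = nn.GELU()
        self.pwconv2 = nn.Conv2d(4 * dim, dim, 1, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.dim:
            raise ValueError(f"ConvNeXtBlock(dim={self.dim}) got {x.shape[1]} channels")
        h = self.dwconv(x)
        h = self.norm(h)
        h = self.pwconv1(h)
        h = self.act(h)
        h = self.pwconv2(h)
        return x + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.pwconv2.backward(dy)
        d = self.act.backward(d)
        d = self.pwconv1.backward(d)
        d = self.norm.backward(d)
        d = self.dwconv.backward(d)
        return dy + d


class _Downsample(nn.Module):
    """LN followed by a 2x2 stride-2 convolution between stages."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.norm = nn.LayerNormChannels(cin, dtype=dtype)
        self.conv = nn.Conv2d(cin, cout, 2, stride=2, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.conv(self.norm(x))

    def backward(self, dy):
        return self.norm.backward(self.conv.backward(dy))


class Encoder(nn.Module):
    """ConvNeXt encoder: stem, four stages, per-stage skip taps, latent out."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator,
                 in_channels: int | None = None, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        cin = cfg.in_channels if in_channels is None else in_channels
        self.stem_conv = nn.Conv2d(cin, cfg.dims[0], 4, stride=4, rng=rng, dtype=dtype)
        self.stem_norm = nn.LayerNormChannels(cfg.dims[0], dtype=dtype)
        self.stages = [
            [ConvNeXtBlock(cfg.dims[s], rng, dtype) for _ in range(cfg.depths[s])]
            for s in range(4)
        ]
        self.downsamples = [
            _Downsample(cfg.dims[s], cfg.dims[s + 1], rng, dtype) for s in range(3)
        ]

    def _children(self):
        yield "stem_conv", self.stem_conv
        yield "stem_norm", self.stem_norm
        for s, stage in enumerate(self.stages):
            for i, blk in enumerate(stage):
                yield f"stages.{s}.{i}", blk
        for s, ds in enumerate(self.downsamples):
            yield f"downsamples.{s}", ds

    def forward(self, x: np.ndarray):
        """Returns (skips, latent): skips at strides 4/8/16, latent at 32."""
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {x.shape}")
        h = self.stem_norm(self.stem_conv(x))
        skips = []
        for s in range(4):
            for blk in self.stages[s]:
                h = blk(h)
            if s < 3:
                skips.append(h)
                h = self.downsamples[s](h)
        return skips, h

    def backward(self, dlatent: np.ndarray, dskips: list[np.ndarray] | None = None):
        d = dlatent
        for s in range(3, -1, -1):
            if s < 3:
                d = self.downsamples[s].backward(d)
                if dskips is not None:
                    d = d + dskips[s]
            for blk in reversed(self.stages[s]):
                d = blk.backward(d)
        return self.stem_conv.backward(self.stem_norm.backward(d))


class _ResBlock(nn.Module):
    """Two 3x3 convs with LN/GELU and a projection shortcut (BN-free)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1, rng=rng, init="he", dtype=dtype)
        self.norm1 = nn.LayerNormChannels(cout, dtype=dtype)
        self.act1 = nn.GELU()
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, rng=rng, init="he", dtype=dtype)
        self.norm2 = nn.LayerNormChannels(cout, dtype=dtype)
        self.proj = nn.Conv2d(cin, cout, 1, rng=rng, init="he", dtype=dtype) if cin != cout else None
        self.act_out = nn.GELU()

    def forward(self, x):
        h = self.act1(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        s = self.proj(x) if self.proj is not None else x
        return self.act_out(h + s)

    def backward(self, dy):
        d = self.act_out.backward(dy)
        dh = self.conv2.backward(self.norm2.backward(d))
        dh = self.conv1.backward(self.norm1.backward(self.act1.backward(dh)))
        ds = self.proj.backward(d) if self.proj is not None else d
        return dh + ds


class Decoder(nn.Module):
    """Three (x2 upsample -> [concat skip] -> residual block) stages from
    stride 32 back to stride 4, then a x4 upsample and 1x1 head."""

    def __init__(self, cfg: NetworkConfig, with_skips: bool, rng: np.random.Generator,
                 out_channels: int | None = None, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.cfg = cfg
        self.with_skips = with_skips
        dims = cfg.dims
        self.ups = [nn.UpsampleBilinear(2, dtype=dtype) for _ in range(3)]
        self.blocks = []
        for i in (2, 1, 0):                      # decode to stage-i resolution
            cin = dims[i + 1] + (dims[i] if with_skips else 0)
            self.blocks.append(_ResBlock(cin, dims[i], rng, dtype))
        self.final_up = nn.UpsampleBilinear(4, dtype=dtype)
        cout = cfg.num_classes if out_channels is None else out_channels
        self.head = nn.Conv2d(dims[0], cout, 1, rng=rng, init="he", dtype=dtype)
        self._skip_channels = None

    def forward(self, latent: np.ndarray, skips: list[np.ndarray] | None = None):
        if self.with_skips:
            if skips is None or len(skips) != 3:
                raise ValueError("decoder with skips needs the 3 encoder skip maps")
        h = latent
        for j, i in enumerate((2, 1, 0)):
            h = self.ups[j](h)
            if self.with_skips:
                skip = skips[i]
                if skip.shape[2:] != h.shape[2:]:
                    raise ValueError(f"skip/upsample spatial mismatch at stage {i}: "
                                     f"{skip.shape} vs {h.shape}")
                h = np.concatenate([h, skip], axis=1)
            h = self.blocks[j](h)
        h = self.final_up(h)
        return self.head(h)

    def backward(self, dy: np.ndarray):
        """Returns (dlatent, dskips); dskips is None without skip connections."""
        d = self.head.backward(dy)
        d = self.final_up.backward(d)
        dskips: list | None = [None, None, None] if self.with_skips else None
        for j, i in zip((2, 1, 0), (0, 1, 2)):
            d = self.blocks[j].backward(d)
            if self.with_skips:
                n_up = d.shape[1] - self.cfg.dims[i]
                dskips[i] = d[:, n_up:]
                d = d[:, :n_up]
            d = self.ups[j].backward(d)
        return d, dskips


class SegNetwork(nn.Module):
    """U-shape segmentation network: ConvNeXt encoder + skip decoder."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None,
                 dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng, dtype=dtype)
        self.decoder = Decoder(cfg, with_skips=True, rng=rng, dtype=dtype)
        self._skips = None

    def forward(self, image: np.ndarray):
        """image (N,1,H,W) in [0,1] -> (logits (N,C,H,W), latent (N,dims[-1],H/32,W/32)).

        Inputs are standardized to [-1, 1] internally; a constant-zero
        background would otherwise give the stem layer-norm zero-variance
        vectors, an ill-conditioned point.
        """
        skips, latent = self.encoder(2.0 * np.asarray(image) - 1.0)
        self._skips = skips
        logits = self.decoder(latent, skips)
        return logits, latent

    def backward(self, dlogits: np.ndarray, dlatent_extra: np.ndarray | None = None):
        dlatent, dskips = self.decoder.backward(dlogits)
        if dlatent_extra is not None:
            dlatent = dlatent + dlatent_extra
        return self.encoder.backward(dlatent, dskips)


class ReconNetwork(nn.Module):
    """Mask auto-encoder: ConvNeXt encoder, skip-free decoder, and a
    clipped-linear head producing reconstructions in [0, 1].

    Without skip connections the decoder can only read the bottleneck, which
    forces the latent to carry the full shape prior.  The head is a
    1-channel 1x1 convolution followed by ``clip(., 0, 1)`` with a
    straight-through gradient; under the L1 objective this avoids the
    majority-class saturation collapse a sigmoid head falls into on
    strongly class-imbalanced masks.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None,
                 dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng, in_channels=1, dtype=dtype)
        self.decoder = Decoder(cfg, with_skips=False, rng=rng, out_channels=1, dtype=dtype)
        self.out_act = nn.HardClip()

    def forward(self, mask: np.ndarray, validate: bool = True):
        """mask (N,1,H,W) in {0,1} -> (recon (N,1,H,W) in [0,1], latent)."""
        if validate:
            u = np.unique(mask)
            if not np.all(np.isin(u, (0, 1))):
                raise ValueError(f"reconstruction input must be a binary mask, found {u[:10]}")
        recon = self.out_act(self.decoder(self.encode(mask), None))
        return recon, self._latent

    def encode(self, mask: np.ndarray) -> np.ndarray:
        """Latent only (used as the frozen shape-prior encoder).

        The {0,1} mask is standardized to {-1,+1} before the stem so the
        background is not a zero-variance input to the layer norm.
        """
        x = np.asarray(mask, dtype=self.encoder.stem_conv.weight.data.dtype)
        _, latent = self.encoder(2.0 * x - 1.0)
        self._latent = latent
        return latent

    def backward(self, drecon: np.ndarray):
        d = self.out_act.backward(drecon)
        dlatent, _ = self.decoder.backward(d)
        return self.encoder.backward(dlatent, None)


class Discriminator(nn.Module):
    """Latent-space discriminator: five 3x3 stride-1 conv layers, each
    followed by LeakyReLU(0.2) and batch normalization, then a single FC
    layer to one raw score (no squashing; least-squares objective)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None,
                 latent_spatial: tuple[int, int] | None = None, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = cfg.dims[-1]
        widths = [c, max(c // 2, 8), max(c // 4, 8), max(c // 8, 8), max(c // 8, 8)]
        layers: list[nn.Module] = []
        prev = c
        for width in widths:
            layers.append(nn.Conv2d(prev, width, 3, padding=1, rng=rng, init="he", dtype=dtype))
            layers.append(nn.LeakyReLU(0.2))
            layers.append(nn.BatchNorm2d(width, dtype=dtype))
            prev = width
        self.convs = layers
        self.flatten = nn.Flatten()
        hs, ws = latent_spatial if latent_spatial is not None else cfg.latent_spatial()
        self.fc = nn.Linear(widths[-1] * hs * ws, 1, rng=rng, init="he", dtype=dtype)
        self.latent_channels = c

    def _children(self):
        for i, layer in enumerate(self.convs):
            yield f"convs.{i}", layer
        yield "flatten", self.flatten
        yield "fc", self.fc

    def forward(self, latent: np.ndarray) -> np.ndarray:
        """latent (N, dims[-1], h, w) -> (N,) raw scores."""
        if latent.shape[1] != self.latent_channels:
            raise ValueError(f"discriminator expects {self.latent_channels} latent channels, "
                             f"got {latent.shape[1]}")
        h = latent
        for layer in self.convs:
            h = layer(h)
        return self.fc(self.flatten(h))[:, 0]

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        d = self.fc.backward(np.asarray(dscores).reshape(-1, 1))
        d = self.flatten.backward(d)
        for layer in reversed(self.convs):
            d = layer.backward(d)
        return d


def pool_latent(latent: np.ndarray) -> np.ndarray:
    """Global-average-pool a latent map and L2-normalize per sample.

    An all-zero latent has no direction; it is returned as the zero vector
    with a warning (cosine similarity is undefined for it).
    """
    vec, _ = pool_latent_with_grad(latent)
    return vec


def pool_latent_with_grad(latent: np.ndarray):
    """Returns (unit vectors (N, C), backward closure dvec -> dlatent)."""
    x = np.asarray(latent)
    if x.ndim == 3:
        x = x[None]
    n, c, h, w = x.shape
    raw = x.mean(axis=(2, 3))                       # (N, C)
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    degenerate = norms[:, 0] == 0
    if degenerate.any():
        warnings.warn("all-zero latent pooled: returning zero vector (degenerate)",
                      RuntimeWarning, stacklevel=2)
    safe = np.where(norms == 0, 1.0, norms)
    vec = raw / safe
    vec[degenerate] = 0.0

    def backward(dvec: np.ndarray) -> np.ndarray:
        # d/draw of raw/||raw||: (dvec - vec (vec . dvec)) / ||raw||
        inner = (vec * dvec).sum(axis=1, keepdims=True)
        draw = (dvec - vec * inner) / safe
        draw[degenerate] = 0.0
        return np.broadcast_to(draw[:, :, None, None], (n, c, h, w)) / (h * w)

    if latent.ndim == 3:
        return vec[0], backward
    return vec, backward


def count_layer_types(module: nn.Module) -> dict[str, int]:
    """Census of layer classes in a network (architecture audits)."""
    counts: dict[str, int] = {}

    def visit(m: nn.Module):
        counts[type(m).__name__] = counts.get(type(m).__name__, 0) + 1
        for _, child in m._children():
            visit(child)

    visit(module)
    return counts
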