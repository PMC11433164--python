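"""The five 3D super-resolution architectures.

All networks map a single-channel volume to a single-channel volume of
identical dims (inputs are pre-interpolated onto the reference grid, so
no architecture changes the spatial size end to end).

Widths that the architecture descriptions leave open were calibrated
once against the published trainable-parameter counts and are frozen as
defaults:

======================  ===========  ==============================
architecture            parameters   calibrated defaults
======================  ===========  ==============================
rrdb                    246,865      LFF width 12, fusion 36->72->22
spsr                    493,754      two rrdb trunks + 1x1 fusion
unet / unetmss          5,418,563    depth 2, base width 64
shuffleunet             106,957,377  hidden widths 67/128/266/546
======================  ===========  ==============================

The RRDB here consists of a shallow feature extractor (3x3x3 conv to 4
feature maps) feeding three densely connected blocks (6 conv layers at
growth rate 12, each block closed by a 1x1x1 local feature fusion back
to 12 channels).  The block outputs are concatenated and fused by 1x1x1
and 3x3x3 convolutions down to the output channel; the input is added
back globally (residual reconstruction).

SPSR runs two such trunks in parallel — one on the image and one on its
Sobel gradient-magnitude map.  The gradient trunk ends in a 1x1x1 head
predicting the high-resolution gradient map (supervised by a gradient
loss); both trunks' features are concatenated and fused into the image
estimate.

UNet is a contracting/expanding encoder-decoder with channel doubling,
max-pooling, transposed-convolution upsampling and skip concatenation.
UNetMSS shares the identical trunk and additionally supervises the two
deepest decoder scales through 1x1x1 heads; both classes carry the
heads so their parameter counts coincide.

ShuffleUNet replaces pooling/up-convolution by pixel unshuffle/shuffle:
each contraction block is double conv -> convolutional decomposition
(four parallel 3x3x3 convolutions, each producing a quarter of the
channels) -> pixel unshuffle of one stream; the other three streams are
forwarded as skips.  Expansion blocks mirror this with pixel shuffle,
decomposition, skip addition, concatenation and double conv.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from voxsr import nn
from voxsr.errors import ParameterError
from voxsr.nn import functional as F
from voxsr.nn.tensor import Tensor, concat

ARCHITECTURES = ("rrdb", "spsr", "unet", "unetmss", "shuffleunet")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one network; parameter counts are a pure
    function of this record."""

    name: str
    # rrdb / spsr
    rrdb_blocks: int = 3
    layers_per_block: int = 6
    growth_rate: int = 12
    initial_features: int = 4
    rrdb_fusion_width: int = 72
    rrdb_preout_width: int = 22
    # unet / unetmss
    unet_depth: int = 2
    unet_base_width: int = 64
    mss_scales: int = 3
    # shuffleunet
    shuffle_factor: int = 2
    shuffle_base_width: int = 64
    shuffle_hidden_widths: tuple = (67, 128, 266, 546)

    def __post_init__(self):
        if self.name not in ARCHITECTURES:
            raise ParameterError(f"unknown architecture {self.name!r}; choose from {ARCHITECTURES}")
        if self.mss_scales < 1 or self.mss_scales > self.unet_depth + 1:
            raise ParameterError("mss_scales must be in 1..unet_depth+1")


# ------------------------------------------------------------------ RRDB

class DenseBlock(nn.Module):
    """Densely connected conv layers closed by a 1x1x1 local feature fusion."""

    def __init__(self, cin: int, n_layers: int, growth: int):
        self.layers = [
            nn.ConvBlock(cin + i * growth, growth, 3) for i in range(n_layers)
        ]
        self.lff = nn.Conv3d(cin + n_layers * growth, growth, 1)
        self.site = nn.PerturbationSite("block")

    def forward(self, x: Tensor) -> Tensor:
        cascade = [x]
        for layer in self.layers:
            inp = cascade[0] if len(cascade) == 1 else concat(cascade)
            cascade.append(layer(inp))
        return self.site(self.lff(concat(cascade)))


class RRDBTrunk(nn.Module):
    """Shallow extractor + parallel dense blocks + fusion, ending at
    ``rrdb_preout_width`` feature channels."""

    def __init__(self, spec: ArchitectureSpec):
        f0 = spec.initial_features
        g = spec.growth_rate
        self.shallow = nn.ConvBlock(1, f0, 3)
        self.blocks = [
            DenseBlock(f0, spec.layers_per_block, g) for _ in range(spec.rrdb_blocks)
        ]
        self.fuse1 = nn.ConvBlock(spec.rrdb_blocks * g, spec.rrdb_fusion_width, 1)
        self.fuse3 = nn.ConvBlock(spec.rrdb_fusion_width, spec.rrdb_preout_width, 3)

    def forward(self, x: Tensor) -> Tensor:
        s = self.shallow(x)
        outs = [blk(s) for blk in self.blocks]
        return self.fuse3(self.fuse1(concat(outs)))


class RRDBNet(nn.Module):
    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        self.trunk = RRDBTrunk(spec)
        self.out = nn.Conv3d(spec.rrdb_preout_width, 1, 1)

    @property
    def sites(self):
        return {
            f"block{i + 1}": blk.site for i, blk in enumerate(self.trunk.blocks)
        }

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.trunk(x)) + x

    def infer(self, x: Tensor) -> Tensor:
        return self.forward(x)


class SPSRNet(nn.Module):
    """Structure-preserving SR: image trunk + gradient trunk + fusion."""

    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        self.image_trunk = RRDBTrunk(spec)
        self.gradient_trunk = RRDBTrunk(spec)
        self.gradient_head = nn.Conv3d(spec.rrdb_preout_width, 1, 1)
        self.fusion = nn.Conv3d(2 * spec.rrdb_preout_width, 1, 1)
        self.refine = nn.Conv3d(1, 1, 1)

    @property
    def sites(self):
        return {}

    def forward(self, x: Tensor):
        grad_in = F.sobel_magnitude(x)
        fi = self.image_trunk(x)
        fg = self.gradient_trunk(grad_in)
        sr = self.refine(self.fusion(concat([fi, fg]))) + x
        grad_pred = self.gradient_head(fg)
        return sr, grad_pred

    def infer(self, x: Tensor) -> Tensor:
        return self.forward(x)[0]


# ------------------------------------------------------------------ UNet

class UNetTrunk(nn.Module):
    """Shared UNet/UNetMSS trunk with MSS heads and perturbation sites."""

    def __init__(self, spec: ArchitectureSpec):
        d = spec.unet_depth
        w = spec.unet_base_width
        chans = [w * 2 ** i for i in range(d + 1)]
        self.depth = d
        self.enc = []
        cin = 1
        for c in chans[:-1]:
            self.enc.append(nn.DoubleConv(cin, c, c))
            cin = c
        self.bottleneck = nn.DoubleConv(cin, chans[-1], chans[-1])
        self.ups = []
        self.dec = []
        cin = chans[-1]
        for c in reversed(chans[:-1]):
            self.ups.append(nn.ConvTranspose3d(cin, c))
            self.dec.append(nn.DoubleConv(2 * c, c, c))
            cin = c
        self.final = nn.Conv3d(chans[0], 1, 1)
        # MSS heads on the deepest mss_scales-1 decoder scales
        # (bottleneck counts as the deepest scale)
        n_aux = spec.mss_scales - 1
        aux_chans = ([chans[-1]] + list(reversed(chans[1:-1])))[:n_aux]
        self.mss_heads = [nn.Conv3d(c, 1, 1) for c in aux_chans]
        self.enc_sites = [nn.PerturbationSite(f"enc{i + 1}") for i in range(d)]
        self.bottleneck_site = nn.PerturbationSite("bottleneck")
        self.dec_sites = [nn.PerturbationSite(f"dec{i + 1}") for i in range(d)]

    def forward(self, x: Tensor):
        skips = []
        h = x
        for enc, site in zip(self.enc, self.enc_sites):
            e = site(enc(h))
            skips.append(e)
            h = F.maxpool3d(e)
        h = self.bottleneck_site(self.bottleneck(h))
        scale_feats = [h]  # deepest first
        for up, dec, site, skip in zip(
            self.ups, self.dec, self.dec_sites, reversed(skips)
        ):
            h = site(dec(concat([skip, up(h)])))
            scale_feats.append(h)
        full = self.final(h)
        # aux outputs: deepest decoder scales, excluding the full scale
        aux = [head(feat) for head, feat in zip(self.mss_heads, scale_feats)]
        return full, aux


class UNet(nn.Module):
    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        self.trunk = UNetTrunk(spec)

    @property
    def sites(self):
        t = self.trunk
        names = {}
        for i, s in enumerate(t.enc_sites):
            names[f"enc{i + 1}"] = s
        names["bottleneck"] = t.bottleneck_site
        for i, s in enumerate(t.dec_sites):
            names[f"dec{i + 1}"] = s
        return names

    def forward(self, x: Tensor) -> Tensor:
        full, _ = self.trunk(x)
        return full

    def infer(self, x: Tensor) -> Tensor:
        return self.forward(x)


class UNetMSS(UNet):
    """UNet trained with multi-scale supervision: forward exposes the
    full-scale output plus the auxiliary lower-scale outputs."""

    def forward(self, x: Tensor):
        full, aux = self.trunk(x)
        return [full] + aux

    def infer(self, x: Tensor) -> Tensor:
        return self.trunk(x)[0]


# ------------------------------------------------------------ ShuffleUNet

class ContractionBlock(nn.Module):
    def __init__(self, cin: int, hidden: int, c: int, r: int):
        self.dc = nn.DoubleConv(cin, hidden, c)
        self.decomp = [nn.ConvBlock(c, c // 4, 3) for _ in range(4)]
        self.r = r

    def forward(self, x: Tensor):
        y = self.dc(x)
        streams = [conv(y) for conv in self.decomp]
        down = F.pixel_unshuffle3(streams[3], self.r)
        return streams[:3], down


class ExpansionBlock(nn.Module):
    def __init__(self, pin: int, c: int, r: int):
        self.decomp = [nn.ConvBlock(pin, c // 4, 3) for _ in range(4)]
        self.dc = nn.DoubleConv(c, c, c)
        self.r = r

    def forward(self, x: Tensor, skips):
        up = F.pixel_shuffle3(x, self.r)
        streams = [conv(up) for conv in self.decomp]
        merged = [streams[i] + skips[i] for i in range(3)] + [streams[3]]
        return self.dc(concat(merged))


class ShuffleUNet(nn.Module):
    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        w = spec.shuffle_base_width
        r = spec.shuffle_factor
        cs = [w, 2 * w, 4 * w, 8 * w]
        hs = list(spec.shuffle_hidden_widths)
        ins = [1] + [2 * c for c in cs[:-1]]
        self.contraction = [
            ContractionBlock(i, h, c, r) for i, h, c in zip(ins, hs, cs)
        ]
        latent_w = 2 * cs[-1]
        self.latent = nn.DoubleConv(2 * cs[-1], latent_w, latent_w)
        pins = [latent_w // r ** 3] + [c // r ** 3 for c in reversed(cs[1:])]
        self.expansion = [
            ExpansionBlock(p, c, r) for p, c in zip(pins, reversed(cs))
        ]
        self.out = nn.Conv3d(cs[0], 1, 1)

    @property
    def sites(self):
        return {}

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for blk in self.contraction:
            s, h = blk(h)
            skips.append(s)
        h = self.latent(h)
        for blk, s in zip(self.expansion, reversed(skips)):
            h = blk(h, s)
        return self.out(h)

    def infer(self, x: Tensor) -> Tensor:
        return self.forward(x)


# ------------------------------------------------------------- factories

_CLASSES = {
    "rrdb": RRDBNet,
    "spsr": SPSRNet,
    "unet": UNet,
    "unetmss": UNetMSS,
    "shuffleunet": ShuffleUNet,
}


def build_model(spec: ArchitectureSpec) -> nn.Module:
    """Instantiate the architecture described by ``spec`` (weights zeroed;
    call :func:`voxsr.nn.init_xavier_uniform` or load a checkpoint)."""
    return _CLASSES[spec.name](spec)


def count_parameters(model: nn.Module) -> int:
    """Exact number of independent trainable scalars."""
    return model.count_parameters()


def disarm_all_sites(model: nn.Module):
    for site in getattr(model, "sites", {}).values():
        site.disarm()


# ------------------------------------------------------------ checkpoints

def save_checkpoint(model: nn.Module, path: str, extra: dict | None = None) -> str:
    """Single-archive checkpoint: weights + ArchitectureSpec + extra config."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    meta = {"architecture": asdict(model.spec), "extra": extra or {}}
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())
    return path


def load_checkpoint(path: str):
    """Rebuild the model from a checkpoint; returns (model, extra)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arch = dict(meta["architecture"])
        arch["shuffle_hidden_widths"] = tuple(arch["shuffle_hidden_widths"])
        spec = ArchitectureSpec(**arch)
        model = build_model(spec)
        params = dict(model.named_parameters())
        for name in params:
            params[name].data[...] = npz[name]
    return model, meta["extra"]
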