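"""Network function families: U-Nets, cascade, CVAE shape prior, classifier.

Two stylistic families are used, matching the two pipeline stages:

* anatomical family — convolution → instance norm → leaky ReLU (slope
  0.01), down-sampling by strided convolutions;
* pathological family — convolution → batch norm → ReLU, down-sampling by
  max-pooling; its bottleneck optionally feeds a 2-class patient head via
  global average pooling.

Up-sampling is nearest-neighbour repetition followed by a convolution.
The CVAE encodes one-hot label volumes to a low-dimensional latent code
and decodes a per-class probability grid; a frozen pretrained instance
serves as the shape prior for the inclusion constraint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, concat, maxpool2, softmax, upsample2
from ._layers import BatchNorm, Conv, InstanceNorm, Linear, Module

CHECKPOINT_VERSION = 1


class ShapeError(ValueError):
    """Input spatial shape incompatible with the network's pooling depth."""


@dataclass
class NetConfig:
    """Architecture hyperparameters for :func:`build_net`."""

    kind: str = "unet3d"        # unet2d | unet3d | cascade | cvae | classifier
    depth: int = 3              # pooling levels
    base_channels: int = 16
    norm: str = "instance"      # instance | batch
    activation: str = "leaky_relu"  # leaky_relu | relu
    downsample: str = "strided_conv"  # strided_conv | max_pool
    out_classes: int = 3
    in_channels: int = 1
    leakiness: float = 0.01
    latent_dim: int = 64        # cvae only
    input_shape: tuple | None = None  # cvae only (spatial dims)
    kl_weight: float = 1e-3     # cvae only
    with_classifier: bool = False

    def validate(self):
        if self.kind not in ("unet2d", "unet3d", "cascade", "cvae",
                             "classifier"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.depth < 1 or self.base_channels < 1 or self.out_classes < 1:
            raise ValueError("depth/base_channels/out_classes must be >= 1")
        if self.kind == "cvae" and self.input_shape is None:
            raise ValueError("cvae needs input_shape")
        return self


def anatomical_config(**kw) -> NetConfig:
    """Anatomical-family preset: instance norm, leaky ReLU, strided convs."""
    kw.setdefault("kind", "unet3d")
    kw.setdefault("out_classes", 3)
    cfg = NetConfig(norm="instance", activation="leaky_relu",
                    downsample="strided_conv", **kw)
    return cfg.validate()


def pathological_config(**kw) -> NetConfig:
    """Pathological-family preset: batch norm, ReLU, max-pooling."""
    kw.setdefault("kind", "unet3d")
    kw.setdefault("out_classes", 4)
    kw.setdefault("in_channels", 2)
    kw.setdefault("with_classifier", True)
    cfg = NetConfig(norm="batch", activation="relu", downsample="max_pool",
                    **kw)
    return cfg.validate()


def _act(x: Tensor, cfg: NetConfig) -> Tensor:
    if cfg.activation == "leaky_relu":
        return x.leaky_relu(cfg.leakiness)
    return x.relu()


def _norm_layer(c: int, cfg: NetConfig) -> Module:
    return InstanceNorm(c) if cfg.norm == "instance" else BatchNorm(c)


class ConvBlock(Module):
    """Two (conv → norm → activation) stages."""

    def __init__(self, cin, cout, cfg, nd, rng):
        super().__init__()
        self.cfg = cfg
        self.c1 = Conv(cin, cout, 3, nd=nd, rng=rng)
        self.n1 = _norm_layer(cout, cfg)
        self.c2 = Conv(cout, cout, 3, nd=nd, rng=rng)
        self.n2 = _norm_layer(cout, cfg)

    def forward(self, x):
        x = _act(self.n1(self.c1(x)), self.cfg)
        return _act(self.n2(self.c2(x)), self.cfg)


class UNet(Module):
    """Encoder–decoder with skip connections and a softmax head."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.nd = 2 if cfg.kind == "unet2d" else 3
        ch = [cfg.base_channels * 2 ** l for l in range(cfg.depth + 1)]
        self.enc = []
        cin = cfg.in_channels
        for l in range(cfg.depth):
            self.enc.append(ConvBlock(cin, ch[l], cfg, self.nd, rng))
            cin = ch[l]
        self.downs = []
        for l in range(cfg.depth):
            if cfg.downsample == "strided_conv":
                self.downs.append(Conv(ch[l], ch[l], 3, stride=2, nd=self.nd,
                                       rng=rng))
            else:
                self.downs.append(None)  # max-pool, parameter-free
        self.bottleneck = ConvBlock(ch[cfg.depth - 1], ch[cfg.depth], cfg,
                                    self.nd, rng)
        self.up_convs = [Conv(ch[l + 1], ch[l], 3, nd=self.nd, rng=rng)
                         for l in range(cfg.depth)]
        self.dec = [ConvBlock(2 * ch[l], ch[l], cfg, self.nd, rng)
                    for l in range(cfg.depth)]
        self.head = Conv(ch[0], cfg.out_classes, 1, padding=0, nd=self.nd,
                         rng=rng)
        self.class_head = (Linear(ch[cfg.depth], 2, rng=rng)
                           if cfg.with_classifier else None)

    def _check_shape(self, x):
        spatial = x.shape[2:]
        f = 2 ** self.cfg.depth
        bad = [s for s in spatial if s % f]
        if bad:
            need = tuple((-s) % f for s in spatial)
            raise ShapeError(
                f"spatial shape {spatial} not divisible by 2^depth={f}; "
                f"pad by {need}")

    def forward(self, x, return_scores: bool = False):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        self._check_shape(x)
        skips = []
        for l in range(self.cfg.depth):
            x = self.enc[l](x)
            skips.append(x)
            x = (self.downs[l](x) if self.downs[l] is not None
                 else maxpool2(x))
            if self.downs[l] is not None:
                x = _act(x, self.cfg)
        x = self.bottleneck(x)
        bottleneck = x
        for l in reversed(range(self.cfg.depth)):
            x = self.up_convs[l](upsample2(x))
            x = concat([skips[l], x], axis=1)
            x = self.dec[l](x)
        probs = softmax(self.head(x), axis=1)
        if not return_scores:
            return probs
        scores = None
        if self.class_head is not None:
            gap = bottleneck.mean(axis=tuple(range(2, bottleneck.ndim)))
            scores = self.class_head(gap)
        return probs, scores


class CascadeUNet(Module):
    """Coarse-to-fine pair: a U-Net on a 2× down-sampled volume whose
    up-sampled class probabilities condition a full-resolution U-Net."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        from dataclasses import replace
        self.cfg = cfg
        base = replace(cfg, kind="unet3d")
        self.coarse = UNet(base, rng)
        fine_cfg = replace(base, in_channels=cfg.in_channels + cfg.out_classes)
        self.fine = UNet(fine_cfg, rng)

    def forward(self, x, return_scores: bool = False):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        d = x.data
        n, c = d.shape[:2]
        half = tuple(s // 2 for s in d.shape[2:])
        lo = d.reshape(n, c, half[0], 2, half[1], 2, half[2], 2
                       ).mean(axis=(3, 5, 7))
        coarse_probs = self.coarse(Tensor(lo))
        up = coarse_probs
        up = upsample2(up)
        return self.fine(concat([x, up], axis=1), return_scores=return_scores)


class ConvClassifier(Module):
    """Small strided-conv encoder + GAP + linear 2-class scorer."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ch = [cfg.base_channels * 2 ** l for l in range(cfg.depth)]
        self.convs = []
        cin = cfg.in_channels
        for c in ch:
            self.convs.append(Conv(cin, c, 3, stride=2, nd=3, rng=rng))
            cin = c
        self.fc = Linear(ch[-1], 2, rng=rng)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        for conv in self.convs:
            x = conv(x).relu()
        gap = x.mean(axis=tuple(range(2, x.ndim)))
        return self.fc(gap)


class CVAE(Module):
    """Convolutional variational autoencoder over one-hot label volumes.

    Two stride-2 encoding stages, a diagonal-Gaussian latent of
    ``latent_dim`` and a mirrored decoder ending in a per-voxel softmax.
    Decoding from the latent mean is deterministic; sampling uses the
    reparameterisation trick with a caller-supplied generator.
    """

    N_DOWN = 2

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        spatial = tuple(cfg.input_shape)
        f = 2 ** self.N_DOWN
        if any(s % f for s in spatial):
            raise ShapeError(f"cvae input shape {spatial} must be divisible "
                             f"by {f}")
        b = cfg.base_channels
        self.e1 = Conv(cfg.in_channels, b, 3, stride=2, nd=3, rng=rng)
        self.e2 = Conv(b, 2 * b, 3, stride=2, nd=3, rng=rng)
        self.bottom_shape = (2 * b,) + tuple(s // f for s in spatial)
        flat = int(np.prod(self.bottom_shape))
        self.fc_mu = Linear(flat, cfg.latent_dim, rng=rng)
        self.fc_logvar = Linear(flat, cfg.latent_dim, rng=rng)
        self.fc_dec = Linear(cfg.latent_dim, flat, rng=rng)
        self.d1 = Conv(2 * b, b, 3, nd=3, rng=rng)
        self.d2 = Conv(b, b, 3, nd=3, rng=rng)
        self.out = Conv(b, cfg.in_channels, 1, padding=0, nd=3, rng=rng)

    def encode(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        h = self.e2(self.e1(x).relu()).relu()
        h = h.reshape(h.shape[0], -1)
        return self.fc_mu(h), self.fc_logvar(h)

    def decode(self, z):
        h = self.fc_dec(z).relu()
        h = h.reshape((z.shape[0],) + self.bottom_shape)
        h = self.d1(upsample2(h)).relu()
        h = self.d2(upsample2(h)).relu()
        return softmax(self.out(h), axis=1)

    def forward(self, x, sample: bool = False,
                rng: np.random.Generator | None = None):
        mu, logvar = self.encode(x)
        if sample:
            rng = rng or np.random.default_rng()
            eps = Tensor(rng.standard_normal(mu.shape).astype(np.float32))
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        return self.decode(z), mu, logvar


def build_net(cfg: NetConfig, rng: np.random.Generator | None = None):
    """Instantiate the network family requested by `cfg`."""
    cfg.validate()
    rng = rng or np.random.default_rng()
    if cfg.kind in ("unet2d", "unet3d"):
        return UNet(cfg, rng)
    if cfg.kind == "cascade":
        return CascadeUNet(cfg, rng)
    if cfg.kind == "cvae":
        return CVAE(cfg, rng)
    return ConvClassifier(cfg, rng)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: Module, cfg: NetConfig, path) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(cfg)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path, rng: np.random.Generator | None = None):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfgd = meta["config"]
        if cfgd.get("input_shape") is not None:
            cfgd["input_shape"] = tuple(cfgd["input_shape"])
        cfg = NetConfig(**cfgd)
        n = len([k for k in z.files if k.startswith("p")])
        arrays = [z[f"p{i}"] for i in range(n)]
    model = build_net(cfg, rng or np.random.default_rng(0))
    model.load_arrays(arrays)
    return model, cfg
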