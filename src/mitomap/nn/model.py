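"""Trinary nucleus/mitochondria/background segmentation network.

A U-Net-style encoder-decoder with three departures from the vanilla form:
residual blocks instead of plain double-convs (encoder widths 32, 64, 128,
256, 256 by default); downsampling capped at one-eighth of the input
(max-pooling after the first three encoder stages only, so small organelles
survive in the feature maps); and an atrous spatial pyramid pooling (ASPP)
block with dilation rates 6, 12, 18, 24 closing the encoder to widen the
receptive field.  The decoder mirrors the three pooled stages with
nearest-neighbour upsampling and skip concatenations.  Output is a
(3, H, W) logit map; the per-pixel label is the argmax (ties resolve to the
lowest class id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Conv2D, LeakyReLU, MaxPool2, Param, Upsample2

__all__ = ["NetConfig", "ResBlock", "ASPP", "SegmentationNet", "build_model", "predict_mask"]


@dataclass
class NetConfig:
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 256)
    max_downsampling_factor: int = 8
    aspp_rates: tuple[int, ...] = (6, 12, 18, 24)
    n_classes: int = 3
    leaky_slope: float = 0.01
    input_size: int = 768  # nominal training resolution (H = W)
    seed: int = 0

    def __post_init__(self):
        n_pools = int(np.log2(self.max_downsampling_factor))
        if 2**n_pools != self.max_downsampling_factor:
            raise ValueError("max_downsampling_factor must be a power of 2")
        if len(self.encoder_filters) <= n_pools:
            raise ValueError("need more encoder stages than pooling steps")

    @property
    def n_pools(self) -> int:
        return int(np.log2(self.max_downsampling_factor))


class ResBlock:
    """conv3x3 -> leaky ReLU -> conv3x3, plus a (projected) identity shortcut."""

    def __init__(self, c_in: int, c_out: int, slope: float, rng):
        self.conv1 = Conv2D(c_in, c_out, 3, rng=rng)
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv2D(c_out, c_out, 3, rng=rng)
        self.proj = Conv2D(c_in, c_out, 1, rng=rng) if c_in != c_out else None
        self.act2 = LeakyReLU(slope)

    def forward(self, x):
        h = self.conv2.forward(self.act1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.act2.forward(h + s)

    def backward(self, dout):
        d = self.act2.backward(dout)
        dx = self.conv1.backward(self.act1.backward(self.conv2.backward(d)))
        dx += self.proj.backward(d) if self.proj is not None else d
        return dx

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


class ASPP:
    """Parallel dilated conv branches, concatenated and fused by a 1x1 conv."""

    def __init__(self, c_in: int, c_out: int, rates, slope: float, rng):
        branch_out = max(1, c_out // len(rates))
        self.branches = [Conv2D(c_in, branch_out, 3, dilation=r, rng=rng) for r in rates]
        self.acts = [LeakyReLU(slope) for _ in rates]
        self.fuse = Conv2D(branch_out * len(rates), c_out, 1, rng=rng)
        self.fuse_act = LeakyReLU(slope)
        self._splits: list[int] | None = None

    def forward(self, x):
        outs = [a.forward(b.forward(x)) for b, a in zip(self.branches, self.acts)]
        self._splits = [o.shape[1] for o in outs]
        cat = np.concatenate(outs, axis=1)
        return self.fuse_act.forward(self.fuse.forward(cat))

    def backward(self, dout):
        dcat = self.fuse.backward(self.fuse_act.backward(dout))
        dx = None
        start = 0
        for b, a, c in zip(self.branches, self.acts, self._splits):
            dpart = b.backward(a.backward(dcat[:, start : start + c]))
            dx = dpart if dx is None else dx + dpart
            start += c
        return dx

    def params(self):
        out = []
        for b in self.branches:
            out += b.params()
        return out + self.fuse.params()


class SegmentationNet:
    """Encoder-decoder segmentation model built from a :class:`NetConfig`."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.encoder_filters
        slope = config.leaky_slope
        self.enc_blocks = []
        c_prev = 1
        for c in f:
            self.enc_blocks.append(ResBlock(c_prev, c, slope, rng))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(config.n_pools)]
        self.aspp = ASPP(f[-1], f[-1], config.aspp_rates, slope, rng)
        # decoder mirrors the pooled stages: skips come from stages n_pools..1
        self.ups = [Upsample2() for _ in range(config.n_pools)]
        self.dec_blocks = []
        c_prev = f[-1]
        for i in range(config.n_pools - 1, -1, -1):
            c_skip = f[i]
            self.dec_blocks.append(ResBlock(c_prev + c_skip, c_skip, slope, rng))
            c_prev = c_skip
        self.head = Conv2D(c_prev, config.n_classes, 1, rng=rng)
        self.feature_shapes: list[tuple[int, int]] = []
        self._skip_channels: list[int] = []

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) -> (N, n_classes, H, W); records feature-map sides."""
        self._check_input(x)
        self.feature_shapes = []
        skips = []
        h = x.astype(np.float32)
        n_pools = self.config.n_pools
        for i, block in enumerate(self.enc_blocks):
            h = block.forward(h)
            self.feature_shapes.append(h.shape[2:])
            if i < n_pools:
                skips.append(h)
                h = self.pools[i].forward(h)
                self.feature_shapes.append(h.shape[2:])
        h = self.aspp.forward(h)
        self._n_skip = len(skips)
        self._skip_channels = []
        for i, (up, block) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h)
            skip = skips[-(i + 1)]
            self._skip_channels.append(skip.shape[1])
            h = block.forward(np.concatenate([h, skip], axis=1))
            self.feature_shapes.append(h.shape[2:])
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = [None] * self._n_skip
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dcat = self.dec_blocks[i].backward(d)
            c_up = dcat.shape[1] - self._skip_channels[i]
            dup, dskip = dcat[:, :c_up], dcat[:, c_up:]
            j = self._n_skip - 1 - i
            dskips[j] = dskip if dskips[j] is None else dskips[j] + dskip
            d = self.ups[i].backward(dup)
        d = self.aspp.backward(d)
        n_pools = self.config.n_pools
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < n_pools:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc_blocks[i].backward(d)

    # -- utilities ---------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for b in self.enc_blocks + self.dec_blocks:
            out += b.params()
        out += self.aspp.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def smallest_feature_side(self) -> int:
        if not self.feature_shapes:
            raise RuntimeError("run a forward pass first")
        return min(min(s) for s in self.feature_shapes)

    def _check_input(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        f = self.config.max_downsampling_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"input sides must be divisible by {f}; got {x.shape[2]}x{x.shape[3]} "
                "(pad or resize before calling)"
            )


def build_model(config: NetConfig | None = None) -> SegmentationNet:
    """Construct the segmentation network for a configuration."""
    return SegmentationNet(config or NetConfig())


def save_model(model: SegmentationNet, path) -> None:
    """Checkpoint weights with the NetConfig embedded."""
    import json

    cfg = json.dumps(model.config.__dict__)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, _config=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> SegmentationNet:
    import json

    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["_config"]).decode())
        cfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in cfg_raw.items()})
        model = SegmentationNet(cfg)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
    return model


def predict_mask(model: SegmentationNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel class labels for one image (H, W) or a stack (N, H, W).

    Slices of a stack are predicted independently, order preserved.  Argmax
    ties resolve to the lowest class id.
    """
    img = np.asarray(image, dtype=np.float32)
    single = img.ndim == 2
    if single:
        img = img[None]
    if img.ndim != 3:
        raise ValueError("expected (H, W) or (N, H, W) input")
    out = []
    for sl in img:  # slices are independent
        logits = model.forward(sl[None, None])
        out.append(np.argmax(logits[0], axis=0).astype(np.uint8))
    labels = np.stack(out)
    return labels[0] if single else labels
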