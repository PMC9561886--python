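"""Network architectures: 3D encoder-decoder U-Nets, the 2D slice selector,
and the single-level keypoint detector.

All are desk-scale reinterpretations of their full-size counterparts: the
segmentation and heatmap networks are U-Nets with strided-convolution
downsampling, transpose-convolution upsampling and skip concatenation; the
slice selector stacks 1x3x3 convolution pairs with in-plane-only max pooling
so an N x 256 x 256 stack collapses to N slice scores; the detector reads a
single low-resolution feature map and predicts one box whose center is the
keypoint.
"""

from __future__ import annotations

import numpy as np

from aclloc.nn.layers import (
    BatchNorm,
    ChannelSoftmax,
    Conv3dSame,
    ConvDown,
    ConvUp,
    GroupNorm,
    LeakyReLU,
    MaxPool,
    Sequential,
    Sigmoid,
)


def _norm(kind: str, channels: int, groups: int):
    if kind == "group":
        g = groups
        while channels % g:
            g -= 1
        return GroupNorm(channels, groups=max(g, 1))
    if kind == "batch":
        return BatchNorm(channels)
    raise ValueError(f"unknown norm {kind!r}")


def _block(in_c, out_c, kernel, norm, groups, rng):
    return Sequential(
        Conv3dSame(in_c, out_c, kernel, rng=rng),
        _norm(norm, out_c, groups),
        LeakyReLU(),
        Conv3dSame(out_c, out_c, kernel, rng=rng),
        _norm(norm, out_c, groups),
        LeakyReLU(),
    )


class UNet3D:
    """Encoder-decoder with skip concatenation at equal resolution.

    ``final_activation``: "sigmoid" squashes every output channel to [0, 1]
    independently (heatmap regression); "softmax" makes channels compete
    per voxel (multi-class segmentation); "none" leaves raw scores.
    """

    kind = "unet3d"

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 8,
        in_channels: int = 1,
        n_outputs: int = 1,
        norm: str = "group",
        groups: int = 4,
        final_activation: str = "sigmoid",
        seed: int = 0,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2**l for l in range(depth)]
        self.depth, self.channels = depth, ch
        self.enc, self.down, self.up, self.dec = [], [], [], []
        for l in range(depth):
            in_c = in_channels if l == 0 else ch[l]
            self.enc.append(_block(in_c, ch[l], (3, 3, 3), norm, groups, rng))
            if l < depth - 1:
                self.down.append(ConvDown(ch[l], ch[l + 1], (2, 2, 2), rng=rng))
        for l in range(depth - 2, -1, -1):
            self.up.append(ConvUp(ch[l + 1], ch[l], (2, 2, 2), rng=rng))
            self.dec.append(_block(2 * ch[l], ch[l], (3, 3, 3), norm, groups, rng))
        self.final = Conv3dSame(ch[0], n_outputs, (1, 1, 1), rng=rng)
        if final_activation == "sigmoid":
            self.act = Sigmoid()
        elif final_activation == "softmax":
            self.act = ChannelSoftmax()
        elif final_activation == "none":
            self.act = None
        else:
            raise ValueError(f"unknown final_activation {final_activation!r}")
        self._dec_levels = list(range(depth - 2, -1, -1))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[None]
        x = np.asarray(x, dtype=np.float32)
        d = 2 ** (self.depth - 1)
        if any(s % d for s in x.shape[1:]):
            raise ValueError(f"input shape {x.shape[1:]} not divisible by 2^(depth-1)={d}")
        skips = []
        h = x
        for l in range(self.depth - 1):
            h = self.enc[l].forward(h)
            skips.append(h)
            h = self.down[l].forward(h)
        h = self.enc[self.depth - 1].forward(h)
        for i, l in enumerate(self._dec_levels):
            h = self.up[i].forward(h)
            h = np.concatenate([skips[l], h], axis=0)
            h = self.dec[i].forward(h)
        h = self.final.forward(h)
        if self.act is not None:
            h = self.act.forward(h)
        return h

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.act is not None:
            g = self.act.backward(g)
        g = self.final.backward(g)
        skip_grads = {}
        for i in range(len(self._dec_levels) - 1, -1, -1):
            l = self._dec_levels[i]
            g = self.dec[i].backward(g)
            c = self.channels[l]
            skip_grads[l] = g[:c]
            g = self.up[i].backward(g[c:])
        g = self.enc[self.depth - 1].backward(g)
        for l in range(self.depth - 2, -1, -1):
            g = self.down[l].backward(g)
            g = g + skip_grads[l]
            g = self.enc[l].backward(g)
        return g

    def params(self):
        parts = self.enc + self.down + self.up + self.dec + [self.final]
        return [p for layer in parts for p in layer.params()]

    def iter_layers(self):
        for layer in self.enc + self.down + self.up + self.dec + [self.final]:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer


class SliceNet:
    """Slice-selection network: N x H x W stack -> N-way probability vector.

    Eight convolution sets (two 1x3x3 convolutions each) with max pooling on
    the in-plane dimensions only, so an H = W = 256 input collapses to 1 x 1
    after 2^8 halvings while the slice count is preserved; a final 1x1x1
    convolution reduces to one channel and a softmax over slices gives the
    per-slice probabilities.
    """

    kind = "slicenet"
    N_BLOCKS = 8

    def __init__(
        self,
        n_slices: int = 6,
        in_plane: int = 256,
        base_channels: int = 8,
        norm: str = "group",
        groups: int = 4,
        seed: int = 0,
    ):
        if in_plane != 2**self.N_BLOCKS:
            raise ValueError(f"in-plane size must be {2 ** self.N_BLOCKS}")
        rng = np.random.default_rng(seed)
        c = base_channels
        layers = []
        in_c = 1
        for _ in range(self.N_BLOCKS):
            layers += [
                Conv3dSame(in_c, c, (1, 3, 3), rng=rng),
                _norm(norm, c, groups),
                LeakyReLU(),
                Conv3dSame(c, c, (1, 3, 3), rng=rng),
                _norm(norm, c, groups),
                LeakyReLU(),
                MaxPool((1, 2, 2)),
            ]
            in_c = c
        layers.append(Conv3dSame(c, 1, (1, 1, 1), rng=rng))
        self.body = Sequential(*layers)
        self.n_slices = n_slices
        self.in_plane = in_plane
        self._probs = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n_slices, H, W) or (1, n_slices, H, W) -> (n_slices,) probabilities."""
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.n_slices or x.shape[2:] != (self.in_plane, self.in_plane):
            raise ValueError(
                f"expected (1, {self.n_slices}, {self.in_plane}, {self.in_plane}), got {x.shape}"
            )
        scores = self.body.forward(np.asarray(x, dtype=np.float32))[0, :, 0, 0]
        e = np.exp(scores - scores.max())
        self._probs = e / e.sum()
        return self._probs

    def backward(self, g_probs: np.ndarray) -> np.ndarray:
        p = self._probs
        g_scores = p * (g_probs - np.dot(g_probs, p))  # softmax jacobian
        g = np.zeros((1, self.n_slices, 1, 1), dtype=np.float32)
        g[0, :, 0, 0] = g_scores
        return self.body.backward(g)

    def params(self):
        return self.body.params()

    def iter_layers(self):
        return self.body.iter_layers()


class Detector:
    """Single-level keypoint-as-box-center detector on a 2D image.

    A small convolutional backbone downsamples by 8; the head reads only this
    deepest feature map and predicts per cell an objectness logit and a
    within-cell (dx, dy) offset.  Decoding takes the best cell; the keypoint
    is the decoded box center.  Box size is fixed (the ligament's nominal
    width) rather than regressed.
    """

    kind = "detector"
    STRIDE = 8

    def __init__(self, base_channels: int = 8, norm: str = "group", groups: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.body = Sequential(
            Conv3dSame(1, c, (1, 3, 3), rng=rng),
            _norm(norm, c, groups),
            LeakyReLU(),
            ConvDown(c, 2 * c, (1, 2, 2), rng=rng),
            Conv3dSame(2 * c, 2 * c, (1, 3, 3), rng=rng),
            _norm(norm, 2 * c, groups),
            LeakyReLU(),
            ConvDown(2 * c, 4 * c, (1, 2, 2), rng=rng),
            Conv3dSame(4 * c, 4 * c, (1, 3, 3), rng=rng),
            _norm(norm, 4 * c, groups),
            LeakyReLU(),
            ConvDown(4 * c, 4 * c, (1, 2, 2), rng=rng),
            Conv3dSame(4 * c, 4 * c, (1, 3, 3), rng=rng),
            LeakyReLU(),
            Conv3dSame(4 * c, 3, (1, 1, 1), rng=rng),
        )
        self._shape = None

    def forward(self, image: np.ndarray) -> np.ndarray:
        """image: (H, W) -> raw head map (3, 1, H/8, W/8): [obj logit, dx, dy]."""
        if image.ndim != 2:
            raise ValueError("detector expects a single 2D image")
        self._shape = image.shape
        x = np.asarray(image, dtype=np.float32)[None, None]
        return self.body.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.body.backward(g)

    def decode(self, raw: np.ndarray, image_shape=None):
        """Best box from a head map: (center_px (2,), score in [0,1])."""
        shape = image_shape or self._shape
        obj = raw[0, 0]
        r, c = np.unravel_index(int(np.argmax(obj)), obj.shape)
        off = 1.0 / (1.0 + np.exp(-raw[1:3, 0, r, c]))
        center = (np.array([r, c], dtype=float) + off) * self.STRIDE
        center = np.clip(center, 0.0, np.array(shape, dtype=float) - 1.0)
        score = float(1.0 / (1.0 + np.exp(-obj[r, c])))
        return center, score

    def params(self):
        return self.body.params()

    def iter_layers(self):
        return self.body.iter_layers()
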