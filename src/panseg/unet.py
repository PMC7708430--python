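"""A small UNet implemented in plain numpy, with hand-written backprop.

No neural-network framework is assumed by the package; the architecture is
the standard UNet encoder/decoder: per level two 3x3 same-padded
convolutions with ReLU, 2x2 max-pooling down, nearest-neighbour upsampling
and skip concatenation up, and a 1x1 convolution head producing one logit
per pixel (sigmoid applied by callers).  Same-padding keeps the output
aligned with the input, which overlap-averaged stitching requires.

Arrays are NHWC float32.  All randomness (He initialisation) is seeded, and
training with Adam on one thread is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "build_unet", "Adam"]


class _Conv:
    """KxK same-padded convolution (K odd, K <= 3).

    Reflect padding, not zero padding: a constant input then stays constant
    through every layer, so the network is exactly translation invariant on
    featureless tiles and tile borders carry no padding artifact.
    """

    def __init__(self, rng, cin, cout, k=3):
        self.k = k
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x_pad = None

    def forward(self, x, train):
        k, p = self.k, self.k // 2
        N, H, W, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="reflect") if p else x
        y = np.tile(self.b, (N, H, W, 1)).astype(np.float32)
        for ki in range(k):
            for kj in range(k):
                y += xp[:, ki : ki + H, kj : kj + W, :] @ self.W[ki, kj]
        if train:
            self._x_pad = xp
        return y

    def backward(self, dy):
        k, p = self.k, self.k // 2
        N, H, W, _ = dy.shape
        xp = self._x_pad
        self.db[:] = dy.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, ki : ki + H, kj : kj + W, :]
                self.dW[ki, kj] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, ki : ki + H, kj : kj + W, :] += dy @ self.W[ki, kj].T
        self._x_pad = None
        if not p:
            return dxp
        # fold reflect-padded gradients back: padded row 0 mirrors source
        # row 1 (= padded row 2), etc.  Rows first, then columns, so the
        # corner contributions compose correctly.
        dxp[:, 2, :, :] += dxp[:, 0, :, :]
        dxp[:, -3, :, :] += dxp[:, -1, :, :]
        dxp[:, :, 2, :] += dxp[:, :, 0, :]
        dxp[:, :, -3, :] += dxp[:, :, -1, :]
        return dxp[:, p : p + H, p : p + W, :]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x, train):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max pool; single-winner argmax so gradients never double."""

    def forward(self, x, train):
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(N, H // 2, W // 2, C, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy):
        N, H, W, C = self._shape
        flat = np.zeros((N, H // 2, W // 2, C, 4), dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(N, H // 2, W // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W, C)
        )

    def params(self):
        return []


class _Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        N, H, W, C = dy.shape
        return dy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))

    def params(self):
        return []


def _block(rng, cin, cout):
    return [_Conv(rng, cin, cout), _ReLU(), _Conv(rng, cout, cout), _ReLU()]


def _run(layers, x, train):
    for l in layers:
        x = l.forward(x, train)
    return x


def _run_back(layers, dy):
    for l in reversed(layers):
        dy = l.backward(dy)
    return dy


class UNet:
    """Binary-segmentation UNet: NHWC in, per-pixel logits out."""

    def __init__(self, in_channels=3, base_channels=8, depth=2, seed=0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_channels = base_channels
        self.in_channels = in_channels
        chans = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        cin = in_channels
        for c in chans[:-1]:
            self.enc.append(_block(rng, cin, c))
            cin = c
        self.pools = [_MaxPool2() for _ in range(depth)]
        self.bottleneck = _block(rng, chans[-2], chans[-1])
        self.ups = [_Upsample2() for _ in range(depth)]
        self.dec = []
        for i in reversed(range(depth)):
            # input: upsampled (chans[i+1]) concatenated with skip (chans[i])
            self.dec.append(_block(rng, chans[i + 1] + chans[i], chans[i]))
        self.head = _Conv(rng, chans[0], 1, k=1)

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        for blk in self.dec:
            yield from blk
        yield self.head

    def params(self):
        out = []
        for l in self._all_layers():
            out.extend(l.params())
        return out

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        for (p, _), w in zip(self.params(), weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def _check(self, x):
        x = np.ascontiguousarray(np.asarray(x, np.float32))
        if x.ndim == 3:
            x = x[None]
        N, H, W, C = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        m = 2**self.depth
        if H % m or W % m:
            raise ValueError(f"input size {H}x{W} not divisible by 2^depth = {m}")
        return x

    def forward(self, x, train=False):
        """Logits of shape (N, H, W)."""
        x = self._check(x)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = _run(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = _run(self.bottleneck, x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append((x.shape[-1], skip.shape[-1]))
            x = np.concatenate([x, skip], axis=-1)
            x = _run(blk, x, train)
        return self.head.forward(x, train)[..., 0]

    def backward(self, dlogits):
        dy = self.head.backward(dlogits[..., None])
        dskips = []
        for up, blk, (c_up, c_skip) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            dy = _run_back(blk, dy)
            dskips.append(dy[..., c_up:])
            dy = up.backward(dy[..., :c_up])
        dy = _run_back(self.bottleneck, dy)
        # dskips was collected shallowest-first; reversed(enc) runs deepest-first
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy) + dskip
            dy = _run_back(blk, dy)
        return dy

    def predict_proba(self, x):
        """Sigmoid probabilities in [0, 1], shape (N, H, W) or (H, W)."""
        squeeze = np.asarray(x).ndim == 3
        z = self.forward(x, train=False)
        p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        return p[0] if squeeze else p


class Adam:
    def __init__(self, params, lr=7e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def build_unet(model_scale: int = 8, input_size: int = 64, depth: int = 2, seed: int = 0) -> UNet:
    """Construct an untrained UNet; ``input_size`` must be divisible by
    ``2**depth`` (checked here so misconfiguration fails before training)."""
    if input_size % 2**depth:
        raise ValueError(
            f"input_size {input_size} is not divisible by 2^depth = {2**depth}"
        )
    return UNet(in_channels=3, base_channels=model_scale, depth=depth, seed=seed)
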