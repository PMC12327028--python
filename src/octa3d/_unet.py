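"""Compact CPU U-Net in plain numpy.

Encoder/decoder ("contraction"/"expansion") architecture: each level is
two 3x3 convolutions with ReLU; 2x2 max-pooling between encoder levels;
2x2 transposed-convolution upsampling with skip concatenation on the
decoder side; a final 1x1 convolution produces per-class logits.
Gradients are computed analytically layer by layer and applied with
Adam.  Everything is deterministic for a fixed seed.

Sized for desk-scale phantom segmentation (tens of small B-scans), not
for production imaging workloads.
"""

from __future__ import annotations

import numpy as np

_EIN = dict(optimize=True)


# --------------------------------------------------------------------------
# layer primitives (N, C, H, W)
# --------------------------------------------------------------------------

def conv3x3_forward(x, W, b):
    N, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.empty((N, W.shape[0], H, Wd), dtype=W.dtype)
    y[:] = b[None, :, None, None]
    for di in range(3):
        for dj in range(3):
            y += np.einsum("nchw,oc->nohw", xp[:, :, di:di + H, dj:dj + Wd],
                           W[:, :, di, dj], **_EIN)
    return y


def conv3x3_backward(dy, x, W):
    N, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            sl = xp[:, :, di:di + H, dj:dj + Wd]
            dW[:, :, di, dj] = np.einsum("nohw,nchw->oc", dy, sl, **_EIN)
            dxp[:, :, di:di + H, dj:dj + Wd] += np.einsum(
                "nohw,oc->nchw", dy, W[:, :, di, dj], **_EIN)
    db = dy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


def conv1x1_forward(x, W, b):
    return np.einsum("nchw,oc->nohw", x, W, **_EIN) + b[None, :, None, None]


def conv1x1_backward(dy, x, W):
    dW = np.einsum("nohw,nchw->oc", dy, x, **_EIN)
    dx = np.einsum("nohw,oc->nchw", dy, W, **_EIN)
    return dx, dW, dy.sum(axis=(0, 2, 3))


def maxpool2_forward(x):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool2_backward(dy, idx, in_shape):
    N, C, H, W = in_shape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(in_shape)


def upconv2_forward(x, W, b):
    # W: (C_in, C_out, 2, 2), stride 2 == kernel, so blocks do not overlap
    N, C, H, Wd = x.shape
    O = W.shape[1]
    y = np.empty((N, O, H * 2, Wd * 2), dtype=W.dtype)
    for di in range(2):
        for dj in range(2):
            y[:, :, di::2, dj::2] = np.einsum("nchw,co->nohw", x,
                                              W[:, :, di, dj], **_EIN)
    return y + b[None, :, None, None]


def upconv2_backward(dy, x, W):
    dW = np.empty_like(W)
    dx = np.zeros_like(x)
    for di in range(2):
        for dj in range(2):
            dyb = dy[:, :, di::2, dj::2]
            dW[:, :, di, dj] = np.einsum("nchw,nohw->co", x, dyb, **_EIN)
            dx += np.einsum("nohw,co->nchw", dyb, W[:, :, di, dj], **_EIN)
    return dx, dW, dy.sum(axis=(0, 2, 3))


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

class UNet2D:
    """U-Net with ``depth`` pooling stages and ``base`` channels at the top."""

    def __init__(self, depth=2, base=8, in_ch=1, n_classes=3, seed=0,
                 dtype="float32"):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth, self.base = int(depth), int(base)
        self.in_ch, self.n_classes = int(in_ch), int(n_classes)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        chans = [base * 2 ** l for l in range(depth + 1)]
        c_prev = in_ch
        for l, c in enumerate(chans[:-1]):
            self._init_double(rng, f"enc{l}", c_prev, c)
            c_prev = c
        self._init_double(rng, "bot", chans[-2], chans[-1])
        for l in reversed(range(depth)):
            c_hi, c_lo = chans[l + 1], chans[l]
            self._init_conv(rng, f"up{l}", (c_hi, c_lo, 2, 2), c_lo, fan=c_hi * 4)
            self._init_double(rng, f"dec{l}", 2 * c_lo, c_lo)
        self._init_conv(rng, "out", (n_classes, chans[0]), n_classes,
                        fan=chans[0])
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                      for k, v in self.params.items()}
        self._t = 0

    def _init_conv(self, rng, name, wshape, n_out, fan):
        w = rng.normal(0, np.sqrt(2.0 / fan), wshape).astype(self.dtype)
        self.params[name + "_W"] = w
        n_b = wshape[1] if len(wshape) == 4 and wshape[2] == 2 else wshape[0]
        self.params[name + "_b"] = np.zeros(n_b, self.dtype)

    def _init_double(self, rng, name, c_in, c_out):
        for k, ci in (("a", c_in), ("b", c_out)):
            w = rng.normal(0, np.sqrt(2.0 / (ci * 9)), (c_out, ci, 3, 3))
            self.params[f"{name}{k}_W"] = w.astype(self.dtype)
            self.params[f"{name}{k}_b"] = np.zeros(c_out, self.dtype)

    # -- forward/backward --------------------------------------------------
    def _double(self, x, name, cache):
        p = self.params
        z1 = conv3x3_forward(x, p[f"{name}a_W"], p[f"{name}a_b"])
        a1 = np.maximum(z1, 0)
        z2 = conv3x3_forward(a1, p[f"{name}b_W"], p[f"{name}b_b"])
        a2 = np.maximum(z2, 0)
        cache[name] = (x, z1, a1, z2)
        return a2

    def _double_back(self, da2, name, cache, grads):
        p = self.params
        x, z1, a1, z2 = cache[name]
        dz2 = da2 * (z2 > 0)
        da1, dWb, dbb = conv3x3_backward(dz2, a1, p[f"{name}b_W"])
        dz1 = da1 * (z1 > 0)
        dx, dWa, dba = conv3x3_backward(dz1, x, p[f"{name}a_W"])
        grads[f"{name}b_W"], grads[f"{name}b_b"] = dWb, dbb
        grads[f"{name}a_W"], grads[f"{name}a_b"] = dWa, dba
        return dx

    def forward(self, x, cache=None):
        """x: (N, in_ch, H, W) with H, W divisible by 2**depth -> logits."""
        x = np.asarray(x, self.dtype)
        H, W = x.shape[2:]
        if H % 2 ** self.depth or W % 2 ** self.depth:
            raise ValueError(f"H, W must be divisible by {2 ** self.depth}")
        c = {} if cache is None else cache
        skips = []
        h = x
        for l in range(self.depth):
            h = self._double(h, f"enc{l}", c)
            skips.append(h)
            hp, idx = maxpool2_forward(h)
            c[f"pool{l}"] = (idx, h.shape)
            h = hp
        h = self._double(h, "bot", c)
        for l in reversed(range(self.depth)):
            p = self.params
            u = upconv2_forward(h, p[f"up{l}_W"], p[f"up{l}_b"])
            c[f"up{l}"] = h
            h = np.concatenate([skips[l], u], axis=1)
            c[f"cat{l}"] = skips[l].shape[1]
            h = self._double(h, f"dec{l}", c)
        logits = conv1x1_forward(h, self.params["out_W"], self.params["out_b"])
        c["head"] = h
        return (logits, c) if cache is not None else logits

    def backward(self, dlogits, cache):
        grads: dict[str, np.ndarray] = {}
        dh, dW, db = conv1x1_backward(dlogits, cache["head"],
                                      self.params["out_W"])
        grads["out_W"], grads["out_b"] = dW, db
        dskips = [None] * self.depth
        for l in range(self.depth):
            dh = self._double_back(dh, f"dec{l}", cache, grads)
            nskip = cache[f"cat{l}"]
            dskip, du = dh[:, :nskip], dh[:, nskip:]
            dskips[l] = dskip
            dh, dW, db = upconv2_backward(du, cache[f"up{l}"],
                                          self.params[f"up{l}_W"])
            grads[f"up{l}_W"], grads[f"up{l}_b"] = dW, db
        dh = self._double_back(dh, "bot", cache, grads)
        for l in reversed(range(self.depth)):
            idx, shape = cache[f"pool{l}"]
            dh = maxpool2_backward(dh, idx, shape)
            dh = dh + dskips[l]
            dh = self._double_back(dh, f"enc{l}", cache, grads)
        return grads

    def adam_step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        t = self._t
        for k, g in grads.items():
            m, v = self._adam[k]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence -------------------------------------------------------
    def config(self) -> dict:
        return {"depth": self.depth, "base": self.base, "in_ch": self.in_ch,
                "n_classes": self.n_classes, "seed": self.seed,
                "dtype": str(self.dtype)}

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        for k in self.params:
            self.params[k] = np.asarray(state[k])


# --------------------------------------------------------------------------
# loss: weighted cross-entropy + soft Dice (equal weights)
# --------------------------------------------------------------------------

def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def ce_dice_loss(logits, target, class_weights=None, w_ce=1.0, w_dice=1.0):
    """Composite loss and its gradient w.r.t. the logits.

    target: (N, H, W) int class map.  Class weights counter the heavy
    background/tissue imbalance; ``None`` uses inverse-frequency weights
    normalized to mean 1 over the classes present.
    """
    N, K, H, W = logits.shape
    p = softmax(logits)
    onehot = np.zeros_like(p)
    nn, hh, ww = np.meshgrid(np.arange(N), np.arange(H), np.arange(W),
                             indexing="ij")
    onehot[nn, target, hh, ww] = 1.0

    if class_weights is None:
        freq = onehot.mean(axis=(0, 2, 3))
        inv = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-8), 0.0)
        class_weights = inv / max(inv[freq > 0].mean(), 1e-12)
    cw = np.asarray(class_weights, float)

    npix = N * H * W
    wmap = cw[target][:, None]                      # (N,1,H,W)
    logp = np.log(np.maximum(p, 1e-12))
    ce = -float((wmap * onehot * logp).sum() / npix)
    dce = wmap * (p - onehot) / npix                # d ce / d logits

    eps = 1e-6
    inter = (p * onehot).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + eps
    dice = (2 * inter + eps) / denom
    dloss_dp = -(2 * onehot * denom[None, :, None, None]
                 - (2 * inter + eps)[None, :, None, None]) / \
        (K * denom[None, :, None, None] ** 2)
    # softmax Jacobian
    ddice = p * (dloss_dp - (dloss_dp * p).sum(axis=1, keepdims=True))
    loss = w_ce * ce + w_dice * float(1 - dice.mean())
    return loss, w_ce * dce + w_dice * ddice, cw
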