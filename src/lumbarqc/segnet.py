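"""Concurrent spatial/channel squeeze-and-excitation (scSE) U-net, in NumPy.

The segmenter is an encoder-decoder fully convolutional network with U-net
skip connections in which every encoder and decoder convolution block is
followed by an scSE block: the concurrent combination of

* a spatial SE branch (sSE) — the feature map ``M`` of shape (H, W, C) is
  squeezed along channels by a learned 1x1 projection and excited spatially,
  ``M̂[h,w,c] = M[h,w,c] * sigmoid(q[h,w])``;
* a channel SE branch (cSE) — global average pooling squeezes space to a
  per-channel descriptor ``z``; two affine maps C -> C/r -> C with a ReLU
  and a logistic gate produce channel weights ``w[c] in (0,1)`` that rescale
  each channel.

Tensors are laid out NHWC.  Everything — convolution (im2col), max pooling,
nearest-neighbour upsampling, the SE blocks, the soft-dice + cross-entropy
loss, and the Adam optimizer — is implemented here with explicit forward and
backward passes, so training is fully deterministic given a seed and every
operation can be checked against a scalar-loop oracle.

Two trained networks are applied as a cascade: a binary network first
delineates the lumbar region, then a multi-class network labels the
anatomical structures, with pixels outside the stage-1 region forced to
background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .schema import GrayImage, LabelMask, Position, schema_for

__all__ = [
    "ScseConfig",
    "UnetConfig",
    "TrainConfig",
    "ScseUnet",
    "normalize_image",
    "spatial_se",
    "channel_se",
    "scse",
    "train",
    "two_stage_segment",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class ScseConfig:
    """scSE hyperparameters: cSE bottleneck divisor and branch combination."""

    reduction_ratio: int = 2
    combine_mode: str = "max"  # "max" | "sum"

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.combine_mode not in ("max", "sum"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")


@dataclass(frozen=True)
class UnetConfig:
    depth: int = 4
    base_channels: int = 16
    n_classes: int = 2
    in_channels: int = 1
    input_size: tuple[int, int] = (256, 256)
    scse: ScseConfig = field(default_factory=ScseConfig)

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1 or self.n_classes < 1:
            raise ValueError("depth, base_channels and n_classes must be >= 1")
        h, w = self.input_size
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2^depth={f}")
        if self.base_channels < self.scse.reduction_ratio:
            raise ValueError(
                "base_channels must be >= the cSE reduction ratio")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "dice+cross_entropy"  # "dice" | "cross_entropy" | "dice+cross_entropy"
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.loss not in ("dice", "cross_entropy", "dice+cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# image normalization

def normalize_image(raw: GrayImage | np.ndarray) -> GrayImage | np.ndarray:
    """Min-max normalize intensities to [0, 1] (network input convention).

    The minimum maps to 0 and the maximum to 1; a constant image has no
    contrast to normalize and raises.
    """
    arr = raw.pixels if isinstance(raw, GrayImage) else np.asarray(raw)
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant image (no contrast)")
    out = (arr - lo) / (hi - lo)
    if isinstance(raw, GrayImage):
        return GrayImage(out, position=raw.position)
    return out


# ---------------------------------------------------------------------------
# primitive math

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,k*k*C) patches with same-padding, stride 1."""
    if k == 1:
        return x
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (N,H,W,k,k,C)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(v).reshape(n, h, w, k * k * x.shape[3])


# ---------------------------------------------------------------------------
# layers: each has params/grads dicts and forward/backward with a cache

class _Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.cache: tuple = ()

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(_Layer):
    """k x k convolution, stride 1, same padding; weight (k*k*cin, cout)."""

    def __init__(self, cin: int, cout: int, k: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = k * k * cin
        self.params["W"] = (rng.standard_normal((fan_in, cout))
                            * np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.params["b"] = np.zeros(cout, dtype=_DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = _im2col(x, self.k)
        n, h, w, kk = cols.shape
        y = cols.reshape(-1, kk) @ self.params["W"] + self.params["b"]
        self.cache = (cols, x.shape)
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self.cache
        n, h, w, kk = cols.shape
        dyf = dy.reshape(-1, self.cout)
        self.grads["W"] = cols.reshape(-1, kk).T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].T).reshape(n, h, w, kk)
        if self.k == 1:
            return dcols
        p = self.k // 2
        c = x_shape[3]
        d = dcols.reshape(n, h, w, self.k, self.k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dy.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += d[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.cache = (x > 0,)
        return np.where(self.cache[0], x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self.cache[0], dy, 0)


class MaxPool2(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self.cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self.cache
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :],
                          axis=3)
        dxr = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dxr.reshape(n, h, w, c)


class Upsample2(_Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SpatialSE(_Layer):
    """sSE: squeeze channels with a learned 1x1 projection, excite spatially."""

    def __init__(self, c: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c = c
        self.params["W"] = (rng.standard_normal((c, 1))
                            * np.sqrt(1.0 / c)).astype(_DTYPE)
        self.params["b"] = np.zeros(1, dtype=_DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = x @ self.params["W"] + self.params["b"]  # (N,H,W,1)
        s = _sigmoid(q)
        self.cache = (x, s)
        return x * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self.cache
        ds = (dy * x).sum(axis=-1, keepdims=True)
        dq = ds * s * (1.0 - s)
        self.grads["W"] = (x.reshape(-1, self.c).T
                           @ dq.reshape(-1, 1))
        self.grads["b"] = dq.sum(axis=(0, 1, 2))
        return dy * s + dq @ self.params["W"].T


class ChannelSE(_Layer):
    """cSE: global-average-pool squeeze, bottleneck excitation per channel."""

    def __init__(self, c: int, reduction_ratio: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if c < reduction_ratio:
            raise ValueError(
                f"cSE needs C >= reduction_ratio ({c} < {reduction_ratio})")
        self.c = c
        self.cr = max(1, c // reduction_ratio)
        self.params["W1"] = (rng.standard_normal((c, self.cr))
                             * np.sqrt(2.0 / c)).astype(_DTYPE)
        self.params["b1"] = np.zeros(self.cr, dtype=_DTYPE)
        self.params["W2"] = (rng.standard_normal((self.cr, c))
                             * np.sqrt(2.0 / self.cr)).astype(_DTYPE)
        self.params["b2"] = np.zeros(c, dtype=_DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        z = x.mean(axis=(1, 2))                     # (N,C) spatial squeeze
        pre1 = z @ self.params["W1"] + self.params["b1"]
        h1 = np.maximum(pre1, 0)
        u = _sigmoid(h1 @ self.params["W2"] + self.params["b2"])  # (N,C)
        self.cache = (x, z, pre1, h1, u)
        return x * u[:, None, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, pre1, h1, u = self.cache
        n, h, w, c = x.shape
        du = (dy * x).sum(axis=(1, 2))
        dpre2 = du * u * (1.0 - u)
        self.grads["W2"] = h1.T @ dpre2
        self.grads["b2"] = dpre2.sum(axis=0)
        dh1 = dpre2 @ self.params["W2"].T
        dpre1 = np.where(pre1 > 0, dh1, 0)
        self.grads["W1"] = z.T @ dpre1
        self.grads["b1"] = dpre1.sum(axis=0)
        dz = dpre1 @ self.params["W1"].T
        return dy * u[:, None, None, :] + dz[:, None, None, :] / (h * w)


class ScSE(_Layer):
    """Concurrent sSE + cSE, combined elementwise by max (default) or sum."""

    def __init__(self, c: int, config: ScseConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.mode = config.combine_mode
        self.sse = SpatialSE(c, rng)
        self.cse = ChannelSE(c, config.reduction_ratio, rng)

    @property
    def children(self) -> list[_Layer]:
        return [self.sse, self.cse]

    def n_params(self) -> int:
        return self.sse.n_params() + self.cse.n_params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        ys = self.sse.forward(x)
        yc = self.cse.forward(x)
        if self.mode == "sum":
            self.cache = ()
            return ys + yc
        winner = ys >= yc  # ties go to the spatial branch, deterministically
        self.cache = (winner,)
        return np.where(winner, ys, yc)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.mode == "sum":
            return self.sse.backward(dy) + self.cse.backward(dy)
        (winner,) = self.cache
        return (self.sse.backward(np.where(winner, dy, 0))
                + self.cse.backward(np.where(winner, 0, dy)))


# ---------------------------------------------------------------------------
# functional SE ops on a single (H, W, C) feature map

def spatial_se(m: np.ndarray, weight: np.ndarray,
               bias: float | np.ndarray = 0.0) -> np.ndarray:
    """sSE recalibration of one feature map with explicit projection weights.

    ``weight`` has shape (C,) or (C, 1); the gate is
    ``sigmoid(sum_c M[h,w,c] * weight[c] + bias)``.
    """
    m = np.asarray(m, dtype=np.float64)
    w = np.asarray(weight, dtype=np.float64).reshape(m.shape[-1], 1)
    q = m @ w + np.asarray(bias, dtype=np.float64).reshape(-1)
    return m * _sigmoid(q)


def channel_se(m: np.ndarray, w1: np.ndarray, b1: np.ndarray,
               w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """cSE recalibration of one feature map with explicit bottleneck weights.

    ``w1``: (C, C/r), ``w2``: (C/r, C).  The channel weights are
    ``sigmoid(relu(z @ w1 + b1) @ w2 + b2)`` with ``z`` the per-channel
    spatial mean.
    """
    m = np.asarray(m, dtype=np.float64)
    c = m.shape[-1]
    w1 = np.asarray(w1, dtype=np.float64)
    if w1.shape[0] != c or w1.shape[1] < 1:
        raise ValueError("w1 must have shape (C, C/r) with C/r >= 1")
    z = m.mean(axis=(0, 1))
    h1 = np.maximum(z @ w1 + np.asarray(b1, dtype=np.float64), 0.0)
    u = _sigmoid(h1 @ np.asarray(w2, dtype=np.float64)
                 + np.asarray(b2, dtype=np.float64))
    return m * u


def scse(m: np.ndarray, sse_params: tuple, cse_params: tuple,
         combine_mode: str = "max") -> np.ndarray:
    """Concurrent recalibration: elementwise max or sum of the two branches."""
    ys = spatial_se(m, *sse_params)
    yc = channel_se(m, *cse_params)
    if combine_mode == "max":
        return np.maximum(ys, yc)
    if combine_mode == "sum":
        return ys + yc
    raise ValueError(f"unknown combine_mode {combine_mode!r}")


# ---------------------------------------------------------------------------
# the U-net

class _ConvBlock(_Layer):
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.layers = [Conv2d(cin, cout, 3, rng), ReLU(),
                       Conv2d(cout, cout, 3, rng), ReLU()]

    @property
    def children(self) -> list[_Layer]:
        return self.layers

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ScseUnet:
    """Encoder-decoder segmentation network with scSE recalibration.

    ``forward`` maps (N, H, W, in_channels) to per-pixel class probabilities
    (N, H, W, n_classes) that sum to 1 across classes.  Exactly one scSE
    block follows each encoder and each decoder convolution block.
    """

    def __init__(self, config: UnetConfig, seed: int = 0) -> None:
        self.config = config
        self._pending_skip_grads: list[np.ndarray] = []
        rng = np.random.default_rng(seed)
        d, b = config.depth, config.base_channels
        chans = [b * 2 ** i for i in range(d + 1)]
        self.enc_blocks: list[_ConvBlock] = []
        self.enc_scse: list[ScSE] = []
        self.pools: list[MaxPool2] = []
        cin = config.in_channels
        for i in range(d):
            self.enc_blocks.append(_ConvBlock(cin, chans[i], rng))
            self.enc_scse.append(ScSE(chans[i], config.scse, rng))
            self.pools.append(MaxPool2())
            cin = chans[i]
        self.bottleneck = _ConvBlock(chans[d - 1], chans[d], rng)
        self.ups: list[Upsample2] = []
        self.up_convs: list[Conv2d] = []
        self.dec_blocks: list[_ConvBlock] = []
        self.dec_scse: list[ScSE] = []
        for i in reversed(range(d)):
            self.ups.append(Upsample2())
            self.up_convs.append(Conv2d(chans[i + 1], chans[i], 3, rng))
            self.dec_blocks.append(_ConvBlock(2 * chans[i], chans[i], rng))
            self.dec_scse.append(ScSE(chans[i], config.scse, rng))
        self.head = Conv2d(chans[0], config.n_classes, 1, rng)
        self._skip_channels = [chans[i] for i in reversed(range(d))]

    # -- bookkeeping ---------------------------------------------------

    def _layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for blk, se in zip(self.enc_blocks, self.enc_scse):
            out += [blk, se]
        out.append(self.bottleneck)
        for up, blk, se in zip(self.up_convs, self.dec_blocks, self.dec_scse):
            out += [up, blk, se]
        out.append(self.head)
        return out

    def _param_layers(self) -> list[tuple[str, _Layer]]:
        named: list[tuple[str, _Layer]] = []

        def add(prefix: str, layer: _Layer) -> None:
            kids = getattr(layer, "children", None)
            if kids:
                for j, kid in enumerate(kids):
                    add(f"{prefix}.{j}", kid)
            elif layer.params:
                named.append((prefix, layer))

        for i, (blk, se) in enumerate(zip(self.enc_blocks, self.enc_scse)):
            add(f"enc{i}", blk)
            add(f"enc{i}.scse", se)
        add("bottleneck", self.bottleneck)
        for i, (up, blk, se) in enumerate(
                zip(self.up_convs, self.dec_blocks, self.dec_scse)):
            add(f"dec{i}.up", up)
            add(f"dec{i}", blk)
            add(f"dec{i}.scse", se)
        add("head", self.head)
        return named

    def n_params(self) -> int:
        return sum(layer.n_params() for _, layer in self._param_layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{name}/{k}": v for name, layer in self._param_layers()
                for k, v in layer.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._param_layers():
            for k in layer.params:
                key = f"{name}/{k}"
                arr = np.asarray(state[key], dtype=_DTYPE)
                if arr.shape != layer.params[k].shape:
                    raise ValueError(f"shape mismatch for {key}")
                layer.params[k] = arr

    # -- forward / backward --------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        f = 2 ** self.config.depth
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ValueError(
                f"expected input (N,H,W,{self.config.in_channels}), got {x.shape}")
        if x.shape[1] % f or x.shape[2] % f:
            raise ValueError(
                f"input spatial size {x.shape[1]}x{x.shape[2]} must be "
                f"divisible by 2^depth={f}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probability map for a batch of images."""
        x = np.asarray(x, dtype=_DTYPE)
        self._check_input(x)
        skips = []
        for blk, se, pool in zip(self.enc_blocks, self.enc_scse, self.pools):
            x = se.forward(blk.forward(x))
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, conv, blk, se, skip in zip(
                self.ups, self.up_convs, self.dec_blocks, self.dec_scse,
                reversed(skips)):
            x = conv.forward(up.forward(x))
            x = np.concatenate([skip, x], axis=-1)
            x = se.forward(blk.forward(x))
        logits = self.head.forward(x).astype(np.float64)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the head logits."""
        dy = self.head.backward(dlogits.astype(_DTYPE))
        skip_grads: list[np.ndarray] = []
        for up, conv, blk, se in zip(reversed(self.ups),
                                     reversed(self.up_convs),
                                     reversed(self.dec_blocks),
                                     reversed(self.dec_scse)):
            dy = blk.backward(se.backward(dy))
            c_skip = dy.shape[-1] // 2
            dskip, dy = dy[..., :c_skip], dy[..., c_skip:]
            dy = up.backward(conv.backward(dy))
            skip_grads.append(dskip)
        dy = self.bottleneck.backward(dy)
        # skip_grads were collected shallowest-first; encoder backward runs
        # deepest-first, so pair them in reverse
        for blk, se, pool, dskip in zip(reversed(self.enc_blocks),
                                        reversed(self.enc_scse),
                                        reversed(self.pools),
                                        reversed(skip_grads)):
            dy = pool.backward(dy) + dskip
            dy = blk.backward(se.backward(dy))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Argmax label map for a single (H, W) normalized image."""
        probs = self.forward(np.asarray(image)[None, :, :, None])
        return probs[0].argmax(axis=-1)


def build_unet(config: UnetConfig, seed: int = 0) -> ScseUnet:
    """Construct an scSE U-net with seeded parameter initialization."""
    return ScseUnet(config, seed=seed)


# ---------------------------------------------------------------------------
# loss

def _loss_and_grad(probs: np.ndarray, targets: np.ndarray,
                   loss: str) -> tuple[float, np.ndarray]:
    """Soft-dice / cross-entropy loss and gradient w.r.t. the logits.

    ``probs`` (N,H,W,K) softmax outputs; ``targets`` (N,H,W) integer labels.
    """
    n, h, w, k = probs.shape
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
    npix = n * h * w
    eps = 1e-6
    total = 0.0
    dldp = np.zeros_like(probs)

    if loss in ("cross_entropy", "dice+cross_entropy"):
        p_true = np.take_along_axis(probs, targets[..., None], axis=-1)
        total += float(-np.log(np.maximum(p_true, 1e-12)).mean())
        dldp += -onehot / np.maximum(probs, 1e-12) / npix

    if loss in ("dice", "dice+cross_entropy"):
        num = 2.0 * (probs * onehot).sum(axis=(0, 1, 2)) + eps
        den = probs.sum(axis=(0, 1, 2)) + onehot.sum(axis=(0, 1, 2)) + eps
        dsc = num / den
        total += float(1.0 - dsc.mean())
        # d(num/den)/dp = (2*t - dsc) / den per pixel
        dldp += -(2.0 * onehot - dsc) / den / k

    # chain rule through softmax
    dlogits = probs * (dldp - (dldp * probs).sum(axis=-1, keepdims=True))
    return total, dlogits


# ---------------------------------------------------------------------------
# Adam

class _Adam:
    def __init__(self, model: ScseUnet, lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.layers = [layer for _, layer in model._param_layers()]
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k].astype(_DTYPE)
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= (self.lr * (m[k] / c1)
                      / (np.sqrt(v[k] / c2) + self.eps)).astype(_DTYPE)


# ---------------------------------------------------------------------------
# training and the two-stage cascade

def _prepare_arrays(samples, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack sample images/masks; binarize targets for a 2-class model."""
    xs, ys = [], []
    for s in samples:
        img = normalize_image(np.asarray(s.image.pixels, dtype=np.float64))
        t = np.asarray(s.mask.labels, dtype=np.int64)
        if n_classes == 2:
            t = (t > 0).astype(np.int64)
        elif t.max() >= n_classes:
            raise ValueError(
                f"mask label {int(t.max())} outside the model's "
                f"{n_classes}-class schema")
        xs.append(img)
        ys.append(t)
    x = np.stack(xs)[..., None]
    y = np.stack(ys)
    return x, y


def train(model: ScseUnet, samples, tc: TrainConfig) -> dict[str, list[float]]:
    """Train in place; returns per-epoch train/validation loss history.

    Deterministic given the seed: the train/validation split, batch order
    and every weight update derive from ``tc.seed``.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to train")
    x, y = _prepare_arrays(samples, model.config.n_classes)
    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(len(samples))
    n_val = max(1, int(round(tc.validation_fraction * len(samples))))
    if n_val >= len(samples):
        n_val = len(samples) - 1
    val_idx, train_idx = order[:n_val], order[n_val:]
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    opt = _Adam(model, tc.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for _ in range(tc.epochs):
        perm = rng.permutation(len(xt))
        losses = []
        for start in range(0, len(xt), tc.batch_size):
            idx = perm[start:start + tc.batch_size]
            probs = model.forward(xt[idx])
            loss, dlogits = _loss_and_grad(probs, yt[idx], tc.loss)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        vlosses = []
        for start in range(0, len(xv), tc.batch_size):
            probs = model.forward(xv[start:start + tc.batch_size])
            vloss, _ = _loss_and_grad(probs, yv[start:start + tc.batch_size],
                                      tc.loss)
            vlosses.append(vloss)
        history["val_loss"].append(float(np.mean(vlosses)))
    return history


def two_stage_segment(image: GrayImage, stage1: ScseUnet,
                      stage2: ScseUnet) -> LabelMask:
    """Cascade inference: lumbar region first, then structures within it.

    Stage 1 must be binary (background vs lumbar region); pixels outside its
    predicted region are background in the final mask, pixels inside take
    the stage-2 argmax label.
    """
    if stage1.config.n_classes != 2:
        raise ValueError("stage-1 model must be binary (lumbar region)")
    if image.position is None:
        raise ValueError("image must carry its projection tag")
    arr = np.asarray(image.pixels, dtype=np.float64)
    if np.ptp(arr) > 0:
        arr = normalize_image(arr)
    else:
        arr = np.zeros_like(arr)
    region = stage1.predict(arr) == 1
    labels = stage2.predict(arr)
    labels[~region] = 0
    return LabelMask(labels.astype(np.int64), position=image.position)


# ---------------------------------------------------------------------------
# checkpoint I/O: weights as .npz with a JSON config sidecar

def save_model(model: ScseUnet, path: str | Path,
               metadata: dict | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.state_dict())
    cfg = asdict(model.config)
    cfg["scse"] = asdict(model.config.scse)
    sidecar = {"unet_config": cfg, "metadata": metadata or {}}
    (path / "config.json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> tuple[ScseUnet, dict]:
    path = Path(path)
    sidecar = json.loads((path / "config.json").read_text())
    cfg_d = dict(sidecar["unet_config"])
    cfg_d["scse"] = ScseConfig(**cfg_d["scse"])
    cfg_d["input_size"] = tuple(cfg_d["input_size"])
    model = ScseUnet(UnetConfig(**cfg_d))
    with np.load(path / "weights.npz") as state:
        model.load_state_dict(dict(state))
    return model, sidecar.get("metadata", {})
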