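"""Minimal CNN layer family with hand-written autodiff.

The streaming engine only needs *local* layers — convolution, max-pooling,
frozen batch normalization and ReLU — followed by a global-max-pool head with
a dense binary classifier.  That family is small enough to implement directly
on NumPy arrays, which keeps the whole package runnable on a plain CPU stack
and makes every gradient auditable against finite differences.

Feature maps are ``(channels, rows, cols)`` float64 arrays.  Input images are
scaled to ``[0, 1]`` before entering the stack (white = 1.0).

Two padding regimes exist:

* the *naive* full-image path pads every convolution by its nominal ``p`` on
  all sides (standard zero padding);
* the *windowed* path used by the streaming engine passes explicit per-side
  pad amounts, which are nonzero only where a tile's halo would cross the
  global image boundary — so tiled and global computation agree exactly.

Frozen batch normalization follows evaluation-mode semantics: the stored
per-channel statistics (mu, sigma^2) are constants and only gamma and beta are
trainable, which keeps the layer local and therefore streamable.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tiling import LayerGeometry, TilingError, total_stride

Pads = tuple[int, int, int, int]  # top, bottom, left, right
_NO_PAD: Pads = (0, 0, 0, 0)


class Layer:
    """A local (finite receptive field) layer."""

    name: str = ""
    geometry: LayerGeometry

    def forward(self, x: np.ndarray, pads: Pads = _NO_PAD) -> np.ndarray:
        raise NotImplementedError

    def backward(
        self, x: np.ndarray, g: np.ndarray, pads: Pads = _NO_PAD
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Return (gradient w.r.t. unpadded input, parameter gradients)."""
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def out_channels(self, in_channels: int) -> int:
        return in_channels


def _pad(x: np.ndarray, pads: Pads, value: float = 0.0) -> np.ndarray:
    if pads == _NO_PAD:
        return x
    t, b, l, r = pads
    return np.pad(x, ((0, 0), (t, b), (l, r)), constant_values=value)


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with square kernel."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray, stride: int = 1, padding: int = 0):
        weight = np.asarray(weight, dtype=np.float64)
        bias = np.asarray(bias, dtype=np.float64)
        if weight.ndim != 4 or weight.shape[2] != weight.shape[3]:
            raise TilingError("conv weight must be (out, in, k, k)")
        if bias.shape != (weight.shape[0],):
            raise TilingError("conv bias shape mismatch")
        self.weight = weight
        self.bias = bias
        self.geometry = LayerGeometry(weight.shape[2], stride, padding)

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def out_channels(self, in_channels: int) -> int:
        if in_channels != self.weight.shape[1]:
            raise TilingError(f"{self.name}: expected {self.weight.shape[1]} input channels")
        return self.weight.shape[0]

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.geometry.kernel, self.geometry.stride
        return sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]

    def forward(self, x, pads=_NO_PAD):
        xp = _pad(x, pads)
        v = self._windows(xp)
        return np.einsum("cijmn,ocmn->oij", v, self.weight, optimize=True) + self.bias[
            :, None, None
        ]

    def backward(self, x, g, pads=_NO_PAD):
        k, s = self.geometry.kernel, self.geometry.stride
        xp = _pad(x, pads)
        v = self._windows(xp)
        dw = np.einsum("oij,cijmn->ocmn", g, v, optimize=True)
        db = g.sum(axis=(1, 2))
        ho, wo = g.shape[1:]
        dxp = np.zeros_like(xp)
        for m in range(k):
            for n in range(k):
                dxp[:, m : m + ho * s : s, n : n + wo * s : s] += np.einsum(
                    "oij,oc->cij", g, self.weight[:, :, m, n], optimize=True
                )
        t, b, l, r = pads
        dx = dxp[:, t : dxp.shape[1] - b, l : dxp.shape[2] - r]
        return dx, {"weight": dw, "bias": db}


class MaxPool2D(Layer):
    """Max pooling; padded positions (if any) never win the max."""

    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        self.geometry = LayerGeometry(kernel, stride if stride is not None else kernel, padding)

    def _argmax(self, xp: np.ndarray):
        k, s = self.geometry.kernel, self.geometry.stride
        v = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        flat = v.reshape(v.shape[:3] + (k * k,))
        idx = np.argmax(flat, axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        return y, idx

    def forward(self, x, pads=_NO_PAD):
        xp = _pad(x, pads, value=-np.inf)
        y, _ = self._argmax(xp)
        return y

    def backward(self, x, g, pads=_NO_PAD):
        k, s = self.geometry.kernel, self.geometry.stride
        xp = _pad(x, pads, value=-np.inf)
        _, idx = self._argmax(xp)
        c, ho, wo = g.shape
        rows = np.arange(ho)[None, :, None] * s + idx // k
        cols = np.arange(wo)[None, None, :] * s + idx % k
        chans = np.arange(c)[:, None, None]
        dxp = np.zeros(xp.shape, dtype=np.float64)
        np.add.at(dxp, (np.broadcast_to(chans, idx.shape), rows, cols), g)
        t, b, l, r = pads
        dx = dxp[:, t : dxp.shape[1] - b, l : dxp.shape[2] - r]
        return dx, {}


class ReLU(Layer):
    geometry = LayerGeometry(1, 1, 0)

    def forward(self, x, pads=_NO_PAD):
        assert pads == _NO_PAD
        return np.maximum(x, 0.0)

    def backward(self, x, g, pads=_NO_PAD):
        assert pads == _NO_PAD
        return g * (x > 0.0), {}


class FrozenBatchNorm(Layer):
    """Evaluation-mode batch normalization: fixed (mu, var), trainable (gamma, beta)."""

    geometry = LayerGeometry(1, 1, 0)

    def __init__(
        self,
        gamma: np.ndarray,
        beta: np.ndarray,
        mean: np.ndarray,
        var: np.ndarray,
        eps: float = 1e-5,
    ):
        self.gamma = np.asarray(gamma, dtype=np.float64)
        self.beta = np.asarray(beta, dtype=np.float64)
        self.mean = np.asarray(mean, dtype=np.float64)
        self.var = np.asarray(var, dtype=np.float64)
        if np.any(self.var < 0):
            raise TilingError("batch-norm variance must be non-negative")
        shapes = {a.shape for a in (self.gamma, self.beta, self.mean, self.var)}
        if len(shapes) != 1:
            raise TilingError("batch-norm parameter shapes must agree")
        self.eps = float(eps)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def _scale(self):
        return 1.0 / np.sqrt(self.var + self.eps)

    def forward(self, x, pads=_NO_PAD):
        assert pads == _NO_PAD
        if x.shape[0] != self.gamma.shape[0]:
            raise TilingError(f"{self.name}: channel mismatch")
        s = self._scale()
        return (self.gamma * s)[:, None, None] * x + (self.beta - self.gamma * self.mean * s)[
            :, None, None
        ]

    def backward(self, x, g, pads=_NO_PAD):
        assert pads == _NO_PAD
        s = self._scale()
        xhat = (x - self.mean[:, None, None]) * s[:, None, None]
        dgamma = (g * xhat).sum(axis=(1, 2))
        dbeta = g.sum(axis=(1, 2))
        dx = g * (self.gamma * s)[:, None, None]
        return dx, {"gamma": dgamma, "beta": dbeta}


def frozen_bn_apply(x: np.ndarray, bn: FrozenBatchNorm) -> np.ndarray:
    """Apply evaluation-mode batch normalization: gamma*(x-mu)/sqrt(var+eps)+beta."""
    return bn.forward(np.asarray(x, dtype=np.float64))


class StreamableNet:
    """Ordered local layers plus a global-max-pool + dense binary head.

    The head reduces the final feature map to one value per channel by its
    spatial maximum and scores ``logit = w . maxima + b``.  The global max
    keeps lesion evidence regardless of how small it is relative to the slide,
    and makes the spatial gradient one-hot per channel.
    """

    def __init__(self, layers: list[Layer], head_w: np.ndarray, head_b: float, in_channels: int = 3):
        self.layers = list(layers)
        self.head_w = np.asarray(head_w, dtype=np.float64)
        self.head_b = float(head_b)
        self.in_channels = in_channels
        c = in_channels
        for i, layer in enumerate(self.layers):
            if not isinstance(layer, Layer):
                raise TilingError(f"layer {i} ({type(layer).__name__}) is not streamable")
            layer.name = layer.name or f"{type(layer).__name__.lower()}{i}"
            c = layer.out_channels(c)
        if self.head_w.shape != (c,):
            raise TilingError(f"head weight must have {c} entries, got {self.head_w.shape}")
        self.feature_channels = c

    # -- geometry ---------------------------------------------------------
    def geometries(self) -> list[LayerGeometry]:
        return [layer.geometry for layer in self.layers]

    @property
    def stride(self) -> int:
        return total_stride(self.geometries())

    # -- parameters -------------------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for pname, arr in layer.params().items():
                out[f"{layer.name}.{pname}"] = arr
        out["head.w"] = self.head_w
        out["head.b"] = np.array([self.head_b])
        return out

    def apply_update(self, updates: dict[str, np.ndarray]) -> None:
        """Add ``updates`` in place (same keys/shapes as :meth:`params`)."""
        for layer in self.layers:
            for pname, arr in layer.params().items():
                arr += updates[f"{layer.name}.{pname}"]
        self.head_w += updates["head.w"]
        self.head_b += float(updates["head.b"][0])

    def zero_gradients(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params().items()}

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        arch = []
        arrays = {}
        for i, layer in enumerate(self.layers):
            g = layer.geometry
            spec = {"type": type(layer).__name__, "name": layer.name}
            if isinstance(layer, Conv2D):
                spec.update(stride=g.stride, padding=g.padding)
                arrays[f"{i}.weight"] = layer.weight
                arrays[f"{i}.bias"] = layer.bias
            elif isinstance(layer, MaxPool2D):
                spec.update(kernel=g.kernel, stride=g.stride, padding=g.padding)
            elif isinstance(layer, FrozenBatchNorm):
                spec.update(eps=layer.eps)
                for pname in ("gamma", "beta", "mean", "var"):
                    arrays[f"{i}.{pname}"] = getattr(layer, pname)
            arch.append(spec)
        meta = {"arch": arch, "in_channels": self.in_channels, "head_b": self.head_b}
        np.savez(path, __meta__=np.str_(json.dumps(meta)), head_w=self.head_w, **arrays)

    @classmethod
    def load(cls, path) -> "StreamableNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            layers: list[Layer] = []
            for i, spec in enumerate(meta["arch"]):
                t = spec["type"]
                if t == "Conv2D":
                    layers.append(
                        Conv2D(data[f"{i}.weight"], data[f"{i}.bias"], spec["stride"], spec["padding"])
                    )
                elif t == "MaxPool2D":
                    layers.append(MaxPool2D(spec["kernel"], spec["stride"], spec["padding"]))
                elif t == "ReLU":
                    layers.append(ReLU())
                elif t == "FrozenBatchNorm":
                    layers.append(
                        FrozenBatchNorm(
                            data[f"{i}.gamma"],
                            data[f"{i}.beta"],
                            data[f"{i}.mean"],
                            data[f"{i}.var"],
                            spec["eps"],
                        )
                    )
                else:
                    raise TilingError(f"unknown layer type {t} in checkpoint")
            net = cls(layers, data["head_w"], meta["head_b"], meta["in_channels"])
        return net


def random_net(
    rng: np.random.Generator,
    depth: int = 3,
    channels: int = 4,
    kernels=(1, 3, 5),
    strides=(1, 2),
    with_bn: bool = True,
    with_pool: bool = True,
    in_channels: int = 3,
) -> StreamableNet:
    """Random small streamable net for property tests and demos (He init)."""
    layers: list[Layer] = []
    c = in_channels
    for _ in range(depth):
        k = int(rng.choice(kernels))
        s = int(rng.choice(strides))
        w = rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(channels, c, k, k))
        layers.append(Conv2D(w, rng.normal(0, 0.05, size=channels), stride=s, padding=k // 2))
        c = channels
        if with_bn and rng.random() < 0.5:
            layers.append(
                FrozenBatchNorm(
                    rng.uniform(0.5, 1.5, c),
                    rng.normal(0, 0.1, c),
                    rng.normal(0, 0.2, c),
                    rng.uniform(0.5, 2.0, c),
                )
            )
        layers.append(ReLU())
        if with_pool and rng.random() < 0.4:
            layers.append(MaxPool2D(2, 2, 0))
    head_w = rng.normal(0, 1.0 / np.sqrt(c), size=c)
    return StreamableNet(layers, head_w, float(rng.normal(0, 0.1)), in_channels)


def demo_net(rng: np.random.Generator, channels: tuple[int, int, int] = (8, 16, 16)) -> StreamableNet:
    """Small fixed-architecture classifier (total stride 8) for synthetic slides.

    Initialization choices that make weakly supervised training through a
    global-max head reliable from scratch (no pretrained weights):

    * a leading frozen-BN fixed to the affine ``x -> 1 - x``, so the white
      slide background maps to zero and tissue absorbance drives the maxima;
    * the first convolution's first two channels are stain-deconvolution
      color priors (hematoxylin direction, and eosin orthogonalized against
      hematoxylin) as centered 1x1-like taps, the rest random;
    * deeper convolutions use Dirac (identity-preserving) initialization
      plus noise, so first-layer color channels survive the stack until the
      head has learned which of them predict the label.
    """
    from .augmentation import DEFAULT_STAIN_MATRIX

    c1, c2, c3 = channels

    def dirac_conv(ci, co, k, s, noise=0.05):
        w = rng.normal(0.0, noise / np.sqrt(ci), size=(co, ci, k, k))
        for o in range(co):
            w[o, o % ci, k // 2, k // 2] += 1.0
        return Conv2D(w, np.zeros(co), stride=s, padding=k // 2)

    u_h = DEFAULT_STAIN_MATRIX[0]
    u_e = DEFAULT_STAIN_MATRIX[1] - (DEFAULT_STAIN_MATRIX[1] @ u_h) * u_h
    u_e = u_e / np.linalg.norm(u_e)
    w1 = rng.normal(0.0, 0.05, size=(c1, 3, 3, 3))
    w1[0, :, 1, 1] += u_h
    w1[1, :, 1, 1] += 2.0 * u_e  # amplified so eosin foci compete with dense H texture
    for o in range(2, c1):
        w1[o, :, 1, 1] += rng.normal(0.0, np.sqrt(2.0 / 3.0), size=3)
    layers = [
        FrozenBatchNorm(-np.ones(3), np.zeros(3), np.ones(3), np.ones(3) - 1e-5, eps=1e-5),
        Conv2D(w1, np.zeros(c1), stride=2, padding=1),
        ReLU(),
        MaxPool2D(2, 2, 0),
        dirac_conv(c1, c2, 3, 1),
        ReLU(),
        MaxPool2D(2, 2, 0),
        dirac_conv(c2, c3, 3, 1),
        ReLU(),
    ]
    head_w = rng.normal(0, 0.3 / np.sqrt(c3), size=c3)
    return StreamableNet(layers, head_w, 0.0, 3)


class AdamW:
    """Decoupled-weight-decay Adam; one instance per net."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def __call__(self, net: StreamableNet, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        params = net.params()
        updates = {}
        for k, p in params.items():
            g = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            updates[k] = -self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)
        net.apply_update(updates)
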