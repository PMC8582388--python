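"""Backbone contract, partial fine-tuning, and trainable-parameter accounting.

Two backbone families are provided:

``tiny-test-cnn``
    A small convolutional network (frozen random trunk, two batch-norm
    layers, single sigmoid head) with forward and backward passes written
    directly in numpy.  It is the trainable model used throughout the test
    suite and the end-to-end synthetic experiments: under partial
    fine-tuning only the batch-norm affine parameters and the head receive
    gradients, which keeps the backward pass small and exactly auditable.

``efficientnet-b1`` / ``efficientnet-b3``
    Exact parameter bookkeeping for the EfficientNet architecture: every
    weight tensor (stem, MBConv expansion/depthwise/squeeze-excite/project
    convolutions, batch norms, top convolution, pooled classifier head) is
    enumerated with its shape, so freezing rules and trainable-parameter
    counts are exact.  The convolutional forward pass is intentionally not
    provided; these entries exist for the transfer-learning accounting
    (with a single sigmoid unit on the 1280-feature pooled output, the
    partial fine-tuning rule leaves exactly 63,329 trainable scalars on B1).

Partial fine-tuning freezes everything except the batch-normalization
scale/shift pairs and the final classification layer.  Batch-norm running
statistics are buffers, never counted as trainable, and by default continue
to update in training mode.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModelContract",
    "ParamTensor",
    "TinyCNN",
    "EfficientNetBackbone",
    "build_backbone",
    "apply_partial_finetuning",
    "count_trainable_parameters",
]

_BN_AFFINE_SUFFIXES = (".bn_scale", ".bn_shift")
_HEAD_PREFIX = "head."


@dataclass
class ParamTensor:
    """One named parameter tensor with its trainability status.

    ``buffer`` marks non-learnable state (batch-norm running statistics)
    that never counts as trainable regardless of the flag.
    """

    name: str
    shape: tuple[int, ...]
    trainable: bool = True
    buffer: bool = False
    array: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


class ModelContract:
    """Minimal interface every backbone exposes to the pipeline.

    ``predict_proba`` maps a batch of tiles to per-tile positive-class
    probabilities in [0, 1]; ``train_step`` performs one optimization step
    and returns the batch loss; ``parameters`` enumerates every tensor with
    its trainable flag.
    """

    input_size: int
    name: str

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def train_step(self, batch: np.ndarray, labels: np.ndarray, rate: float) -> float:
        raise NotImplementedError

    def parameters(self) -> list[ParamTensor]:
        raise NotImplementedError

    def save(self, path: str | Path) -> None:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# tiny-test-cnn: a numpy CNN with a frozen random trunk
# ---------------------------------------------------------------------------


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Cross-correlation of NCHW input with FCkk filters."""
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    return np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)


def _conv2d_input_grad(
    dout: np.ndarray, w: np.ndarray, x_shape: tuple[int, ...], stride: int, pad: int
) -> np.ndarray:
    """Gradient of _conv2d with respect to its input."""
    n, c, h, wd = x_shape
    k = w.shape[-1]
    ho, wo = dout.shape[2], dout.shape[3]
    dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            contrib = np.einsum("nfhw,fc->nchw", dout, w[:, :, i, j], optimize=True)
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += contrib
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class _BatchNorm:
    """Per-channel batch normalization with trainable affine parameters."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.scale = np.ones(channels)
        self.shift = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.update_running_stats = True
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.update_running_stats:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mu
                self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.scale[None, :, None, None] * xhat + self.shift[None, :, None, None]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (dx, dscale, dshift) using the cached training-mode stats."""
        xhat, inv = self._cache
        dscale = (dout * xhat).sum(axis=(0, 2, 3))
        dshift = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.scale[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (inv[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx, dscale, dshift


class TinyCNN(ModelContract):
    """Small two-BN-layer CNN with a frozen random trunk.

    Architecture (stride-2 convolutions, 3x3 kernels, pad 1)::

        conv 3->c1 (frozen) -> BN -> ReLU -> conv c1->c2 (frozen) -> BN
        -> ReLU -> global average pool -> linear c2->1 -> sigmoid

    Input tiles are float arrays in [0, 1] (HWC or NHWC, 3 channels); they
    are standardized with fixed mean 0.5 / scale 0.25 before the trunk.
    With the default channels (8, 16) partial fine-tuning leaves
    2*8 + 2*16 + 16 + 1 = 65 trainable scalars.
    """

    def __init__(self, input_size: int = 64, channels: tuple[int, int] = (8, 16), seed: int = 0):
        self.name = "tiny-test-cnn"
        self.input_size = int(input_size)
        self.channels = tuple(int(c) for c in channels)
        c1, c2 = self.channels
        rng = np.random.default_rng(seed)
        # He-style init for the frozen random feature extractor
        self.conv1 = rng.normal(0.0, math.sqrt(2.0 / (3 * 9)), size=(c1, 3, 3, 3))
        self.conv2 = rng.normal(0.0, math.sqrt(2.0 / (c1 * 9)), size=(c2, c1, 3, 3))
        self.bn1 = _BatchNorm(c1)
        self.bn2 = _BatchNorm(c2)
        self.head_w = np.zeros(c2)
        self.head_b = np.zeros(1)
        self._trainable: dict[str, bool] = {
            "conv1": True,
            "conv2": True,
            "bn1.bn_scale": True,
            "bn1.bn_shift": True,
            "bn2.bn_scale": True,
            "bn2.bn_shift": True,
            "head.weight": True,
            "head.bias": True,
        }
        self._partial = False
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self.beta1 = 0.9
        self.beta2 = 0.999

    # -- bookkeeping --------------------------------------------------------

    def _tensor_map(self) -> dict[str, np.ndarray]:
        return {
            "conv1": self.conv1,
            "conv2": self.conv2,
            "bn1.bn_scale": self.bn1.scale,
            "bn1.bn_shift": self.bn1.shift,
            "bn2.bn_scale": self.bn2.scale,
            "bn2.bn_shift": self.bn2.shift,
            "head.weight": self.head_w,
            "head.bias": self.head_b,
        }

    def parameters(self) -> list[ParamTensor]:
        out = [
            ParamTensor(name, arr.shape, trainable=self._trainable[name], array=arr)
            for name, arr in self._tensor_map().items()
        ]
        for bn_name, bn in (("bn1", self.bn1), ("bn2", self.bn2)):
            out.append(ParamTensor(f"{bn_name}.running_mean", bn.running_mean.shape,
                                   trainable=False, buffer=True, array=bn.running_mean))
            out.append(ParamTensor(f"{bn_name}.running_var", bn.running_var.shape,
                                   trainable=False, buffer=True, array=bn.running_var))
        return out

    def set_trainable(self, name: str, flag: bool) -> None:
        if name not in self._trainable:
            raise KeyError(f"unknown parameter tensor {name!r}")
        self._trainable[name] = flag

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _prepare(batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] == 3 and x.shape[1] != 3:
            x = np.transpose(x, (0, 3, 1, 2))
        return (x - 0.5) / 0.25

    def _forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, dict]:
        z1 = _conv2d(x, self.conv1, stride=2, pad=1)
        b1 = self.bn1.forward(z1, training)
        r1 = np.maximum(b1, 0.0)
        z2 = _conv2d(r1, self.conv2, stride=2, pad=1)
        b2 = self.bn2.forward(z2, training)
        r2 = np.maximum(b2, 0.0)
        feats = r2.mean(axis=(2, 3))
        logits = feats @ self.head_w + self.head_b[0]
        probs = 1.0 / (1.0 + np.exp(-logits))
        cache = {"x": x, "z1": z1, "b1": b1, "r1": r1, "b2": b2, "r2": r2,
                 "feats": feats, "probs": probs}
        return probs, cache

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(self._prepare(batch), training=False)
        return probs

    def train_step(self, batch: np.ndarray, labels: np.ndarray, rate: float) -> float:
        if not self._partial:
            raise RuntimeError(
                "tiny-test-cnn only implements the frozen-trunk gradient path; "
                "call apply_partial_finetuning(model) before train_step"
            )
        x = self._prepare(batch)
        y = np.asarray(labels, dtype=np.float64).ravel()
        probs, cache = self._forward(x, training=True)
        p = np.clip(probs, 1e-7, 1.0 - 1e-7)
        loss = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))

        n = len(y)
        dlogits = (probs - y) / n
        grads: dict[str, np.ndarray] = {}
        grads["head.weight"] = cache["feats"].T @ dlogits
        grads["head.bias"] = np.array([dlogits.sum()])
        dfeats = np.outer(dlogits, self.head_w)
        h, w = cache["r2"].shape[2], cache["r2"].shape[3]
        dr2 = np.broadcast_to(dfeats[:, :, None, None], cache["r2"].shape) / (h * w)
        db2 = np.where(cache["b2"] > 0, dr2, 0.0)
        dz2, grads["bn2.bn_scale"], grads["bn2.bn_shift"] = self.bn2.backward(db2)
        dr1 = _conv2d_input_grad(dz2, self.conv2, cache["r1"].shape, stride=2, pad=1)
        db1 = np.where(cache["b1"] > 0, dr1, 0.0)
        _, grads["bn1.bn_scale"], grads["bn1.bn_shift"] = self.bn1.backward(db1)

        self._adam_update(grads, rate)
        return loss

    def _adam_update(self, grads: dict[str, np.ndarray], rate: float) -> None:
        self._adam_t += 1
        t = self._adam_t
        tensors = self._tensor_map()
        for name, g in grads.items():
            if not self._trainable[name]:
                continue
            if name not in self._adam_m:
                self._adam_m[name] = np.zeros_like(g)
                self._adam_v[name] = np.zeros_like(g)
            m = self._adam_m[name] = self.beta1 * self._adam_m[name] + (1 - self.beta1) * g
            v = self._adam_v[name] = self.beta2 * self._adam_v[name] + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            tensors[name] -= rate * mhat / (np.sqrt(vhat) + 1e-8)

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.copy() for k, v in self._tensor_map().items()}
        d["bn1.running_mean"] = self.bn1.running_mean.copy()
        d["bn1.running_var"] = self.bn1.running_var.copy()
        d["bn2.running_mean"] = self.bn2.running_mean.copy()
        d["bn2.running_var"] = self.bn2.running_var.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        self.conv1 = d["conv1"].copy()
        self.conv2 = d["conv2"].copy()
        self.bn1.scale = d["bn1.bn_scale"].copy()
        self.bn1.shift = d["bn1.bn_shift"].copy()
        self.bn2.scale = d["bn2.bn_scale"].copy()
        self.bn2.shift = d["bn2.bn_shift"].copy()
        self.head_w = d["head.weight"].copy()
        self.head_b = d["head.bias"].copy()
        self.bn1.running_mean = d["bn1.running_mean"].copy()
        self.bn1.running_var = d["bn1.running_var"].copy()
        self.bn2.running_mean = d["bn2.running_mean"].copy()
        self.bn2.running_var = d["bn2.running_var"].copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = {
            "backbone": self.name,
            "input_size": self.input_size,
            "channels": list(self.channels),
            "partial_finetuning": self._partial,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TinyCNN":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(input_size=sidecar["input_size"], channels=tuple(sidecar["channels"]))
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        if sidecar.get("partial_finetuning"):
            apply_partial_finetuning(model)
        return model


# ---------------------------------------------------------------------------
# EfficientNet parameter bookkeeping
# ---------------------------------------------------------------------------

# (width_coefficient, depth_coefficient) of the compound-scaled variants
_EFFICIENTNET_SCALING = {
    "efficientnet-b0": (1.0, 1.0),
    "efficientnet-b1": (1.0, 1.1),
    "efficientnet-b2": (1.1, 1.2),
    "efficientnet-b3": (1.2, 1.4),
}

# base (B0) stage table: (expand_ratio, kernel, out_channels, repeats)
_MBCONV_BASE = [
    (1, 3, 16, 1),
    (6, 3, 24, 2),
    (6, 5, 40, 2),
    (6, 3, 80, 3),
    (6, 5, 112, 3),
    (6, 5, 192, 4),
    (6, 3, 320, 1),
]

_STEM_FILTERS = 32
_TOP_FILTERS = 1280
_SE_RATIO = 0.25


def _round_filters(filters: int, width: float, divisor: int = 8) -> int:
    filters *= width
    new = max(divisor, int(filters + divisor / 2) // divisor * divisor)
    if new < 0.9 * filters:
        new += divisor
    return int(new)


def _round_repeats(repeats: int, depth: float) -> int:
    return int(math.ceil(depth * repeats))


def _enumerate_efficientnet_tensors(variant: str) -> list[ParamTensor]:
    width, depth = _EFFICIENTNET_SCALING[variant]
    tensors: list[ParamTensor] = []

    def add_bn(prefix: str, ch: int) -> None:
        tensors.append(ParamTensor(f"{prefix}.bn_scale", (ch,)))
        tensors.append(ParamTensor(f"{prefix}.bn_shift", (ch,)))
        tensors.append(ParamTensor(f"{prefix}.running_mean", (ch,), trainable=False, buffer=True))
        tensors.append(ParamTensor(f"{prefix}.running_var", (ch,), trainable=False, buffer=True))

    stem = _round_filters(_STEM_FILTERS, width)
    tensors.append(ParamTensor("stem.conv", (stem, 3, 3, 3)))
    add_bn("stem", stem)

    c_in = stem
    for stage, (expand, kernel, c_base, repeats) in enumerate(_MBCONV_BASE):
        c_out = _round_filters(c_base, width)
        for block in range(_round_repeats(repeats, depth)):
            p = f"blocks.{stage}.{block}"
            c_exp = c_in * expand
            if expand != 1:
                tensors.append(ParamTensor(f"{p}.expand.conv", (c_exp, c_in, 1, 1)))
                add_bn(f"{p}.expand", c_exp)
            tensors.append(ParamTensor(f"{p}.depthwise.conv", (c_exp, 1, kernel, kernel)))
            add_bn(f"{p}.depthwise", c_exp)
            c_se = max(1, int(c_in * _SE_RATIO))
            tensors.append(ParamTensor(f"{p}.se.reduce.conv", (c_se, c_exp, 1, 1)))
            tensors.append(ParamTensor(f"{p}.se.reduce.bias", (c_se,)))
            tensors.append(ParamTensor(f"{p}.se.expand.conv", (c_exp, c_se, 1, 1)))
            tensors.append(ParamTensor(f"{p}.se.expand.bias", (c_exp,)))
            tensors.append(ParamTensor(f"{p}.project.conv", (c_out, c_exp, 1, 1)))
            add_bn(f"{p}.project", c_out)
            c_in = c_out

    top = _round_filters(_TOP_FILTERS, width)
    tensors.append(ParamTensor("top.conv", (top, c_in, 1, 1)))
    add_bn("top", top)
    # single-logit sigmoid head on the globally pooled feature vector
    tensors.append(ParamTensor("head.weight", (top, 1)))
    tensors.append(ParamTensor("head.bias", (1,)))
    return tensors


class EfficientNetBackbone(ModelContract):
    """EfficientNet architecture with exact per-tensor parameter accounting.

    Enumerates every weight tensor of the compound-scaled architecture with
    a single sigmoid classification unit on the pooled feature vector, and
    supports the freezing and counting semantics of partial fine-tuning.
    The convolutional forward pass of the trunk is not implemented here;
    the trainable ``tiny-test-cnn`` backbone fills that role for every
    experiment in this package.
    """

    def __init__(self, variant: str, input_size: int):
        if input_size not in (224, 512):
            raise ValueError(f"input_size must be 224 or 512 for {variant}, got {input_size}")
        self.name = variant
        self.input_size = int(input_size)
        self._tensors = _enumerate_efficientnet_tensors(variant)

    def parameters(self) -> list[ParamTensor]:
        return list(self._tensors)

    def set_trainable(self, name: str, flag: bool) -> None:
        for t in self._tensors:
            if t.name == name:
                t.trainable = flag
                return
        raise KeyError(f"unknown parameter tensor {name!r}")

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        raise NotImplementedError(
            f"{self.name} is provided for architecture accounting (freezing and "
            "parameter counting); use the tiny-test-cnn backbone for runnable "
            "training and inference"
        )

    def train_step(self, batch: np.ndarray, labels: np.ndarray, rate: float) -> float:
        raise NotImplementedError(self.predict_proba.__doc__)

    def save(self, path: str | Path) -> None:
        sidecar = {"backbone": self.name, "input_size": self.input_size}
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

_SUPPORTED = ("efficientnet-b1", "efficientnet-b3", "tiny-test-cnn")


def build_backbone(name: str, input_size: int, seed: int = 0) -> ModelContract:
    """Construct a backbone with a single-logit sigmoid head.

    ``name`` is one of ``efficientnet-b1``, ``efficientnet-b3`` (input size
    224 or 512) or ``tiny-test-cnn`` (any input size; used by the tests and
    synthetic experiments).
    """
    if name == "tiny-test-cnn":
        return TinyCNN(input_size=input_size, seed=seed)
    if name in ("efficientnet-b1", "efficientnet-b3"):
        return EfficientNetBackbone(name, input_size)
    raise ValueError(f"unknown backbone {name!r}; supported: {', '.join(_SUPPORTED)}")


def _is_partial_trainable(name: str) -> bool:
    return name.endswith(_BN_AFFINE_SUFFIXES) or name.startswith(_HEAD_PREFIX)


def apply_partial_finetuning(model: ModelContract) -> ModelContract:
    """Freeze every tensor except BN scale/shift and the classification head.

    Batch-norm running statistics (buffers) are unaffected: they keep
    updating in training mode unless a backbone exposes a flag to freeze
    them.  Models without any batch-norm layer are allowed; only the head
    then remains trainable (a warning is emitted).
    """
    has_bn = False
    for t in model.parameters():
        if t.buffer:
            continue
        flag = _is_partial_trainable(t.name)
        if t.name.endswith(_BN_AFFINE_SUFFIXES):
            has_bn = True
        model.set_trainable(t.name, flag)
    if not has_bn:
        warnings.warn(
            f"{model.name} has no batch-normalization layers; partial fine-tuning "
            "leaves only the classification head trainable",
            stacklevel=2,
        )
    if isinstance(model, TinyCNN):
        model._partial = True
    return model


def count_trainable_parameters(model: ModelContract) -> int:
    """Exact number of scalar parameters receiving gradients."""
    return sum(t.size for t in model.parameters() if t.trainable and not t.buffer)
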