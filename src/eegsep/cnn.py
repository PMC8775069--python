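"""A small convolutional network for sub-band epoch tensors, in pure NumPy.

The architecture operates on inputs laid out as (channels=19, time=512,
bands=6): EEG channels are the spatial height, time is the width and the six
wavelet sub-bands are the input feature planes.  Both convolutions use 1 x k
kernels, i.e. they filter along time only and never mix EEG channels; this
layout is forced by the reference parameter counts (Conv1: 1*6*6*16 + 16 =
592).  Pooling also acts along time only.

Layer stack: Conv1 (16 filters 1x6, stride 1x2, SAME) + ReLU -> MaxPool 1x2
-> Conv2 (32 filters 1x3, stride 1x2, SAME) + ReLU -> MaxPool 1x2 -> Flatten
-> Dense 32 -> Dropout 0.3 -> Dense 16 -> Dense 1 + sigmoid.  Training uses
Adam on binary cross-entropy.  Label convention: PNES -> 0, ES -> 1; an
epoch with output > 0.5 is labeled ES.

Everything is deterministic given the seeds (single-threaded NumPy ops).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

FEATURE_LAYERS = ("input", "Conv1", "Conv2")


@dataclass(frozen=True)
class CNNSpec:
    """Architecture hyperparameters (defaults reproduce the reference net)."""

    input_shape: Tuple[int, int, int] = (19, 512, 6)
    conv1_filters: int = 16
    conv1_kernel: int = 6
    conv1_stride: int = 2
    conv2_filters: int = 32
    conv2_kernel: int = 3
    conv2_stride: int = 2
    pool_size: int = 2
    dense1_units: int = 32
    dense2_units: int = 16
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if len(self.input_shape) != 3 or min(self.input_shape) < 1:
            raise ValueError("input_shape must be three positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Adam optimizer settings for :meth:`ConvNet.fit`."""

    learning_rate: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 107
    epochs: int = 10
    seed: int = 0
    shuffle: bool = True
    #: weight the two classes inversely to their frequency; LOOCV training
    #: folds are imbalanced by one subject, and with weak signal that prior
    #: alone otherwise dominates the majority vote on the held-out subject
    balance_classes: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1/beta2 must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


#: Per-layer (output shape, parameter count) of the reference architecture.
REFERENCE_TABLE: Tuple[Tuple[str, Tuple[int, ...], int], ...] = (
    ("Input", (19, 512, 6), 0),
    ("Conv1", (19, 256, 16), 592),
    ("MaxPool1", (19, 128, 16), 0),
    ("Conv2", (19, 64, 32), 1568),
    ("MaxPool2", (19, 32, 32), 0),
    ("Flatten", (19456,), 0),
    ("Dense1", (32,), 622624),
    ("Dropout", (32,), 0),
    ("Dense2", (16,), 528),
    ("Dense3", (1,), 17),
)
REFERENCE_TOTAL_PARAMETERS = 625329


def _same_pad(t_in: int, kernel: int, stride: int) -> Tuple[int, int, int]:
    """SAME-padding arithmetic: output length and left/right pads."""
    t_out = -(-t_in // stride)  # ceil
    pad_total = max((t_out - 1) * stride + kernel - t_in, 0)
    left = pad_total // 2
    return t_out, left, pad_total - left


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _ConvTime:
    """1 x k convolution over the time axis of (B, H, T, C) inputs."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype) -> None:
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _glorot(rng, (kernel * in_ch, out_ch),
                         kernel * in_ch, kernel * out_ch, dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def out_time(self, t_in: int) -> int:
        return _same_pad(t_in, self.kernel, self.stride)[0]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # per-tap accumulation: k flat GEMMs instead of one giant im2col
        B, H, T, C = x.shape
        t_out, pl, pr = _same_pad(T, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        Wk = self.W.reshape(self.kernel, C, self.out_ch)
        taps = []
        acc = np.zeros((B * H * t_out, self.out_ch), dtype=x.dtype)
        for j in range(self.kernel):
            sl = np.ascontiguousarray(
                xp[:, :, j : j + self.stride * t_out : self.stride, :]
            ).reshape(-1, C)
            acc += sl @ Wk[j]
            if training:
                taps.append(sl)
        y = acc.reshape(B, H, t_out, self.out_ch) + self.b
        if training:
            self._cache = (taps, (B, H, T, C), (t_out, pl, pr))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        taps, (B, H, T, C), (t_out, pl, pr) = self._cache
        self._cache = None
        dy2 = dy.reshape(-1, self.out_ch)
        Wk = self.W.reshape(self.kernel, C, self.out_ch)
        dW = np.empty_like(Wk)
        self.db = dy2.sum(axis=0)
        dxp = np.zeros((B, H, T + pl + pr, C), dtype=dy.dtype)
        for j in range(self.kernel):
            dW[j] = taps[j].T @ dy2
            dxp[:, :, j : j + self.stride * t_out : self.stride, :] += \
                (dy2 @ Wk[j].T).reshape(B, H, t_out, C)
        self.dW = dW.reshape(self.kernel * C, self.out_ch)
        return dxp[:, :, pl : pl + T, :]

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    n_params = 0

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask

    def params_grads(self):
        return []


class _MaxPoolTime:
    """1 x p max pooling (stride p) over the time axis of (B, H, T, C)."""

    n_params = 0

    def __init__(self, pool: int) -> None:
        self.pool = pool

    def forward(self, x, training=False):
        B, H, T, C = x.shape
        if T % self.pool:
            raise ValueError(f"time axis {T} not divisible by pool {self.pool}")
        xr = x.reshape(B, H, T // self.pool, self.pool, C)
        if training:
            self._arg = xr.argmax(axis=3)
            self._shape = xr.shape
        return xr.max(axis=3)

    def backward(self, dy):
        dxr = np.zeros(self._shape, dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        B, H, T2, p, C = self._shape
        return dxr.reshape(B, H, T2 * p, C)

    def params_grads(self):
        return []


class _Flatten:
    n_params = 0

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params_grads(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng, dtype):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    @property
    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dropout:
    """Inverted dropout; identity at inference."""

    n_params = 0

    def __init__(self, rate: float) -> None:
        self.rate = rate
        self.rng: Optional[np.random.Generator] = None

    def forward(self, x, training=False):
        self._active = training and self.rate > 0.0
        if not self._active:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if not self._active:
            return dy
        return dy * self._mask.astype(dy.dtype)

    def params_grads(self):
        return []


class ConvNet:
    """The sub-band epoch classifier.

    Parameters
    ----------
    spec : CNNSpec
    seed : int
        Seed for weight initialization.
    dtype : numpy dtype
        float32 by default; use float64 for gradient checking.
    """

    def __init__(self, spec: CNNSpec = CNNSpec(), seed: int = 0,
                 dtype=np.float32, normalize_input: bool = True) -> None:
        self.spec = spec
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.normalize_input = normalize_input
        self.input_scale_: float = 1.0
        self.fitted = False
        self.loss_history_: List[float] = []
        rng = np.random.default_rng(seed)
        H, T, C = spec.input_shape

        self._conv1 = _ConvTime(C, spec.conv1_filters, spec.conv1_kernel,
                                spec.conv1_stride, rng, self.dtype)
        t1 = self._conv1.out_time(T)
        self._pool1 = _MaxPoolTime(spec.pool_size)
        t1p = t1 // spec.pool_size
        self._conv2 = _ConvTime(spec.conv1_filters, spec.conv2_filters,
                                spec.conv2_kernel, spec.conv2_stride,
                                rng, self.dtype)
        t2 = self._conv2.out_time(t1p)
        self._pool2 = _MaxPoolTime(spec.pool_size)
        t2p = t2 // spec.pool_size
        flat = H * t2p * spec.conv2_filters
        self._dense1 = _Dense(flat, spec.dense1_units, rng, self.dtype)
        self._dropout = _Dropout(spec.dropout_rate)
        self._dense2 = _Dense(spec.dense1_units, spec.dense2_units, rng,
                              self.dtype)
        self._dense3 = _Dense(spec.dense2_units, 1, rng, self.dtype)

        self._relu1, self._relu2 = _ReLU(), _ReLU()
        self._relu_d1, self._relu_d2 = _ReLU(), _ReLU()
        self._flatten = _Flatten()
        self._layers = [
            self._conv1, self._relu1, self._pool1,
            self._conv2, self._relu2, self._pool2,
            self._flatten,
            self._dense1, self._relu_d1, self._dropout,
            self._dense2, self._relu_d2,
            self._dense3,
        ]
        self._table = (
            ("Input", (H, T, C), 0),
            ("Conv1", (H, t1, spec.conv1_filters), self._conv1.n_params),
            ("MaxPool1", (H, t1p, spec.conv1_filters), 0),
            ("Conv2", (H, t2, spec.conv2_filters), self._conv2.n_params),
            ("MaxPool2", (H, t2p, spec.conv2_filters), 0),
            ("Flatten", (flat,), 0),
            ("Dense1", (spec.dense1_units,), self._dense1.n_params),
            ("Dropout", (spec.dense1_units,), 0),
            ("Dense2", (spec.dense2_units,), self._dense2.n_params),
            ("Dense3", (1,), self._dense3.n_params),
        )
        if spec == CNNSpec():
            self._verify_reference()

    # -- construction-time self check against the reference table ----------
    def _verify_reference(self) -> None:
        for (name, shape, params), (rname, rshape, rparams) in zip(
            self._table, REFERENCE_TABLE
        ):
            if shape != rshape:
                raise RuntimeError(
                    f"layer {name}: derived shape {shape} != reference {rshape}"
                )
            if params != rparams:
                raise RuntimeError(
                    f"layer {name}: parameter count {params} != {rparams}"
                )
        if self.n_parameters != REFERENCE_TOTAL_PARAMETERS:
            raise RuntimeError("total parameter count mismatch")

    # -- introspection ------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return sum(p for _, _, p in self._table)

    def shape_table(self) -> pd.DataFrame:
        """Per-layer output shape and learnable parameter count."""
        rows = [
            {"layer": name,
             "output_shape": " x ".join(str(s) for s in shape),
             "parameters": params}
            for name, shape, params in self._table
        ]
        return pd.DataFrame(rows)

    def layer_params(self) -> Dict[str, int]:
        return {name: p for name, _, p in self._table}

    # -- forward paths ------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec "
                f"{self.spec.input_shape}"
            )
        return x.astype(self.dtype, copy=False)

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self._check_input(x)
        if self.input_scale_ != 1.0:
            out = out * self.dtype.type(self.input_scale_)
        for layer in self._layers:
            out = layer.forward(out, training=training)
        return out[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-epoch sigmoid outputs in [0, 1] (usable on untrained nets)."""
        x = self._check_input(x)
        out = np.empty(x.shape[0])
        for s in range(0, x.shape[0], batch_size):
            z = self.forward_logits(x[s : s + batch_size]).astype(np.float64)
            out[s : s + batch_size] = 1.0 / (1.0 + np.exp(-z))
        return out

    def feature_maps(self, x: np.ndarray, layer: str,
                     batch_size: int = 256) -> np.ndarray:
        """Activations at ``input`` (as-is), ``Conv1`` or ``Conv2``
        (both post-ReLU)."""
        if layer not in FEATURE_LAYERS:
            raise ValueError(f"layer must be one of {FEATURE_LAYERS}")
        x = self._check_input(x)
        if layer == "input":
            return x
        if self.input_scale_ != 1.0:
            x = x * self.dtype.type(self.input_scale_)
        chunks = []
        for s in range(0, x.shape[0], batch_size):
            h = self._relu1.forward(self._conv1.forward(x[s : s + batch_size]))
            if layer == "Conv2":
                h = self._relu2.forward(self._conv2.forward(
                    self._pool1.forward(h)))
            chunks.append(h)
        return np.concatenate(chunks, axis=0)

    # -- training -----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray,
            cfg: TrainConfig = TrainConfig()) -> "ConvNet":
        """Train with Adam on binary cross-entropy.

        ``y`` holds per-epoch labels in {0, 1} (PNES -> 0, ES -> 1); both
        classes must be present.  ``loss_history_`` records the mean
        training loss of each pass.

        When ``normalize_input`` is set (the default), inputs are rescaled
        by the reciprocal of the global training-set standard deviation
        (recorded in ``input_scale_`` and applied at inference too);
        microvolt-scale inputs otherwise saturate the sigmoid early and
        stall optimization within a 10-pass budget.
        """
        x = self._check_input(x)
        if self.normalize_input:
            sd = float(np.std(x))
            self.input_scale_ = 1.0 / sd if sd > 0 else 1.0
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.shape[0] != x.shape[0]:
            raise ValueError("labels length must equal number of epochs")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be 0/1")
        if np.unique(y).size < 2:
            raise ValueError("training set must contain both classes")

        if cfg.balance_classes:
            n_pos = float(y.sum())
            n_neg = float(y.size - n_pos)
            sw = np.where(y > 0.5, y.size / (2.0 * n_pos),
                          y.size / (2.0 * n_neg))
        else:
            sw = np.ones_like(y)

        rng = np.random.default_rng(cfg.seed)
        self._dropout.rng = rng
        params = [pg for layer in self._layers for pg in
                  ([(layer.W, None), (layer.b, None)]
                   if isinstance(layer, (_ConvTime, _Dense)) else [])]
        m = [np.zeros_like(p) for p, _ in params]
        v = [np.zeros_like(p) for p, _ in params]
        t = 0
        n = x.shape[0]
        self.loss_history_ = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n) if cfg.shuffle else np.arange(n)
            epoch_loss = 0.0
            for s in range(0, n, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                xb, yb, wb = x[idx], y[idx], sw[idx]
                z = self.forward_logits(xb, training=True).astype(np.float64)
                p = 1.0 / (1.0 + np.exp(-z))
                loss = float(np.mean(wb * (np.logaddexp(0.0, z) - yb * z)))
                epoch_loss += loss * len(idx)
                dz = (wb * (p - yb) / len(idx)).astype(self.dtype)[:, None]
                grad = dz
                for layer in reversed(self._layers):
                    grad = layer.backward(grad)
                t += 1
                grads = [g for layer in self._layers for _, g in
                         layer.params_grads()]
                for i, ((p_arr, _), g) in enumerate(zip(params, grads)):
                    m[i] = cfg.beta1 * m[i] + (1 - cfg.beta1) * g
                    v[i] = cfg.beta2 * v[i] + (1 - cfg.beta2) * g * g
                    mhat = m[i] / (1 - cfg.beta1 ** t)
                    vhat = v[i] / (1 - cfg.beta2 ** t)
                    p_arr -= (cfg.learning_rate * mhat
                              / (np.sqrt(vhat) + cfg.epsilon)).astype(self.dtype)
            self.loss_history_.append(epoch_loss / n)
        self.fitted = True
        return self

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self._layers):
            if isinstance(layer, (_ConvTime, _Dense)):
                arrays[f"W{i}"] = layer.W
                arrays[f"b{i}"] = layer.b
        meta = {"spec": asdict(self.spec), "seed": self.seed,
                "fitted": self.fitted, "dtype": self.dtype.name,
                "normalize_input": self.normalize_input,
                "input_scale": self.input_scale_}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConvNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec_d = meta["spec"]
            spec_d["input_shape"] = tuple(spec_d["input_shape"])
            model = cls(CNNSpec(**spec_d), seed=meta["seed"],
                        dtype=np.dtype(meta["dtype"]),
                        normalize_input=meta.get("normalize_input", True))
            for i, layer in enumerate(model._layers):
                if isinstance(layer, (_ConvTime, _Dense)):
                    layer.W = data[f"W{i}"]
                    layer.b = data[f"b{i}"]
        model.fitted = meta["fitted"]
        model.input_scale_ = float(meta.get("input_scale", 1.0))
        return model


# ---------------------------------------------------------------------------
# Module-level operation wrappers
# ---------------------------------------------------------------------------

def build(spec: CNNSpec = CNNSpec(), seed: int = 0, dtype=np.float32
          ) -> Tuple[ConvNet, pd.DataFrame]:
    """Construct an untrained network and its shape/parameter table."""
    model = ConvNet(spec, seed=seed, dtype=dtype)
    return model, model.shape_table()


def train(model: ConvNet, tensor_values: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig = TrainConfig()) -> ConvNet:
    """Fit ``model`` on per-epoch sub-band tensors (epochs, 19, 512, 6)."""
    return model.fit(tensor_values, labels, cfg)


def predict_epochs(model: ConvNet, tensor_values: np.ndarray) -> np.ndarray:
    """Per-epoch class probabilities of a *trained* model."""
    if not model.fitted:
        raise ValueError("model has not been trained")
    return model.predict_proba(tensor_values)


def extract_feature_maps(model: ConvNet, tensor_values: np.ndarray,
                         layer: str) -> np.ndarray:
    """Per-epoch activations at input / Conv1 / Conv2 (Conv post-ReLU)."""
    return model.feature_maps(tensor_values, layer)


class CNNEstimator:
    """Adapter exposing the fit/predict protocol used by the LOOCV driver."""

    def __init__(self, spec: CNNSpec = CNNSpec(),
                 cfg: TrainConfig = TrainConfig(), seed: Optional[int] = None):
        self.spec = spec
        self.cfg = cfg if seed is None else TrainConfig(
            **{**asdict(cfg), "seed": seed})
        self.model: Optional[ConvNet] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNEstimator":
        self.model = ConvNet(self.spec, seed=self.cfg.seed)
        self.model.fit(X, y, self.cfg)
        return self

    def predict_proba_epochs(self, X: np.ndarray) -> np.ndarray:
        return predict_epochs(self.model, X)
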