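"""1D U-Net denoiser: NumPy implementation with explicit backpropagation.

The network maps a noisy normalized spectrum (length 1024) to its clean
counterpart.  It is the classic encoder–decoder shape: ``n_levels`` encoder
stages of paired Conv1D→ReLU layers followed by 2× max-pooling, a bottleneck
stage, and a symmetric decoder using 2× linear-interpolation upsampling with
skip concatenations from the matching encoder stage, closed by a 1×1 output
projection.  Convolutions use same-padding (zero), so the output length
equals the input length.

Everything — im2col convolutions routed through BLAS matrix products,
gradients, the Adam optimizer, MSE training with MAE monitoring and
best-validation model selection — is implemented here directly on NumPy
arrays; gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError
from .noise import AugmentationDataset
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "DenoiserModel",
    "build_model",
    "train",
    "denoise",
    "denoise_matrix",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``base_channels`` doubles at every level.  The input length must be
    divisible by ``pool_factor ** n_levels`` (1024 with three 2× poolings).
    """

    n_levels: int = 3
    base_channels: int = 8
    kernel_size: int = 9
    pool_factor: int = 2
    input_length: int = 1024

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.base_channels < 1:
            raise InvalidArgumentError("n_levels and base_channels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise InvalidArgumentError("kernel_size must be odd (same-padding)")
        if self.pool_factor != 2:
            raise InvalidArgumentError("only pool_factor 2 is supported")
        if self.input_length % (self.pool_factor ** self.n_levels) != 0:
            raise InvalidArgumentError(
                f"input_length {self.input_length} not divisible by "
                f"{self.pool_factor ** self.n_levels}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; all stochastic elements derive from ``seed``."""

    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise InvalidArgumentError("val_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# layers (all activations are channels-last: (batch, length, channels))
# ---------------------------------------------------------------------------

class _Conv1d:
    """Same-padding 1-D convolution via k shifted GEMMs (no im2col copies).

    y[b, l, o] = b[o] + Σ_t Σ_c x_pad[b, l+t, c] · W[t, c, o]
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        scale = np.sqrt(2.0 / (cin * k))  # He initialization for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(k, cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.cin, self.cout, self.k = cin, cout, k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0))) if pad else x
        self._xp = xp
        bsz, l = x.shape[0], x.shape[1]
        y = np.empty((bsz, l, self.cout), dtype=xp.dtype)
        y[:] = self.b
        for t in range(self.k):
            y += xp[:, t:t + l, :] @ self.W[t]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None
        xp = self._xp
        l = dy.shape[1]
        pad = self.k // 2
        self.db = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for t in range(self.k):
            src = xp[:, t:t + l, :]
            self.dW[t] = np.matmul(src.transpose(0, 2, 1), dy).sum(axis=0)
            dxp[:, t:t + l, :] += dy @ self.W[t].T
        self._xp = None
        return dxp[:, pad:pad + l, :] if pad else dxp


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        xr = x.reshape(b, l // 2, 2, c)
        self._idx = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, l, c = self._shape
        dxr = np.zeros((b, l // 2, 2, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxr.reshape(b, l, c)


class _UpsampleLinear2:
    """Length-doubling linear interpolation: y[2i]=x[i], y[2i+1]=(x[i]+x[i+1])/2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        y = np.empty((b, 2 * l, c), dtype=x.dtype)
        y[:, 0::2] = x
        y[:, 1:-1:2] = 0.5 * (x[:, :-1] + x[:, 1:])
        y[:, -1] = x[:, -1]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy[:, 0::2].copy()
        mid = dy[:, 1:-1:2]
        dx[:, :-1] += 0.5 * mid
        dx[:, 1:] += 0.5 * mid
        dx[:, -1] += dy[:, -1]
        return dx


class _UNetNet:
    """Parameter container and forward/backward pass for the U-Net topology."""

    def __init__(self, config: UNetConfig, seed: int = 0, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        enc_ch = [config.base_channels * 2 ** i for i in range(config.n_levels)]
        bott_ch = config.base_channels * 2 ** config.n_levels

        self.enc_convs: list[tuple[_Conv1d, _ReLU, _Conv1d, _ReLU]] = []
        cin = 1
        for ch in enc_ch:
            self.enc_convs.append(
                (_Conv1d(cin, ch, k, rng, dtype), _ReLU(),
                 _Conv1d(ch, ch, k, rng, dtype), _ReLU())
            )
            cin = ch
        self.pools = [_MaxPool2() for _ in enc_ch]
        self.bott = (_Conv1d(cin, bott_ch, k, rng, dtype), _ReLU(),
                     _Conv1d(bott_ch, bott_ch, k, rng, dtype), _ReLU())
        self.ups: list[_UpsampleLinear2] = []
        self.dec_convs: list[tuple[_Conv1d, _ReLU, _Conv1d, _ReLU]] = []
        prev = bott_ch
        for ch in reversed(enc_ch):
            self.ups.append(_UpsampleLinear2())
            self.dec_convs.append(
                (_Conv1d(prev + ch, ch, k, rng, dtype), _ReLU(),
                 _Conv1d(ch, ch, k, rng, dtype), _ReLU())
            )
            prev = ch
        self.head = _Conv1d(prev, 1, 1, rng, dtype)

    # -- parameter access ---------------------------------------------------
    def _conv_layers(self) -> list[_Conv1d]:
        layers: list[_Conv1d] = []
        for block in self.enc_convs:
            layers += [block[0], block[2]]
        layers += [self.bott[0], self.bott[2]]
        for block in self.dec_convs:
            layers += [block[0], block[2]]
        layers.append(self.head)
        return layers

    @property
    def n_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self._conv_layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self._conv_layers()):
            out[f"conv{i}.W"] = l.W.copy()
            out[f"conv{i}.b"] = l.b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self._conv_layers()):
            l.W = np.asarray(state[f"conv{i}.W"], dtype=self.dtype).reshape(l.W.shape)
            l.b = np.asarray(state[f"conv{i}.b"], dtype=self.dtype).reshape(l.b.shape)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, L, 1) → (B, L, 1)."""
        if x.shape[1] % (self.config.pool_factor ** self.config.n_levels) != 0:
            raise InvalidArgumentError(
                f"input length {x.shape[1]} not divisible by "
                f"{self.config.pool_factor ** self.config.n_levels}"
            )
        h = x.astype(self.dtype, copy=False)
        skips = []
        for block, pool in zip(self.enc_convs, self.pools):
            c1, r1, c2, r2 = block
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
            skips.append(h)
            h = pool.forward(h)
        c1, r1, c2, r2 = self.bott
        h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec_convs, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append((h.shape[2], skip.shape[2]))
            h = np.concatenate([h, skip], axis=2)
            c1, r1, c2, r2 = block
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(dy.astype(self.dtype, copy=False))
        dskips = []
        for (up, block), (ch_up, ch_skip) in zip(
            reversed(list(zip(self.ups, self.dec_convs))),
            reversed(self._skip_channels),
        ):
            c1, r1, c2, r2 = block
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
            d_up, d_skip = d[:, :, :ch_up], d[:, :, ch_up:]
            dskips.append(d_skip)
            d = up.backward(d_up)
        c1, r1, c2, r2 = self.bott
        d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
        for block, pool, d_skip in zip(
            reversed(self.enc_convs), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + d_skip
            c1, r1, c2, r2 = block
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
        return d


class _Adam:
    """Adam with the standard bias correction (β₁=0.9, β₂=0.999, ε=1e-8)."""

    def __init__(self, layers: list[_Conv1d], lr: float) -> None:
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for l, (mW, mb), (vW, vb) in zip(self.layers, self.m, self.v):
            for p, g, m, v in ((l.W, l.dW, mW, vW), (l.b, l.db, mb, vb)):
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


# ---------------------------------------------------------------------------
# public model API
# ---------------------------------------------------------------------------

@dataclass
class DenoiserModel:
    """A (possibly trained) 1D U-Net denoiser with its training history."""

    config: UNetConfig
    net: _UNetNet
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters


def build_model(config: UNetConfig = UNetConfig(), seed: int = 0,
                dtype=np.float32) -> DenoiserModel:
    """Construct an untrained U-Net; identical seeds give identical weights."""
    return DenoiserModel(config=config, net=_UNetNet(config, seed=seed, dtype=dtype))


def _forward_batches(net: _UNetNet, x: np.ndarray, batch: int) -> np.ndarray:
    outs = [net.forward(x[i:i + batch]) for i in range(0, x.shape[0], batch)]
    return np.concatenate(outs, axis=0)


def train(model: DenoiserModel, data: AugmentationDataset,
          tc: TrainConfig = TrainConfig()) -> DenoiserModel:
    """Train by MSE on noisy→clean pairs; monitor MAE; keep the best-validation weights.

    The dataset is split into train/validation by a seeded permutation; every
    epoch records train and validation MSE and MAE.  The returned model (the
    same object, mutated) carries the weights of the epoch with the lowest
    validation MSE.
    """
    if data.n_pairs == 0:
        raise InvalidArgumentError("empty dataset")
    lo = min(float(data.clean.min()), float(data.noisy.min()))
    hi = max(float(data.clean.max()), float(data.noisy.max()))
    if lo < -1e-6 or hi > 1 + 1e-6:
        raise InvalidArgumentError("dataset rows must lie in [0, 1]")

    net = model.net
    rng = np.random.default_rng(tc.seed)
    n = data.n_pairs
    perm = rng.permutation(n)
    n_val = max(1, int(round(tc.val_fraction * n)))
    if n_val >= n:
        raise InvalidArgumentError("validation split leaves no training data")
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    x = data.noisy[:, :, None].astype(net.dtype)
    y = data.clean[:, :, None].astype(net.dtype)
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    layers = net._conv_layers()
    opt = _Adam(layers, tc.learning_rate)
    hist = {"train_mse": [], "train_mae": [], "val_mse": [], "val_mae": []}
    best_val = np.inf
    best_state = net.state_dict()

    for epoch in range(tc.epochs):
        order = rng.permutation(len(train_idx))
        mse_sum = mae_sum = 0.0
        count = 0
        for start in range(0, len(order), tc.batch_size):
            sel = order[start:start + tc.batch_size]
            xb, yb = xt[sel], yt[sel]
            pred = net.forward(xb)
            diff = pred - yb
            mse_sum += float(np.sum(diff.astype(np.float64) ** 2))
            mae_sum += float(np.sum(np.abs(diff.astype(np.float64))))
            count += diff.size
            net.backward(diff * (2.0 / diff.size))
            opt.step()
        hist["train_mse"].append(mse_sum / count)
        hist["train_mae"].append(mae_sum / count)

        pred_v = _forward_batches(net, xv, tc.batch_size).astype(np.float64)
        dv = pred_v - yv
        val_mse = float(np.mean(dv ** 2))
        val_mae = float(np.mean(np.abs(dv)))
        hist["val_mse"].append(val_mse)
        hist["val_mae"].append(val_mae)
        if val_mse < best_val:
            best_val = val_mse
            best_state = net.state_dict()
        logger.debug(
            "epoch %d: train MSE %.3e, val MSE %.3e", epoch, hist["train_mse"][-1], val_mse
        )

    net.load_state_dict(best_state)
    model.history = hist
    return model


def denoise(model: DenoiserModel, s: Spectrum) -> Spectrum:
    """Apply the denoiser to one normalized spectrum; deterministic inference."""
    if s.values.size != model.config.input_length:
        raise InvalidArgumentError(
            f"expected length {model.config.input_length}, got {s.values.size}"
        )
    out = model.net.forward(s.values[None, :, None])[0, :, 0].astype(float)
    return s.copy_with(values=out, provenance="denoised")


def denoise_matrix(model: DenoiserModel, noisy: np.ndarray,
                   batch_size: int = 32) -> np.ndarray:
    """Vectorized inference over a (n_spectra, length) matrix."""
    noisy = np.asarray(noisy)
    if noisy.ndim != 2 or noisy.shape[1] != model.config.input_length:
        raise InvalidArgumentError("expected a (n, input_length) matrix")
    out = _forward_batches(model.net, noisy[:, :, None], batch_size)
    return out[:, :, 0].astype(float)
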