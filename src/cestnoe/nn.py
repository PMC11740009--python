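"""A small 1D-convolutional regression network in pure numpy (+numba kernels).

Forward and backward passes are written out explicitly (im2col convolutions,
ELU activations, inverted dropout, dense layers, Adam updates).  The network
is deliberately tiny — three conv layers with decreasing filter counts over a
~43-point spectral input, a dropout layer, dense layers of 256 and 128 units
and a scalar linear output — so a CPU trains it in minutes.

All parameters live in one flat float32 buffer (layer tensors are views into
it), which keeps the Adam update a single fused pass.  The elementwise
hot spots (ELU, its gradient, Adam) are numba-jitted when numba is available,
with equivalent numpy fallbacks.  Given a fixed seed and a fixed BLAS,
training is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNNRegressor"]

try:  # fused elementwise kernels; numpy fallbacks keep behaviour identical
    import math

    from numba import njit

    @njit(cache=True, fastmath=True)
    def _elu_inplace(x):
        for i in range(x.size):
            if x[i] < 0.0:
                x[i] = math.expm1(x[i])

    @njit(cache=True, fastmath=True)
    def _mul_elu_grad(d, act):
        # ELU'(pre) = 1 if pre>0 else ELU(pre)+1; act stores ELU(pre)
        for i in range(d.size):
            if act[i] <= 0.0:
                d[i] *= act[i] + 1.0

    @njit(cache=True, fastmath=True)
    def _adam_step(theta, g, m, v, lr, b1, b2, eps, c1, c2):
        for i in range(theta.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            theta[i] -= lr * (m[i] / c1) / (math.sqrt(v[i] / c2) + eps)

except ImportError:  # pragma: no cover - numba is normally present

    def _elu_inplace(x):
        neg = x < 0
        x[neg] = np.expm1(x[neg])

    def _mul_elu_grad(d, act):
        neg = act <= 0
        d[neg] *= act[neg] + np.float32(1.0)

    def _adam_step(theta, g, m, v, lr, b1, b2, eps, c1, c2):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        theta -= lr * (m / c1) / (np.sqrt(v / c2) + eps)


class _Adam:
    """Adam on a single flat parameter vector."""

    def __init__(self, n: int, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n, dtype=np.float32)
        self.v = np.zeros(n, dtype=np.float32)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        _adam_step(
            theta, grad, self.m, self.v,
            np.float32(self.lr), np.float32(self.b1), np.float32(self.b2),
            np.float32(self.eps),
            np.float32(1.0 - self.b1**self.t), np.float32(1.0 - self.b2**self.t),
        )


class CNNRegressor:
    """Three conv1d layers -> dropout -> two dense layers -> scalar output.

    Parameters
    ----------
    input_len
        Number of spectral points per sample.
    conv_filters
        Strictly decreasing filter counts of the three convolutions.
    """

    def __init__(
        self,
        input_len: int,
        conv_filters: tuple[int, int, int] = (64, 32, 16),
        kernel: int = 3,
        dropout: float = 0.2,
        dense: tuple[int, int] = (256, 128),
        seed: int = 0,
    ):
        if not (conv_filters[0] > conv_filters[1] > conv_filters[2]):
            raise ValueError("conv filter counts must be strictly decreasing")
        self.input_len = int(input_len)
        self.conv_filters = tuple(conv_filters)
        self.kernel = int(kernel)
        self.dropout = float(dropout)
        self.dense_sizes = tuple(dense)

        k = self.kernel
        chans = (1,) + self.conv_filters
        flat = self.conv_filters[-1] * self.input_len
        sizes = (flat,) + self.dense_sizes + (1,)
        shapes: list[tuple[str, tuple]] = []
        for i in range(3):
            shapes.append((f"cW{i}", (chans[i] * k, chans[i + 1])))
            shapes.append((f"cb{i}", (chans[i + 1],)))
        for i in range(3):
            shapes.append((f"dW{i}", (sizes[i], sizes[i + 1])))
            shapes.append((f"db{i}", (sizes[i + 1],)))
        total = sum(int(np.prod(s)) for _, s in shapes)
        self.theta = np.zeros(total, dtype=np.float32)
        self.grad = np.zeros(total, dtype=np.float32)
        self.params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        pos = 0
        for name, shape in shapes:
            size = int(np.prod(shape))
            self.params[name] = self.theta[pos : pos + size].reshape(shape)
            self._grads[name] = self.grad[pos : pos + size].reshape(shape)
            pos += size

        rng = np.random.default_rng(seed)
        for name, shape in shapes:
            if name[1] == "W":
                fan_in = shape[0]
                self.params[name][...] = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), size=shape
                ).astype(np.float32)

    # -- conv helpers ------------------------------------------------------
    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(N, C, L) -> (N, L, C*k) with same-padding windows."""
        n, c, length = x.shape
        half = self.kernel // 2
        xp = np.zeros((n, c, length + 2 * half), dtype=np.float32)
        xp[:, :, half : half + length] = x
        s0, s1, s2 = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp, shape=(n, length, c, self.kernel), strides=(s0, s2, s1, s2)
        )
        return windows.reshape(n, length, c * self.kernel)

    def _col2im(self, dcol: np.ndarray, c: int) -> np.ndarray:
        """Adjoint of _im2col: (N, L, C*k) -> (N, L, C)."""
        n, length, _ = dcol.shape
        half = self.kernel // 2
        d = dcol.reshape(n, length, c, self.kernel)
        out = np.zeros((n, length + 2 * half, c), dtype=np.float32)
        for j in range(self.kernel):
            out[:, j : j + length, :] += d[:, :, :, j]
        return out[:, half : half + length, :]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """x: (N, L) standardized inputs. Returns (pred (N,), cache)."""
        p = self.params
        n = x.shape[0]
        h = np.ascontiguousarray(x, dtype=np.float32).reshape(n, 1, self.input_len)
        cache: dict = {}
        for i in range(3):
            col = self._im2col(h)  # (N, L, C*k)
            act = col @ p[f"cW{i}"]
            act += p[f"cb{i}"]  # (N, L, F)
            _elu_inplace(act.reshape(-1))
            cache[f"col{i}"] = col
            cache[f"act{i}"] = act
            h = np.ascontiguousarray(act.transpose(0, 2, 1))  # (N, F, L)
        flat = h.reshape(n, -1)
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            mask = (rng.random(flat.shape) >= self.dropout).astype(np.float32)
            mask /= np.float32(1.0 - self.dropout)
            flat = flat * mask
            cache["drop_mask"] = mask
        cache["flat"] = flat
        h = flat
        for i in range(2):
            act = h @ p[f"dW{i}"]
            act += p[f"db{i}"]
            _elu_inplace(act.reshape(-1))
            cache[f"dact{i}"] = act
            cache[f"din{i}"] = h
            h = act
        cache["din2"] = h
        out = h @ p["dW2"] + p["db2"]
        return out[:, 0], cache

    def backward(self, cache: dict, dout: np.ndarray) -> np.ndarray:
        """dout: (N,) gradient of loss wrt predictions; fills the flat grad."""
        p, g = self.params, self._grads
        d = dout.astype(np.float32)[:, None]  # (N, 1)
        np.matmul(cache["din2"].T, d, out=g["dW2"])
        g["db2"][...] = d.sum(axis=0)
        d = d @ p["dW2"].T
        for i in (1, 0):
            _mul_elu_grad(d.reshape(-1), cache[f"dact{i}"].reshape(-1))
            np.matmul(cache[f"din{i}"].T, d, out=g[f"dW{i}"])
            g[f"db{i}"][...] = d.sum(axis=0)
            d = d @ p[f"dW{i}"].T
        if "drop_mask" in cache:
            d *= cache["drop_mask"]
        n = d.shape[0]
        d = np.ascontiguousarray(
            d.reshape(n, self.conv_filters[-1], self.input_len).transpose(0, 2, 1)
        )
        for i in (2, 1, 0):
            _mul_elu_grad(d.reshape(-1), cache[f"act{i}"].reshape(-1))  # (N, L, F)
            dflat = d.reshape(-1, d.shape[-1])
            col = cache[f"col{i}"].reshape(-1, cache[f"col{i}"].shape[-1])
            np.matmul(col.T, dflat, out=g[f"cW{i}"])
            g[f"cb{i}"][...] = dflat.sum(axis=0)
            if i > 0:
                dcol = d @ p[f"cW{i}"].T  # (N, L, C*k)
                d = self._col2im(dcol, self.conv_filters[i - 1])  # (N, L, C)
        return self.grad

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        optimizer: _Adam | None = None,
    ) -> dict:
        """Minimize MSE with Adam; returns a history dict.

        Passing an existing optimizer continues its moment estimates
        (fine-tuning); otherwise a fresh Adam state is created.
        """

        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.ascontiguousarray(y, dtype=np.float32)
        rng = np.random.default_rng(seed)
        if optimizer is None:
            optimizer = _Adam(self.theta.size, lr=lr)
        else:
            optimizer.lr = lr
        n = X.shape[0]
        history: dict = {"loss": [], "val_loss": []}
        for _ in range(int(epochs)):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                pred, cache = self.forward(xb, train=True, rng=rng)
                err = pred - yb
                loss = float(err @ err) / len(idx)
                if not np.isfinite(loss):
                    raise FloatingPointError("training loss diverged (non-finite)")
                total += loss * len(idx)
                dout = (2.0 / len(idx)) * err
                grad = self.backward(cache, dout)
                optimizer.step(self.theta, grad)
            history["loss"].append(total / n)
            if X_val is not None and len(X_val):
                pv = self.predict(X_val)
                history["val_loss"].append(float(np.mean((pv - y_val) ** 2)))
        history["optimizer"] = optimizer
        return history

    def predict(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Deterministic forward pass (dropout off)."""
        out = np.empty(X.shape[0], dtype=np.float32)
        for start in range(0, X.shape[0], batch_size):
            pred, _ = self.forward(X[start : start + batch_size], train=False)
            out[start : start + batch_size] = pred
        return out

    def copy(self) -> "CNNRegressor":
        """Independent copy (fresh flat buffer; layer views rebuilt)."""
        clone = CNNRegressor.from_config(self.get_config())
        clone.theta[...] = self.theta
        return clone

    # -- (de)serialization --------------------------------------------------
    def get_config(self) -> dict:
        return {
            "input_len": self.input_len,
            "conv_filters": list(self.conv_filters),
            "kernel": self.kernel,
            "dropout": self.dropout,
            "dense": list(self.dense_sizes),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "CNNRegressor":
        return cls(
            input_len=cfg["input_len"],
            conv_filters=tuple(cfg["conv_filters"]),
            kernel=cfg["kernel"],
            dropout=cfg["dropout"],
            dense=tuple(cfg["dense"]),
        )
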