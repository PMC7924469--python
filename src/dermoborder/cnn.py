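"""A small convolutional network for border-irregularity images.

Architecture: five 3x3 convolution layers (ReLU), each followed by 2x2
max-pooling, then two dense layers (ReLU, then a single sigmoid unit
whose output is read as the probability of a *regular* border,
label 1).  The input is a 2-channel image (smoothed segmented lesion
and its border map) plus the 27-value irregularity descriptor, which is
standardized and concatenated onto the flattened convolutional features
before the first dense layer.  Training minimizes binary cross-entropy
with Adam (default learning rate 0.001), all randomness flowing from a
single seed.

The implementation is plain numpy: convolutions are im2col matrix
products, pooling is a reshape-max, and gradients are hand-derived.
That keeps the dependency surface small and the forward/backward pass
easy to verify; it is not meant to compete with GPU frameworks on
throughput, and at the package's default problem sizes (128x128 inputs,
tens to hundreds of samples) a CPU epoch takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CNNSpec:
    """Hyper-parameters; defaults mirror the package's standard setup."""

    filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    kernel: int = 3
    dense_units: int = 64
    learning_rate: float = 0.001
    epochs: int = 1
    batch_size: int = 8
    input_size: int = 128
    n_aux: int = 27
    seed: int = 0

    def __post_init__(self):
        if len(self.filters) != 5:
            raise ValueError("the architecture uses exactly 5 convolution layers")
        if self.input_size % 2 ** len(self.filters):
            raise ValueError(
                f"input_size must be divisible by {2 ** len(self.filters)}"
            )


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches with 'same' zero padding."""
    b, c, h, w = x.shape
    p = k // 2
    padded = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(2, 3))
    # (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b, c, h, w = shape
    p = k // 2
    dpad = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    d = dcols.reshape(b, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dpad[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dpad[:, :, p : p + h, p : p + w]


def _maxpool(x: np.ndarray):
    b, c, h, w = x.shape
    r = x.reshape(b, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    count = mask.sum(axis=(3, 5), keepdims=True)
    return out, (mask, count, x.shape)


def _maxpool_back(dout: np.ndarray, cache) -> np.ndarray:
    mask, count, shape = cache
    d = dout[:, :, :, None, :, None] * mask / count
    return d.reshape(shape)


class SmallCNN:
    """Five conv+pool blocks, two dense layers, sigmoid output."""

    def __init__(self, spec: CNNSpec | None = None):
        self.spec = spec or CNNSpec()
        s = self.spec
        rng = np.random.default_rng(s.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 2
        size = s.input_size
        for i, f in enumerate(s.filters):
            fan_in = c_in * s.kernel**2
            self.params[f"Wc{i}"] = (
                rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, f))
            ).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            c_in = f
            size //= 2
        flat = s.filters[-1] * size * size + s.n_aux
        self.params["W1"] = rng.normal(0, np.sqrt(2.0 / flat), (flat, s.dense_units)).astype(
            np.float32
        )
        self.params["b1"] = np.zeros(s.dense_units, dtype=np.float32)
        self.params["W2"] = rng.normal(
            0, np.sqrt(1.0 / s.dense_units), (s.dense_units, 1)
        ).astype(np.float32)
        self.params["b2"] = np.zeros(1, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.aux_mean = np.zeros(s.n_aux, dtype=np.float32)
        self.aux_std = np.ones(s.n_aux, dtype=np.float32)
        self.loss_history: list[float] = []

    # -- forward/backward ---------------------------------------------------

    def _forward(self, x: np.ndarray, aux: np.ndarray, keep_cache: bool = False):
        s = self.spec
        cache = []
        h = x
        for i in range(len(s.filters)):
            b, c, hh, ww = h.shape
            cols = _im2col(h, s.kernel)
            z = cols @ self.params[f"Wc{i}"] + self.params[f"bc{i}"]
            z = z.reshape(b, hh, ww, -1).transpose(0, 3, 1, 2)
            a = np.maximum(z, 0)
            pooled, pcache = _maxpool(a)
            if keep_cache:
                cache.append((cols, (b, c, hh, ww), z, pcache))
            h = pooled
        b = h.shape[0]
        flat = h.reshape(b, -1)
        aux_n = (aux - self.aux_mean) / self.aux_std
        feats = np.concatenate([flat, aux_n.astype(np.float32)], axis=1)
        z1 = feats @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0)
        logit = a1 @ self.params["W2"] + self.params["b2"]
        prob = 1.0 / (1.0 + np.exp(-logit))
        if keep_cache:
            return prob, (cache, h.shape, flat, feats, z1, a1)
        return prob

    def _backward(self, prob, targets, fwd_cache):
        s = self.spec
        cache, hshape, flat, feats, z1, a1 = fwd_cache
        b = prob.shape[0]
        grads = {}
        dlogit = (prob - targets.reshape(-1, 1)).astype(np.float32) / b
        grads["W2"] = a1.T @ dlogit
        grads["b2"] = dlogit.sum(axis=0)
        da1 = dlogit @ self.params["W2"].T
        dz1 = da1 * (z1 > 0)
        grads["W1"] = feats.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dfeats = dz1 @ self.params["W1"].T
        dflat = dfeats[:, : flat.shape[1]]
        dh = dflat.reshape(hshape)
        for i in reversed(range(len(s.filters))):
            cols, in_shape, z, pcache = cache[i]
            da = _maxpool_back(dh, pcache)
            dz = da * (z > 0)
            bb, _, hh, ww = in_shape
            dzf = dz.transpose(0, 2, 3, 1).reshape(bb, hh * ww, -1)
            grads[f"Wc{i}"] = np.einsum("bpk,bpf->kf", cols, dzf)
            grads[f"bc{i}"] = dzf.sum(axis=(0, 1))
            dcols = dzf @ self.params[f"Wc{i}"].T
            dh = _col2im(dcols, in_shape, s.kernel)
        return grads

    def _adam_step(self, grads):
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # -- public API ---------------------------------------------------------

    def fit(self, images: np.ndarray, aux: np.ndarray, labels: np.ndarray) -> "SmallCNN":
        """Train with BCE/Adam; ``labels`` use 1 = regular, 0 = irregular.

        ``images`` is (N, 2, H, W) in [0, 1]; ``aux`` is (N, 27).
        """
        s = self.spec
        x = np.asarray(images, dtype=np.float32)
        aux = np.asarray(aux, dtype=np.float64)
        y = np.asarray(labels, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 2 or x.shape[2] != s.input_size or x.shape[3] != s.input_size:
            raise ValueError(
                f"images must have shape (N, 2, {s.input_size}, {s.input_size}), got {x.shape}"
            )
        self.aux_mean = aux.mean(axis=0).astype(np.float32)
        std = aux.std(axis=0)
        std[std < 1e-8] = 1.0
        self.aux_std = std.astype(np.float32)
        rng = np.random.default_rng(s.seed + 1)
        n = x.shape[0]
        for _ in range(s.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, s.batch_size):
                idx = order[start : start + s.batch_size]
                prob, fc = self._forward(x[idx], aux[idx], keep_cache=True)
                p = np.clip(prob[:, 0], 1e-7, 1 - 1e-7)
                epoch_loss += float(
                    -np.sum(y[idx] * np.log(p) + (1 - y[idx]) * np.log(1 - p))
                )
                grads = self._backward(prob, y[idx], fc)
                self._adam_step(grads)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, images: np.ndarray, aux: np.ndarray) -> np.ndarray:
        """Sigmoid outputs s = p(regular), shape (N,)."""
        x = np.asarray(images, dtype=np.float32)
        aux = np.asarray(aux, dtype=np.float64)
        out = []
        for start in range(0, x.shape[0], 16):
            out.append(self._forward(x[start : start + 16], aux[start : start + 16])[:, 0])
        return np.concatenate(out)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            aux_mean=self.aux_mean,
            aux_std=self.aux_std,
            spec_filters=np.array(self.spec.filters),
            spec_scalars=np.array(
                [
                    self.spec.kernel,
                    self.spec.dense_units,
                    self.spec.learning_rate,
                    self.spec.epochs,
                    self.spec.batch_size,
                    self.spec.input_size,
                    self.spec.n_aux,
                    self.spec.seed,
                ]
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "SmallCNN":
        data = np.load(path)
        sc = data["spec_scalars"]
        spec = CNNSpec(
            filters=tuple(int(f) for f in data["spec_filters"]),
            kernel=int(sc[0]),
            dense_units=int(sc[1]),
            learning_rate=float(sc[2]),
            epochs=int(sc[3]),
            batch_size=int(sc[4]),
            input_size=int(sc[5]),
            n_aux=int(sc[6]),
            seed=int(sc[7]),
        )
        model = cls(spec)
        for k in model.params:
            model.params[k] = data[k]
        model.aux_mean = data["aux_mean"]
        model.aux_std = data["aux_std"]
        return model
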