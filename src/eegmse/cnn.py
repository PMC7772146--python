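"""Compact convolutional feature extractor for spatial entropy tensors.

Architecture (defaults): four convolutional layers of 64, 128, 256 and
64 channels with kernels 4x4, 4x4, 4x4 and 2x2, stride 1 and SAME
padding — the 10 x 10 spatial size is preserved throughout — followed
by two fully connected layers of 1024 and 512 units.  Every layer uses
the rectifier ``relu(x) = max(x, 0)``.  A softmax classification head
sits on top for training; downstream sequence classifiers consume the
512-dimensional second fully-connected activation, not the head.

Training minimizes softmax cross-entropy plus an L2 penalty on the
weights with the Adam optimizer (initial learning rate 0.01); dropout
(p = 0.5) is applied to both fully connected layers.  When the
validation error stops improving the learning rate is divided by 10,
repeatedly, until training ends.

The network is implemented directly on numpy (float32, im2col + GEMM);
with 10 x 10 inputs this is fast enough for CPU-only training at the
scales this package targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["relu", "CNNFeatureExtractor"]


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, ``max(x, 0)`` elementwise."""
    return np.maximum(x, 0)


def _same_pad(k: int) -> tuple[int, int]:
    """(before, after) zero padding for SAME output size at stride 1."""
    total = k - 1
    before = total // 2
    return before, total - before


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Conv:
    """Stride-1 SAME-padded convolution with ReLU."""

    def __init__(self, rng, kh, kw, cin, cout):
        self.kh, self.kw = kh, kw
        self.W = _he_init(rng, (kh * kw * cin, cout), kh * kw * cin)
        self.b = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool):
        # x: (B, H, W, Cin)
        (pt, pb), (pl, pr) = _same_pad(self.kh), _same_pad(self.kw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        B, H, W = x.shape[0], x.shape[1], x.shape[2]
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        # cols: (B, H, W, Cin, kh, kw) -> (B*H*W, kh*kw*Cin)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(B * H * W, -1)
        z = cols @ self.W + self.b
        a = relu(z)
        cache = (cols, z > 0, x.shape)
        return a.reshape(B, H, W, -1), cache

    def backward(self, da: np.ndarray, cache):
        cols, mask, xshape = cache
        B, H, W, cin = xshape
        dz = da.reshape(B * H * W, -1) * mask
        self.dW = cols.T @ dz
        self.db = dz.sum(axis=0)
        dcols = dz @ self.W.T
        dcols = dcols.reshape(B, H, W, self.kh, self.kw, cin)
        (pt, pb), (pl, pr) = _same_pad(self.kh), _same_pad(self.kw)
        dxp = np.zeros((B, H + pt + pb, W + pl + pr, cin), dtype=np.float32)
        for ki in range(self.kh):
            for kj in range(self.kw):
                dxp[:, ki : ki + H, kj : kj + W, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, pt : pt + H, pl : pl + W, :]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Dense:
    """Fully connected layer, optional ReLU and dropout."""

    def __init__(self, rng, nin, nout, activation=True, dropout=0.0):
        self.W = _he_init(rng, (nin, nout), nin)
        self.b = np.zeros(nout, dtype=np.float32)
        self.activation = activation
        self.dropout = dropout

    def forward(self, x, train, rng=None):
        z = x @ self.W + self.b
        a = relu(z) if self.activation else z
        drop_mask = None
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            drop_mask = (rng.random(a.shape) < keep).astype(np.float32) / keep
            a = a * drop_mask
        return a, (x, z > 0 if self.activation else None, drop_mask)

    def backward(self, da, cache):
        x, mask, drop_mask = cache
        if drop_mask is not None:
            da = da * drop_mask
        dz = da * mask if mask is not None else da
        self.dW = x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class CNNFeatureExtractor(BaseEstimator, TransformerMixin):
    """CNN producing fixed-length feature vectors from spatial tensors.

    Parameters
    ----------
    conv_channels, kernel_sizes
        Channel widths and kernel shapes of the convolutional stack
        (stride 1, SAME padding; spatial size is preserved).
    fc_sizes
        Fully connected layer widths; the last entry is the feature
        dimension handed to the sequence classifiers (default 512).
    dropout
        Dropout probability on both fully connected layers (default 0.5).
    l2
        L2 penalty coefficient on all weights.
    learning_rate, lr_decay, plateau_patience
        Adam initial learning rate (default 0.01); when validation error
        has not improved for ``plateau_patience`` epochs the rate is
        divided by ``lr_decay`` (default 10).
    batch_size, epochs, validation_fraction
        Minibatch training schedule; ``epochs=0`` leaves the network at
        its initialization.
    random_state
        Seeds initialization, shuffling, dropout and the validation
        split; a fixed seed makes ``fit`` reproducible.

    Attributes
    ----------
    n_features_out_
        Length of the extracted feature vector (``fc_sizes[-1]``).
    history_
        Per-epoch dicts with training loss, validation error and
        learning rate.
    n_parameters_
        Total trainable parameter count.
    """

    def __init__(
        self,
        conv_channels=(64, 128, 256, 64),
        kernel_sizes=((4, 4), (4, 4), (4, 4), (2, 2)),
        fc_sizes=(1024, 512),
        dropout=0.5,
        l2=1e-4,
        learning_rate=0.01,
        lr_decay=10.0,
        plateau_patience=3,
        batch_size=128,
        epochs=50,
        validation_fraction=0.1,
        random_state=None,
    ):
        self.conv_channels = conv_channels
        self.kernel_sizes = kernel_sizes
        self.fc_sizes = fc_sizes
        self.dropout = dropout
        self.l2 = l2
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.plateau_patience = plateau_patience
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- construction -------------------------------------------------

    def build(self, input_shape=(10, 10, 4), n_classes=2):
        """Initialize weights for ``input_shape`` without training."""
        if len(input_shape) != 3:
            raise ValueError(
                f"expected (rows, cols, bands) input shape, got {input_shape}"
            )
        rng = np.random.default_rng(self.random_state)
        h, w, cin = input_shape
        layers = []
        c_prev = cin
        for cout, (kh, kw) in zip(self.conv_channels, self.kernel_sizes):
            layers.append(_Conv(rng, kh, kw, c_prev, cout))
            c_prev = cout
        nin = h * w * c_prev
        for nout in self.fc_sizes:
            layers.append(
                _Dense(rng, nin, nout, activation=True, dropout=self.dropout)
            )
            nin = nout
        head = _Dense(rng, nin, n_classes, activation=False, dropout=0.0)
        self._convs = layers[: len(self.conv_channels)]
        self._fcs = layers[len(self.conv_channels):]
        self._head = head
        self._rng = rng
        self.input_shape_ = tuple(input_shape)
        self.classes_ = np.arange(n_classes)
        self.n_features_out_ = self.fc_sizes[-1]
        self.n_parameters_ = int(
            sum(p[1].size for lay in self._all_layers() for p in lay.params())
        )
        self.history_ = []
        return self

    def _all_layers(self):
        return [*self._convs, *self._fcs, self._head]

    # -- forward ------------------------------------------------------

    def _check_input(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"expected input shaped (batch, {self.input_shape_[0]}, "
                f"{self.input_shape_[1]}, {self.input_shape_[2]}), got "
                f"{tuple(X.shape)}"
            )
        return X

    def _forward(self, X, train=False):
        caches = []
        a = X
        for conv in self._convs:
            a, c = conv.forward(a, train)
            caches.append(c)
        B = a.shape[0]
        flat_shape = a.shape
        a = a.reshape(B, -1)
        feats = None
        for fc in self._fcs:
            a, c = fc.forward(a, train, rng=self._rng)
            caches.append(c)
        feats = a
        logits, c = self._head.forward(a, train, rng=self._rng)
        caches.append(c)
        return feats, logits, caches, flat_shape

    def _backward(self, dlogits, caches, flat_shape):
        da = self._head.backward(dlogits, caches[-1])
        k = len(caches) - 2
        for fc in reversed(self._fcs):
            da = fc.backward(da, caches[k])
            k -= 1
        da = da.reshape(flat_shape)
        for conv in reversed(self._convs):
            da = conv.backward(da, caches[k])
            k -= 1

    # -- training -----------------------------------------------------

    def fit(self, X, y):
        """Train on tensors ``X`` (n, rows, cols, bands) and binary ``y``."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError(
                f"expected (n, rows, cols, bands) training tensors, got "
                f"{X.shape}"
            )
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "training labels contain a single class; need at least two"
            )
        y_idx = np.searchsorted(classes, y)
        self.build(input_shape=X.shape[1:], n_classes=classes.size)
        self.classes_ = classes
        rng = self._rng

        n = X.shape[0]
        n_val = int(round(self.validation_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        # fall back to training error for the plateau rule if the split
        # is empty or single-class
        if n_val == 0 or np.unique(y_idx[val_idx]).size < 2:
            val_idx = tr_idx

        lr = float(self.learning_rate)
        adam_m, adam_v, t_step = {}, {}, 0
        best_err, wait = np.inf, 0
        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                _, logits, caches, flat_shape = self._forward(xb, train=True)
                zmax = logits.max(axis=1, keepdims=True)
                ez = np.exp(logits - zmax)
                probs = ez / ez.sum(axis=1, keepdims=True)
                ce = -np.mean(
                    np.log(probs[np.arange(len(yb)), yb] + 1e-12)
                )
                l2_term = self.l2 * sum(
                    float((lay.W ** 2).sum()) for lay in self._all_layers()
                )
                losses.append(ce + l2_term)
                dlogits = probs
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self._backward(dlogits.astype(np.float32), caches, flat_shape)
                t_step += 1
                self._adam_step(lr, adam_m, adam_v, t_step)
            val_err = self._error_rate(X[val_idx], y_idx[val_idx])
            self.history_.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)),
                    "val_error": float(val_err),
                    "lr": lr,
                }
            )
            if val_err < best_err - 1e-6:
                best_err, wait = val_err, 0
            else:
                wait += 1
                if wait >= self.plateau_patience:
                    lr /= self.lr_decay
                    wait = 0
        return self

    def _adam_step(self, lr, m, v, t, beta1=0.9, beta2=0.999, eps=1e-8):
        for li, lay in enumerate(self._all_layers()):
            for name, param, gname in lay.params():
                g = getattr(lay, gname).astype(np.float32)
                if name == "W":
                    g = g + 2.0 * self.l2 * param
                key = (li, name)
                m[key] = beta1 * m.get(key, 0.0) + (1 - beta1) * g
                v[key] = beta2 * v.get(key, 0.0) + (1 - beta2) * g * g
                mhat = m[key] / (1 - beta1 ** t)
                vhat = v[key] / (1 - beta2 ** t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    def _error_rate(self, X, y_idx, batch=256):
        wrong = 0
        for start in range(0, X.shape[0], batch):
            _, logits, _, _ = self._forward(X[start : start + batch])
            wrong += int((logits.argmax(axis=1) != y_idx[start : start + batch]).sum())
        return wrong / max(X.shape[0], 1)

    # -- inference ----------------------------------------------------

    def transform(self, X, batch_size=256):
        """Feature vectors (n, fc_sizes[-1]); dropout disabled."""
        if not hasattr(self, "_head"):
            raise RuntimeError("extractor is not built; call fit() or build()")
        X = self._check_input(X)
        out = np.empty((X.shape[0], self.n_features_out_), dtype=np.float32)
        for start in range(0, X.shape[0], batch_size):
            feats, _, _, _ = self._forward(X[start : start + batch_size])
            out[start : start + len(feats)] = feats
        return out

    def predict_proba(self, X, batch_size=256):
        """Softmax head probabilities (diagnostic; unused downstream)."""
        X = self._check_input(X)
        out = np.empty((X.shape[0], len(self.classes_)), dtype=np.float32)
        for start in range(0, X.shape[0], batch_size):
            _, logits, _, _ = self._forward(X[start : start + batch_size])
            zmax = logits.max(axis=1, keepdims=True)
            ez = np.exp(logits - zmax)
            out[start : start + len(logits)] = ez / ez.sum(1, keepdims=True)
        return out

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence --------------------------------------------------

    def save(self, path: str) -> None:
        """Persist weights and architecture to a portable .npz file."""
        arrays, meta = {}, {
            "conv_channels": list(self.conv_channels),
            "kernel_sizes": [list(k) for k in self.kernel_sizes],
            "fc_sizes": list(self.fc_sizes),
            "input_shape": list(self.input_shape_),
            "n_classes": int(len(self.classes_)),
        }
        for li, lay in enumerate(self._all_layers()):
            arrays[f"W{li}"] = lay.W
            arrays[f"b{li}"] = lay.b
        import json

        np.savez(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "CNNFeatureExtractor":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            est = cls(
                conv_channels=tuple(meta["conv_channels"]),
                kernel_sizes=tuple(tuple(k) for k in meta["kernel_sizes"]),
                fc_sizes=tuple(meta["fc_sizes"]),
            )
            est.build(
                input_shape=tuple(meta["input_shape"]),
                n_classes=meta["n_classes"],
            )
            for li, lay in enumerate(est._all_layers()):
                lay.W[...] = data[f"W{li}"]
                lay.b[...] = data[f"b{li}"]
        return est
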