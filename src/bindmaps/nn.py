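"""A compact, fully deterministic feed-forward network engine.

Supports exactly what the pathway simulations need: valid 3x3-style
convolutions (im2col + GEMM), 2x2 max-pooling, dense layers with ReLU,
inverted dropout, several independent softmax output heads trained with
summed cross-entropy, and Adam.  Everything is plain numpy, seeded through
``np.random.Generator``, so two runs with the same seed produce identical
weights bit for bit — no backend nondeterminism to document away.

Array convention: images are (batch, height, width, channels) float32.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conv2D", "MaxPool2", "Flatten", "Dense", "Dropout", "ReLU",
           "MultiHeadNet", "Adam", "fit", "FitHistory"]


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
        np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B, OH*OW, k*k*C) for a valid kxk window."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    b, oh, ow, c, _, _ = win.shape
    # -> (B, OH, OW, k, k, C) so the flattened patch is row-major spatial
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(b, oh * ow, k * k * c)


class Conv2D(Layer):
    """Valid kxk convolution followed by ReLU."""

    def __init__(self, in_ch: int, filters: int, k: int,
                 rng: np.random.Generator):
        self.k, self.in_ch, self.filters = k, in_ch, filters
        self.W = _he_init(rng, (k * k * in_ch, filters), k * k * in_ch)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._xshape = x.shape
        b, h, w, _ = x.shape
        oh, ow = h - self.k + 1, w - self.k + 1
        # one large GEMM over all batch patches
        self._cols = _im2col(x, self.k).reshape(b * oh * ow, -1)
        z = self._cols @ self.W + self.b
        self._mask = z > 0
        out = np.where(self._mask, z, 0.0)
        return out.reshape(b, oh, ow, self.filters)

    def backward(self, grad):
        b, oh, ow, f = grad.shape
        g = grad.reshape(b * oh * ow, f) * self._mask
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        # dx via col2im: scatter each patch gradient back
        gcols = g @ self.W.T  # (B*OH*OW, k*k*C)
        _, h, w, c = self._xshape
        dx = np.zeros(self._xshape, dtype=np.float32)
        gcols = gcols.reshape(b, oh, ow, self.k, self.k, c)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + oh, j:j + ow, :] += gcols[:, :, :, i, j, :]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._xshape = x.shape
        x4 = x[:, :h2 * 2, :w2 * 2, :].reshape(b, h2, 2, w2, 2, c)
        self._slices = (x4[:, :, 0, :, 0, :], x4[:, :, 0, :, 1, :],
                        x4[:, :, 1, :, 0, :], x4[:, :, 1, :, 1, :])
        a, bb, cc, d = self._slices
        self._out = np.maximum(np.maximum(a, bb), np.maximum(cc, d))
        return self._out

    def backward(self, grad):
        b, h2, w2, c = grad.shape
        dx4 = np.zeros((b, h2, 2, w2, 2, c), dtype=np.float32)
        # exact first-match routing (window scan order) without argmax
        taken = np.zeros(grad.shape, dtype=bool)
        for idx, s in zip(((0, 0), (0, 1), (1, 0), (1, 1)), self._slices):
            m = (s == self._out) & ~taken
            dx4[:, :, idx[0], :, idx[1], :] = m * grad
            taken |= m
        dx = np.zeros(self._xshape, dtype=np.float32)
        dx[:, :h2 * 2, :w2 * 2, :] = dx4.reshape(b, h2 * 2, w2 * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Affine layer, optionally followed by ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = True):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.relu = relu

    def forward(self, x, train):
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad):
        if self.relu:
            grad = grad * self._mask
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadNet:
    """A trunk of layers with several independent softmax heads.

    The trunk output feeds every head; the loss is the sum over heads of
    the per-head cross-entropy (equal weights), averaged over the batch.
    """

    def __init__(self, trunk: list[Layer], trunk_out: int,
                 head_classes: list[int], rng: np.random.Generator):
        self.trunk = trunk
        self.head_classes = list(head_classes)
        self.heads = [Dense(trunk_out, nc, rng, relu=False)
                      for nc in head_classes]

    # --- forward / backward -------------------------------------------------
    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.trunk:
            x = layer.forward(x, train)
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        feats = self.features(x, train)
        return [_softmax(h.forward(feats, train)) for h in self.heads]

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """y: (batch, n_heads) int class labels.  Fills every grad buffer."""
        b = x.shape[0]
        feats = self.features(x, train=True)
        dfeats = np.zeros_like(feats)
        loss = 0.0
        for h_i, head in enumerate(self.heads):
            probs = _softmax(head.forward(feats, train=True))
            rows = np.arange(b)
            loss -= float(np.log(probs[rows, y[:, h_i]] + 1e-12).sum()) / b
            dlogits = probs
            dlogits[rows, y[:, h_i]] -= 1.0
            dfeats += head.backward(dlogits / b)
        grad = dfeats
        for layer in reversed(self.trunk):
            grad = layer.backward(grad)
        return loss

    # --- parameter access ---------------------------------------------------
    def layers(self) -> list[Layer]:
        return self.trunk + self.heads

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads()]

    def trunk_params(self) -> list[np.ndarray]:
        return [p for layer in self.trunk for p in layer.params()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    def predict(self, x: np.ndarray, batch_size: int = 512) -> list[np.ndarray]:
        outs = None
        for i in range(0, x.shape[0], batch_size):
            batch = self.forward(x[i:i + batch_size], train=False)
            if outs is None:
                outs = [[] for _ in batch]
            for j, o in enumerate(batch):
                outs[j].append(o)
        return [np.concatenate(chunks) for chunks in outs]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (
            1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = 0.0


def _per_slot_accuracy(outputs: list[np.ndarray], y: np.ndarray) -> float:
    correct = sum(int((o.argmax(axis=1) == y[:, i]).sum())
                  for i, o in enumerate(outputs))
    return correct / (y.shape[0] * y.shape[1])


def fit(net: MultiHeadNet, x: np.ndarray, y: np.ndarray,
        x_val: np.ndarray, y_val: np.ndarray, *, batch_size: int = 256,
        lr: float = 1e-3, max_epochs: int = 50, patience: int = 10,
        rng: np.random.Generator | None = None,
        verbose: bool = False) -> FitHistory:
    """Mini-batch Adam training with early stopping on validation
    per-slot accuracy and best-weight restoration."""
    rng = rng or np.random.default_rng(0)
    opt = Adam(net.params(), lr=lr)
    hist = FitHistory()
    best_weights = net.get_weights()
    since_best = 0
    for epoch in range(max_epochs):
        order = rng.permutation(x.shape[0])
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            loss = net.loss_and_grads(x[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            opt.step(net.grads())
            epoch_loss += loss
            n_batches += 1
        val_acc = _per_slot_accuracy(net.predict(x_val), y_val)
        hist.train_loss.append(epoch_loss / max(n_batches, 1))
        hist.val_accuracy.append(val_acc)
        if verbose:
            print(f"epoch {epoch:3d} loss {hist.train_loss[-1]:.4f} "
                  f"val_acc {val_acc:.4f}")
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    net.set_weights(best_weights)
    return hist
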