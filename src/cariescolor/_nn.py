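"""Compact numpy neural-network core for the two neural classifiers.

Implements exactly what the pipeline needs, deterministically seeded:

* dense/ReLU layers with inverted dropout and Gaussian input noise,
* the focal loss -w_y (1 - p_y)^gamma log(p_y) with per-class weights,
* full-batch Adam with reduce-on-plateau learning-rate halving and
  early stopping on validation loss (best parameters restored),
* an MLP over flattened per-tooth feature vectors, and
* a Deep Sets network: a shared per-site encoder, attention pooling
  (softmax over a learned scalar score per site), and a classification
  head.  The pooled representation is a convex combination of the site
  embeddings, so tooth predictions are exactly invariant to site order.

The cohorts here are small (hundreds of teeth, tens of features), so
full-batch training is both fast and bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Scaler",
    "focal_loss_batch",
    "attention_pool",
    "MLPNet",
    "DeepSetsNet",
]

_PROB_FLOOR = 1e-12  # floor on p_y inside the loss; numeric safety


class Scaler:
    """Per-feature standardization fitted on training data only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        flat = X.reshape(-1, X.shape[-1])
        self.mean_ = flat.mean(axis=0)
        self.std_ = np.maximum(flat.std(axis=0), 1e-8)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def focal_loss_batch(
    logits: np.ndarray,
    y: np.ndarray,
    gamma: float,
    class_weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    loss_i = -w_{y_i} (1 - p_{y_i})^gamma log(p_{y_i}); gamma = 0
    recovers weighted cross-entropy.
    """
    n = logits.shape[0]
    p = _softmax(logits, axis=1)
    py = np.clip(p[np.arange(n), y], _PROB_FLOOR, 1.0)
    w = class_weights[y]
    om = np.clip(1.0 - py, _PROB_FLOOR, 1.0)  # (1 - p_y), floored
    loss = float(np.mean(-w * om**gamma * np.log(py)))
    # dL/dp_y, then chain through softmax: dp_y/dz_k = p_y (1[k=y] - p_k)
    g_py = w * (gamma * om ** (gamma - 1.0) * np.log(py) - om**gamma / py)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    dlogits = (g_py * py)[:, None] * (onehot - p) / n
    return loss, dlogits


def attention_pool(
    embeddings: np.ndarray,
    score_vector: np.ndarray | None = None,
    score_bias: float = 0.0,
) -> np.ndarray:
    """Attention-weighted sum of a set of embeddings.

    Each element gets a scalar score (dot product with ``score_vector``
    plus ``score_bias``; all-zero scores if no vector is given); weights
    are the softmax of the scores.  The output is a convex combination
    of the inputs and therefore invariant to their ordering.
    """
    H = np.asarray(embeddings, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("attention_pool expects a non-empty (m, d) array")
    if score_vector is None:
        s = np.full(H.shape[0], score_bias, dtype=float)
    else:
        s = H @ np.asarray(score_vector, dtype=float) + score_bias
    alpha = _softmax(s, axis=0)
    return alpha @ H


class _Adam:
    """Adam over a flat list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


class _BaseNet:
    """Shared training loop: Adam, plateau LR halving, early stopping."""

    def __init__(
        self,
        gamma: float,
        class_weights: np.ndarray,
        lr: float,
        max_epochs: int,
        patience: int,
        plateau_patience: int,
        seed: int,
    ) -> None:
        self.gamma = gamma
        self.class_weights = np.asarray(class_weights, dtype=float)
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.plateau_patience = plateau_patience
        self.rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []

    # subclasses implement
    def _forward_backward(self, X, y) -> tuple[float, list[np.ndarray]]:
        raise NotImplementedError

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _monitor_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        loss, _ = focal_loss_batch(
            self.predict_logits(X), y, self.gamma, self.class_weights
        )
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "_BaseNet":
        opt = _Adam(self.params, self.lr)
        monitor = (X_val, y_val) if X_val is not None and len(X_val) else (X, y)
        best = np.inf
        best_params = [p.copy() for p in self.params]
        stall = 0
        since_reduce = 0
        for _ in range(self.max_epochs):
            _, grads = self._forward_backward(X, y)
            opt.step(grads)
            val_loss = self._monitor_loss(*monitor)
            if val_loss < best - 1e-7:
                best = val_loss
                best_params = [p.copy() for p in self.params]
                stall = 0
                since_reduce = 0
            else:
                stall += 1
                since_reduce += 1
            if since_reduce >= self.plateau_patience:
                opt.lr *= 0.5  # reduce-on-plateau
                since_reduce = 0
            if stall >= self.patience:
                break
        for p, bp in zip(self.params, best_params):
            p[...] = bp
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.predict_logits(X), axis=1)


class MLPNet(_BaseNet):
    """Multilayer perceptron over flattened per-tooth feature vectors.

    Two ReLU hidden layers with inverted dropout, Gaussian noise added
    to the (standardized) inputs during training, focal loss.
    """

    def __init__(
        self,
        n_in: int,
        n_classes: int = 3,
        hidden: tuple[int, int] = (64, 32),
        dropout: float = 0.3,
        noise_sd: float = 0.05,
        gamma: float = 2.0,
        class_weights: np.ndarray | None = None,
        lr: float = 0.01,
        max_epochs: int = 600,
        patience: int = 20,
        plateau_patience: int = 10,
        seed: int = 42,
    ) -> None:
        if class_weights is None:
            class_weights = np.ones(n_classes)
        super().__init__(gamma, class_weights, lr, max_epochs, patience,
                         plateau_patience, seed)
        self.dropout = dropout
        self.noise_sd = noise_sd
        h1, h2 = hidden
        r = self.rng
        self.W1 = _he_init(r, n_in, h1)
        self.b1 = np.zeros(h1)
        self.W2 = _he_init(r, h1, h2)
        self.b2 = np.zeros(h2)
        self.W3 = _he_init(r, h2, n_classes)
        self.b3 = np.zeros(n_classes)
        self.params = [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        h1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        h2 = np.maximum(h1 @ self.W2 + self.b2, 0.0)
        return h2 @ self.W3 + self.b3

    def _forward_backward(self, X, y):
        r = self.rng
        keep = 1.0 - self.dropout
        Xn = X + r.normal(0.0, self.noise_sd, size=X.shape)
        z1 = Xn @ self.W1 + self.b1
        h1 = np.maximum(z1, 0.0)
        m1 = (r.random(h1.shape) < keep) / keep
        h1d = h1 * m1
        z2 = h1d @ self.W2 + self.b2
        h2 = np.maximum(z2, 0.0)
        m2 = (r.random(h2.shape) < keep) / keep
        h2d = h2 * m2
        logits = h2d @ self.W3 + self.b3
        loss, dlogits = focal_loss_batch(logits, y, self.gamma, self.class_weights)
        dW3 = h2d.T @ dlogits
        db3 = dlogits.sum(0)
        dh2 = (dlogits @ self.W3.T) * m2 * (z2 > 0)
        dW2 = h1d.T @ dh2
        db2 = dh2.sum(0)
        dh1 = (dh2 @ self.W2.T) * m1 * (z1 > 0)
        dW1 = Xn.T @ dh1
        db1 = dh1.sum(0)
        return loss, [dW1, db1, dW2, db2, dW3, db3]


class DeepSetsNet(_BaseNet):
    """Permutation-invariant set classifier over a tooth's 5 sites.

    A shared encoder embeds each site's feature block independently;
    the embeddings are aggregated by attention pooling (softmax over a
    learned scalar score per site); a small head maps the pooled
    representation to class logits.  Because pooling is a symmetric
    function of the site embeddings, the output is exactly invariant to
    any permutation of the input sites.
    """

    def __init__(
        self,
        n_in: int,
        n_classes: int = 3,
        encoder: tuple[int, int] = (32, 32),
        head: int = 32,
        dropout: float = 0.3,
        noise_sd: float = 0.05,
        gamma: float = 2.0,
        class_weights: np.ndarray | None = None,
        lr: float = 0.01,
        max_epochs: int = 600,
        patience: int = 20,
        plateau_patience: int = 10,
        seed: int = 42,
    ) -> None:
        if class_weights is None:
            class_weights = np.ones(n_classes)
        super().__init__(gamma, class_weights, lr, max_epochs, patience,
                         plateau_patience, seed)
        self.dropout = dropout
        self.noise_sd = noise_sd
        k1, k2 = encoder
        r = self.rng
        self.We1 = _he_init(r, n_in, k1)
        self.be1 = np.zeros(k1)
        self.We2 = _he_init(r, k1, k2)
        self.be2 = np.zeros(k2)
        self.att_v = r.normal(0.0, 0.1, size=k2)  # attention score vector
        self.att_c = np.zeros(1)
        self.Wh = _he_init(r, k2, head)
        self.bh = np.zeros(head)
        self.Wo = _he_init(r, head, n_classes)
        self.bo = np.zeros(n_classes)
        self.params = [
            self.We1, self.be1, self.We2, self.be2,
            self.att_v, self.att_c, self.Wh, self.bh, self.Wo, self.bo,
        ]

    def _encode(self, X: np.ndarray) -> np.ndarray:
        """X: (n, m, d) -> site embeddings (n, m, k2), no dropout."""
        n, m, d = X.shape
        flat = X.reshape(n * m, d)
        h1 = np.maximum(flat @ self.We1 + self.be1, 0.0)
        h2 = np.maximum(h1 @ self.We2 + self.be2, 0.0)
        return h2.reshape(n, m, -1)

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        H = self._encode(X)
        s = H @ self.att_v + self.att_c[0]
        alpha = _softmax(s, axis=1)
        z = (alpha[..., None] * H).sum(axis=1)
        h3 = np.maximum(z @ self.Wh + self.bh, 0.0)
        return h3 @ self.Wo + self.bo

    def _forward_backward(self, X, y):
        r = self.rng
        keep = 1.0 - self.dropout
        n, m, d = X.shape
        Xn = X + r.normal(0.0, self.noise_sd, size=X.shape)
        flat = Xn.reshape(n * m, d)
        z1 = flat @ self.We1 + self.be1
        h1 = np.maximum(z1, 0.0)
        m1 = (r.random(h1.shape) < keep) / keep
        h1d = h1 * m1
        z2 = h1d @ self.We2 + self.be2
        h2 = np.maximum(z2, 0.0)
        m2 = (r.random(h2.shape) < keep) / keep
        h2d = h2 * m2
        H = h2d.reshape(n, m, -1)
        s = H @ self.att_v + self.att_c[0]
        alpha = _softmax(s, axis=1)
        z = (alpha[..., None] * H).sum(axis=1)
        z3 = z @ self.Wh + self.bh
        h3 = np.maximum(z3, 0.0)
        m3 = (r.random(h3.shape) < keep) / keep
        h3d = h3 * m3
        logits = h3d @ self.Wo + self.bo
        loss, dlogits = focal_loss_batch(logits, y, self.gamma, self.class_weights)
        dWo = h3d.T @ dlogits
        dbo = dlogits.sum(0)
        dh3 = (dlogits @ self.Wo.T) * m3 * (z3 > 0)
        dWh = z.T @ dh3
        dbh = dh3.sum(0)
        dz = dh3 @ self.Wh.T  # (n, k2)
        # through attention pooling
        dalpha = np.einsum("nk,nik->ni", dz, H)
        dH = alpha[..., None] * dz[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dv = np.einsum("nik,ni->k", H, ds)
        dc = np.array([ds.sum()])
        dH = dH + ds[..., None] * self.att_v[None, None, :]
        # through shared encoder
        dh2 = dH.reshape(n * m, -1) * m2 * (z2 > 0)
        dWe2 = h1d.T @ dh2
        dbe2 = dh2.sum(0)
        dh1 = (dh2 @ self.We2.T) * m1 * (z1 > 0)
        dWe1 = flat.T @ dh1
        dbe1 = dh1.sum(0)
        return loss, [dWe1, dbe1, dWe2, dbe2, dv, dc, dWh, dbh, dWo, dbo]
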