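"""Dense text classifier: embedding -> flatten -> hidden -> output.

A deliberately small feed-forward network trained with back-propagation,
sized for short dosing instructions.  Token ids pass through a trainable
embedding, the embedded sequence is flattened, followed by one rectified
hidden layer and either a 1-node sigmoid head (binary) or a softmax head
(multiclass).  Optimised with Adam on cross-entropy.  All randomness
(weight init, epoch shuffling) flows from a single integer seed, and all
arithmetic is plain numpy, so retraining with the same data, config and
seed reproduces every weight bit-exactly on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrainConfig:
    embedding_dim: int = 32
    hidden_units: int = 64
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_split: float = 0.1


class DenseTextNet:
    """Embedding + single-hidden-layer classifier over padded token ids."""

    def __init__(
        self,
        vocab_size: int,
        seq_len: int,
        n_outputs: int,
        config: TrainConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.vocab_size = vocab_size
        self.seq_len = seq_len
        self.n_outputs = n_outputs
        self.config = config or TrainConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        d, h = self.config.embedding_dim, self.config.hidden_units
        flat = seq_len * d

        def glorot(fan_in, fan_out, shape):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        self.emb = glorot(vocab_size, d, (vocab_size, d))
        self.W1 = glorot(flat, h, (flat, h))
        self.b1 = np.zeros(h)
        self.W2 = glorot(h, n_outputs, (h, n_outputs))
        self.b2 = np.zeros(n_outputs)
        self._rng = rng
        self.history: list[dict] = []

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray):
        flat = self.emb[X].reshape(X.shape[0], -1)
        pre = flat @ self.W1 + self.b1
        hid = np.maximum(pre, 0.0)
        logits = hid @ self.W2 + self.b2
        if self.n_outputs == 1:
            prob = 1.0 / (1.0 + np.exp(-logits))
        else:
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            prob = e / e.sum(axis=1, keepdims=True)
        return flat, pre, hid, prob

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities: shape (n,) for the 1-node head, (n, k) otherwise."""
        X = np.asarray(X, dtype=np.int64)
        prob = self._forward(X)[3]
        return prob[:, 0] if self.n_outputs == 1 else prob

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DenseTextNet":
        """Train with Adam on (binary) cross-entropy; keeps a per-epoch
        loss history for audit."""
        cfg = self.config
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y)
        n = X.shape[0]
        n_val = int(round(n * cfg.validation_split))
        perm = self._rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]

        params = [self.emb, self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        step = 0

        for epoch in range(cfg.epochs):
            order = self._rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(Xtr), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                grads, loss = self._backward(xb, yb)
                losses.append(loss)
                step += 1
                lr_t = cfg.learning_rate * (
                    np.sqrt(1 - b2m**step) / (1 - b1m**step)
                )
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1m
                    mi += (1 - b1m) * g
                    vi *= b2m
                    vi += (1 - b2m) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
            entry = {"epoch": epoch, "loss": float(np.mean(losses))}
            if n_val:
                entry["val_loss"] = float(
                    self._loss(X[val_idx], y[val_idx])
                )
            self.history.append(entry)
        return self

    def _loss(self, X, y) -> float:
        prob = self._forward(X)[3]
        if self.n_outputs == 1:
            p = np.clip(prob[:, 0], 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        p = np.clip(prob[np.arange(len(y)), y], 1e-12, None)
        return float(-np.mean(np.log(p)))

    def _backward(self, X, y):
        flat, pre, hid, prob = self._forward(X)
        n = X.shape[0]
        if self.n_outputs == 1:
            p = np.clip(prob[:, 0], 1e-12, 1 - 1e-12)
            loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            dlogits = (prob - y[:, None]) / n
        else:
            p = np.clip(prob[np.arange(n), y], 1e-12, None)
            loss = -np.mean(np.log(p))
            dlogits = prob.copy()
            dlogits[np.arange(n), y] -= 1.0
            dlogits /= n
        dW2 = hid.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dhid = dlogits @ self.W2.T
        dpre = dhid * (pre > 0)
        dW1 = flat.T @ dpre
        db1 = dpre.sum(axis=0)
        dflat = dpre @ self.W1.T
        demb = np.zeros_like(self.emb)
        np.add.at(demb, X.ravel(), dflat.reshape(-1, self.emb.shape[1]))
        return [demb, dW1, db1, dW2, db2], float(loss)
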