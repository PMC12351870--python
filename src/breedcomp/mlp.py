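"""Multi-layer perceptron for genomic breed composition prediction.

The network maps one-hot genotype features through ReLU hidden layers
(default 1024-512-256) to a softmax output over the breed panel, so every
prediction is automatically a valid ancestry vector on the probability
simplex. Under the multi-output regression framework the loss is the mean
squared error between the softmax output and the GBC target vectors —
*not* cross-entropy against class labels — which trains the network to
quantify ancestry proportions rather than to separate categories. The
classification-framework variant shares the architecture and swaps in
cross-entropy against one-hot class targets.

Training is plain backpropagation with Adam, optional inverted dropout on
the hidden activations, L2 weight decay, and early stopping on a held-out
validation split. All randomness (initialisation, batch order, dropout,
validation split) flows from ``random_state``, so a fit is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

_DTYPE = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


class MLPGBCRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward network predicting genomic breed composition.

    Parameters
    ----------
    hidden_sizes : tuple of int
        Hidden-layer widths; default is the three-layer 1024-512-256 stack.
    framework : {"regression", "classification"}
        ``regression``: targets are ancestry vectors, loss is MSE on the
        softmax output. ``classification``: targets are one-hot class
        labels (purebreds + hybrid), loss is cross-entropy.
    lr, dropout, input_dropout, l2 : float
        Adam learning rate, hidden-layer dropout probability, input-layer
        (SNP-block) dropout probability, L2 weight decay strength.
    max_epochs, patience, tol : early stopping — training halts when the
        validation loss has not improved by more than ``tol`` for
        ``patience`` consecutive epochs; the best-validation weights are
        restored.
    validation_fraction : float
        Fraction of the training rows held out for early stopping.
    batch_size : int
    anneal_epochs, anneal_lr_factor : dropout annealing — after the
        regularised phase, training resumes from the best-validation
        weights *without* dropout for up to ``anneal_epochs`` epochs at
        ``lr * anneal_lr_factor``; the annealed snapshot is kept when its
        validation loss is within one standard error of the best. This
        polishes the near-zero GBC components, whose MSE gradients vanish
        quadratically and are otherwise noise-limited under dropout.
    breeds : tuple of str or None
        Breed panel (regression) or class names (classification) recorded
        in the fitted model; inferred as ``class0..`` when None.
    random_state : int
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (1024, 512, 256),
        framework: str = "regression",
        lr: float = 1e-3,
        dropout: float = 0.4,
        input_dropout: float = 0.0,
        l2: float = 1e-4,
        max_epochs: int = 100,
        patience: int = 8,
        tol: float = 1e-6,
        validation_fraction: float = 0.1,
        batch_size: int = 256,
        anneal_epochs: int = 15,
        anneal_lr_factor: float = 1.0,
        breeds: tuple[str, ...] | None = None,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.framework = framework
        self.lr = lr
        self.dropout = dropout
        self.input_dropout = input_dropout
        self.l2 = l2
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.validation_fraction = validation_fraction
        self.batch_size = batch_size
        self.anneal_epochs = anneal_epochs
        self.anneal_lr_factor = anneal_lr_factor
        self.breeds = breeds
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_params(self, d_in: int, d_out: int, rng: np.random.Generator):
        sizes = [d_in, *self.hidden_sizes, d_out]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialisation for the ReLU stack; the softmax layer gets it too
            std = np.sqrt(2.0 / fan_in)
            weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)).astype(_DTYPE))
            biases.append(np.zeros(fan_out, dtype=_DTYPE))
        return weights, biases

    def _forward(self, x, weights, biases, rng=None, dropout=0.0, input_dropout=0.0):
        """Returns (softmax output, cached hidden activations, dropout masks)."""
        if rng is not None and input_dropout > 0.0:
            # SNP-level feature bagging: forces the network to spread
            # evidence over redundant markers, taming per-animal outliers
            mask = (rng.random(x.shape) >= input_dropout).astype(_DTYPE)
            x = x * mask / _DTYPE(1.0 - input_dropout)
        acts = [x]
        masks = []
        a = x
        n_hidden = len(weights) - 1
        for l in range(n_hidden):
            a = np.maximum(a @ weights[l] + biases[l], 0.0)
            if rng is not None and dropout > 0.0:
                mask = (rng.random(a.shape) >= dropout).astype(_DTYPE)
                a = a * mask / _DTYPE(1.0 - dropout)
                masks.append(mask)
            acts.append(a)
        p = softmax(a @ weights[-1] + biases[-1])
        return p, acts, masks

    def _data_loss(self, p, y):
        if self.framework == "regression":
            return float(np.mean((p - y) ** 2))
        return float(-np.mean(np.sum(y * np.log(np.clip(p, 1e-12, None)), axis=1)))

    def _output_grad(self, p, y):
        n, k = p.shape
        if self.framework == "regression":
            g = (2.0 / (n * k)) * (p - y)
            # softmax Jacobian applied to the MSE gradient
            return p * (g - (g * p).sum(axis=1, keepdims=True))
        return (p - y) / n

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=_DTYPE)
        y = np.asarray(y, dtype=_DTYPE)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be 2-D with aligned rows")
        if self.framework not in ("regression", "classification"):
            raise ValueError(f"unknown framework {self.framework!r}")
        n, d_in = X.shape
        k = y.shape[1]
        if int((y.max(axis=0) > 0).sum()) < 2:
            raise ValueError("degenerate targets: fewer than 2 breeds/classes represented")

        rng = np.random.default_rng(self.random_state)
        # validation split for early stopping
        order = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        if n_val >= n:
            raise ValueError("validation split leaves no training rows")
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_tr, y_tr = X[tr_idx], y[tr_idx]
        x_val, y_val = X[val_idx], y[val_idx]

        weights, biases = self._init_params(d_in, k, rng)
        state = {
            "m_w": [np.zeros_like(w) for w in weights],
            "v_w": [np.zeros_like(w) for w in weights],
            "m_b": [np.zeros_like(b) for b in biases],
            "v_b": [np.zeros_like(b) for b in biases],
            "t": 0,
        }
        self.loss_curve_, self.val_loss_curve_ = [], []

        def train_phase(n_epochs, lr, dropout, patience):
            """Run one training phase; returns (best val loss, best snapshot)."""
            best_val = np.inf
            best = None
            stall = 0
            b1, b2, eps = 0.9, 0.999, 1e-8
            for epoch in range(n_epochs):
                perm = rng.permutation(len(x_tr))
                epoch_loss = 0.0
                for start in range(0, len(perm), self.batch_size):
                    idx = perm[start : start + self.batch_size]
                    xb, yb = x_tr[idx], y_tr[idx]
                    in_drop = self.input_dropout if dropout > 0 else 0.0
                    p, acts, masks = self._forward(
                        xb, weights, biases,
                        rng=rng if dropout > 0 or in_drop > 0 else None,
                        dropout=dropout, input_dropout=in_drop,
                    )
                    loss = self._data_loss(p, yb)
                    if not np.isfinite(loss):
                        raise TrainingDivergedError(
                            f"non-finite loss at epoch {epoch}, batch "
                            f"{start // self.batch_size} (lr={lr}); lower the learning rate"
                        )
                    epoch_loss += loss * len(idx)

                    delta = self._output_grad(p, yb).astype(_DTYPE)
                    grads_w = [None] * len(weights)
                    grads_b = [None] * len(biases)
                    for l in range(len(weights) - 1, -1, -1):
                        grads_w[l] = acts[l].T @ delta + _DTYPE(self.l2) * weights[l]
                        grads_b[l] = delta.sum(axis=0)
                        if l > 0:
                            delta = delta @ weights[l].T
                            delta *= acts[l] > 0  # ReLU gate (dropout folded into acts)
                            if masks:
                                delta *= masks[l - 1] / _DTYPE(1.0 - dropout)

                    state["t"] += 1
                    t = state["t"]
                    lr_t = lr * np.sqrt(1 - b2**t) / (1 - b1**t)
                    for l in range(len(weights)):
                        state["m_w"][l] = b1 * state["m_w"][l] + (1 - b1) * grads_w[l]
                        state["v_w"][l] = b2 * state["v_w"][l] + (1 - b2) * grads_w[l] ** 2
                        weights[l] -= (
                            lr_t * state["m_w"][l] / (np.sqrt(state["v_w"][l]) + eps)
                        ).astype(_DTYPE)
                        state["m_b"][l] = b1 * state["m_b"][l] + (1 - b1) * grads_b[l]
                        state["v_b"][l] = b2 * state["v_b"][l] + (1 - b2) * grads_b[l] ** 2
                        biases[l] -= (
                            lr_t * state["m_b"][l] / (np.sqrt(state["v_b"][l]) + eps)
                        ).astype(_DTYPE)

                self.loss_curve_.append(epoch_loss / len(x_tr))
                p_val, _, _ = self._forward(x_val, weights, biases)
                val_loss = self._data_loss(p_val, y_val)
                self.val_loss_curve_.append(val_loss)

                if val_loss < best_val - self.tol:
                    best_val = val_loss
                    best = ([w.copy() for w in weights], [b.copy() for b in biases])
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
            if best is None:
                best_val = val_loss
                best = ([w.copy() for w in weights], [b.copy() for b in biases])
            return best_val, best

        best_val, best = train_phase(self.max_epochs, self.lr, self.dropout, self.patience)
        if self.anneal_epochs and self.dropout > 0.0:
            # dropout annealing: resume from the best-validation weights and
            # polish without dropout at a reduced rate — the regularised
            # phase sets the representation, this phase tightens the small
            # GBC components whose MSE gradients are noise-limited. The
            # annealed snapshot is kept under a one-standard-error rule:
            # validation differences within the SE of the loss estimate are
            # noise, and the annealed weights are the deployment-matched ones.
            for l in range(len(weights)):
                weights[l][...] = best[0][l]
                biases[l][...] = best[1][l]
            p_val, _, _ = self._forward(x_val, weights, biases)
            if self.framework == "regression":
                per_sample = np.mean((p_val - y_val) ** 2, axis=1)
            else:
                per_sample = -np.sum(
                    y_val * np.log(np.clip(p_val, 1e-12, None)), axis=1
                )
            val_se = float(per_sample.std(ddof=1) / np.sqrt(len(per_sample)))
            anneal_val, anneal_best = train_phase(
                self.anneal_epochs, self.lr * self.anneal_lr_factor, 0.0, self.patience
            )
            self.anneal_val_loss_ = float(anneal_val)
            self.anneal_accepted_ = bool(anneal_val <= best_val + val_se)
            if self.anneal_accepted_:
                best_val, best = anneal_val, anneal_best

        self.weights_, self.biases_ = best
        self.n_features_in_ = d_in
        self.n_outputs_ = k
        self.breeds_ = tuple(self.breeds) if self.breeds is not None else tuple(
            f"class{i}" for i in range(k)
        )
        if len(self.breeds_) != k:
            raise ValueError(
                f"breeds lists {len(self.breeds_)} names but targets have {k} columns"
            )
        self.n_epochs_ = len(self.loss_curve_)
        self.best_val_loss_ = float(best_val)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=_DTYPE)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        p, _, _ = self._forward(X, self.weights_, self.biases_)
        return p.astype(np.float64)

    predict_gbc = predict
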