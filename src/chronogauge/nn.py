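"""The base neural sub-predictor.

A small fully connected network (three hidden ReLU layers, two linear
output nodes) maps a scaled expression vector to the sine/negated-cosine
encoding of circadian time.  Training minimises the angular cost
``1 - cosine similarity`` between encoded truth and raw outputs, which
respects the 24-h modulus and makes the output scale irrelevant; an L2
penalty regularises the weights.  Optimisation is Adam with seeded
minibatch shuffling, so a given seed reproduces weights bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .timecodec import (
    decode_time,
    encode_time,
    mean_absolute_circular_error,
    theta_loss,
    theta_loss_grad,
)


@dataclass
class Hyperparams:
    """Tunable training knobs for one sub-predictor."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    l2_factor: float = 1e-4
    hidden_sizes: tuple = (32, 16, 8)
    epochs: int = 300
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.l2_factor < 0:
            raise ValueError("invalid hyperparameters")
        if len(self.hidden_sizes) != 3:
            raise ValueError("exactly 3 hidden layers are required")


class CyclicMLPRegressor(RegressorMixin, BaseEstimator):
    """MLP regressor on the unit circle of time-of-day.

    Parameters mirror :class:`Hyperparams`.  ``fit`` takes ``y`` in
    minutes-since-midnight (any real values, reduced mod 1440);
    ``predict`` returns minutes on [0, 1440).

    Attributes
    ----------
    coefs_, intercepts_ : list of ndarray
        Trained weights and biases per layer.
    loss_curve_ : list of float
        Full-batch angular loss per epoch.
    """

    def __init__(self, hidden_sizes=(32, 16, 8), learning_rate=1e-3,
                 batch_size=16, l2_factor=1e-4, epochs=300, seed=0,
                 n_restarts=1):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.l2_factor = l2_factor
        self.epochs = epochs
        self.seed = seed
        self.n_restarts = n_restarts

    # -- internals ---------------------------------------------------------

    def _forward(self, X, coefs, intercepts):
        acts = [X]
        h = X
        for W, b in zip(coefs[:-1], intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        out = h @ coefs[-1] + intercepts[-1]
        acts.append(out)
        return acts

    def _backward(self, acts, y_sc, coefs):
        grads_W, grads_b = [], []
        delta = theta_loss_grad(y_sc, acts[-1])  # (n, 2), already /n
        for li in range(len(coefs) - 1, -1, -1):
            a_prev = acts[li]
            gW = a_prev.T @ delta + 2.0 * self.l2_factor * coefs[li]
            gb = delta.sum(axis=0)
            grads_W.append(gW)
            grads_b.append(gb)
            if li > 0:
                delta = (delta @ coefs[li].T) * (acts[li] > 0.0)
        return grads_W[::-1], grads_b[::-1]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        """Train, restarting from ``n_restarts`` seeded inits and keeping
        the lowest final training loss (the angular objective has poor
        local minima on small datasets)."""
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if len(np.unique(np.mod(y, 1440.0))) < 2:
            raise ValueError("training requires at least 2 distinct timepoints")
        best = None
        for r in range(max(1, self.n_restarts)):
            state = self._fit_once(X, y, self.seed + 7919 * r)
            if self.epochs == 0:
                best = state
                break
            if best is None or state[2][-1] < best[2][-1]:
                best = state
        self.coefs_, self.intercepts_, self.loss_curve_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_once(self, X, y, seed):
        rng = np.random.default_rng(seed)
        sizes = [X.shape[1], *self.hidden_sizes, 2]
        coefs = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        intercepts = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        y_sc = encode_time(y)

        if self.epochs == 0:
            warnings.warn("epochs=0: returning an initialised, unfit model")
        # Adam state
        mW = [np.zeros_like(W) for W in coefs]
        vW = [np.zeros_like(W) for W in coefs]
        mb = [np.zeros_like(b) for b in intercepts]
        vb = [np.zeros_like(b) for b in intercepts]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_step = 0
        n = X.shape[0]
        bs = min(self.batch_size, n)
        loss_curve = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                acts = self._forward(X[idx], coefs, intercepts)
                gW, gb = self._backward(acts, y_sc[idx], coefs)
                t_step += 1
                lr_t = self.learning_rate * np.sqrt(1 - beta2**t_step) / (1 - beta1**t_step)
                for i in range(len(coefs)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    coefs[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                    intercepts[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
            loss_curve.append(theta_loss(y_sc, self._forward(X, coefs, intercepts)[-1]))
        if not loss_curve:
            loss_curve = [theta_loss(y_sc, self._forward(X, coefs, intercepts)[-1])]
        return coefs, intercepts, loss_curve

    def predict_sc(self, X) -> np.ndarray:
        """Raw (s, c) outputs, arbitrary magnitude."""
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        out = self._forward(X, self.coefs_, self.intercepts_)[-1]
        # a numerically zero output carries no direction; nudge to a fixed one
        norms = np.hypot(out[:, 0], out[:, 1])
        out[norms == 0.0] = (1.0, 0.0)
        return out

    def predict(self, X) -> np.ndarray:
        """Predicted circadian time in minutes on [0, 1440)."""
        return decode_time(self.predict_sc(X))

    def final_loss(self) -> float:
        check_is_fitted(self, "coefs_")
        return self.loss_curve_[-1] if self.loss_curve_ else np.inf


def time_stratified_folds(times_min, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold labels keeping replicates of a timepoint together.

    Unique time labels are ordered around the clock from a seeded random
    start and dealt round-robin into k folds, so every fold spans the
    cycle and no timepoint leaks across folds.
    """
    times_min = np.mod(np.asarray(times_min, dtype=float), 1440.0)
    uniq = np.unique(times_min)
    if k > len(times_min):
        raise ValueError(f"k={k} exceeds n={len(times_min)} samples")
    rng = np.random.default_rng(seed)
    start = rng.integers(0, len(uniq))
    offset = rng.integers(0, k)
    order = np.roll(np.argsort(uniq), -start)
    fold_of_time = {uniq[j]: (i + offset) % k for i, j in enumerate(order)}
    return np.array([fold_of_time[t] for t in times_min])


def cv_mae(X, y_min, estimator_factory, k: int = 5, seed: int = 0,
           folds=None) -> float:
    """Fivefold cross-validated mean absolute circular error (minutes).

    ``estimator_factory()`` must return an unfitted estimator with the
    ``fit``/``predict`` (minutes) contract.  ``folds`` may supply a
    precomputed fold-label array so repeated evaluations are paired.
    """
    X = np.asarray(X, dtype=float)
    y_min = np.asarray(y_min, dtype=float)
    if folds is None:
        folds = time_stratified_folds(y_min, k=k, seed=seed)
    fold_ids = np.unique(folds)
    if len(fold_ids) < 2:
        raise ValueError("need at least 2 folds")
    maes = []
    for f in fold_ids:
        test = folds == f
        if test.all() or not test.any():
            continue
        est = estimator_factory()
        est.fit(X[~test], y_min[~test])
        pred = est.predict(X[test])
        maes.append(mean_absolute_circular_error(pred, y_min[test]))
    return float(np.mean(maes))
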