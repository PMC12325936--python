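"""Cyclic encoding of time-of-day and circular statistics.

A time-of-day lives on a 1440-minute circle.  It is represented to the
regressors as the pair ``(s, c)`` where

    s = sin(2*pi*h/24 + pi/2)
    c = -cos(2*pi*h/24 + pi/2)

with ``h`` the time in hours.  Midnight encodes to (1, 0) and 06:00 to
(0, 1).  The decoder inverts this map via ``atan2`` and is invariant to
positive rescaling of the vector, so raw (unnormalised) network outputs
decode directly.  The training loss is ``1 - cosine similarity`` between
true and predicted vectors, so antipodal predictions cost 2 and exact
ones cost 0, and the loss shares the decoder's scale invariance.
"""

from __future__ import annotations

import warnings

import numpy as np

MINUTES_PER_DAY = 1440.0
HALF_DAY = 720.0

#: norm floor guarding the cosine similarity against zero predictions
EPS_NORM = 1e-12


class DegenerateCircularMeanWarning(UserWarning):
    """Resultant vector of a circular mean is numerically zero."""


def _as_minutes(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time-of-day values must be finite")
    return np.mod(t, MINUTES_PER_DAY)


def encode_time(minutes) -> np.ndarray:
    """Encode minutes-since-midnight to unit-circle ``(s, c)`` pairs.

    Parameters
    ----------
    minutes : scalar or array-like
        Times in minutes; any real value, reduced modulo 1440.

    Returns
    -------
    ndarray, shape (..., 2)
        Unit vectors ``[s, c]``.
    """
    t = _as_minutes(minutes)
    theta = 2.0 * np.pi * (t / 60.0) / 24.0 + np.pi / 2.0
    return np.stack([np.sin(theta), -np.cos(theta)], axis=-1)


def decode_time(sc) -> np.ndarray:
    """Decode ``(s, c)`` vectors back to minutes on [0, 1440).

    Exact inverse of :func:`encode_time` and invariant to positive
    rescaling of the input vector.  Raises on the zero vector, which
    carries no angular information.
    """
    sc = np.asarray(sc, dtype=float)
    s, c = sc[..., 0], sc[..., 1]
    norm = np.hypot(s, c)
    if np.any(norm <= 0.0) or not np.all(np.isfinite(norm)):
        raise ValueError("cannot decode a zero or non-finite (s, c) vector")
    theta = np.arctan2(s, -c)
    hours = np.mod((theta - np.pi / 2.0) * 24.0 / (2.0 * np.pi), 24.0)
    return np.mod(hours * 60.0, MINUTES_PER_DAY)


def signed_circular_error(pred, true) -> np.ndarray:
    """Signed circular difference pred - true in minutes on (-720, 720].

    Positive values are advanced (early-running) estimates.  The
    antipodal case maps to +720 exactly (deterministic tie-break).
    """
    pred = _as_minutes(pred)
    true = _as_minutes(true)
    delta = np.mod(pred - true + HALF_DAY, MINUTES_PER_DAY) - HALF_DAY
    delta = np.where(delta == -HALF_DAY, HALF_DAY, delta)
    return delta


def circular_mean(minutes, degenerate="warn") -> float:
    """Circular mean of times in minutes.

    Decodes the vector sum of the encodings.  When the resultant vector
    length divided by n falls below 1e-6 the mean direction is
    meaningless; this is flagged rather than silently returned.

    Parameters
    ----------
    minutes : array-like
        Non-empty collection of times in minutes.
    degenerate : {"warn", "raise"}
        Behaviour when the resultant is degenerate.
    """
    t = _as_minutes(minutes)
    if t.size == 0:
        raise ValueError("circular_mean of an empty collection")
    vec = encode_time(t).reshape(-1, 2).sum(axis=0)
    r = np.hypot(vec[0], vec[1]) / t.size
    if r < 1e-6:
        msg = f"degenerate circular mean: resultant length {r:.2e}"
        if degenerate == "raise":
            raise ValueError(msg)
        warnings.warn(msg, DegenerateCircularMeanWarning, stacklevel=2)
        if not np.hypot(vec[0], vec[1]) > 0.0:
            # perfectly balanced: fall back to angle of first element
            vec = encode_time(t.ravel()[0])
    return float(decode_time(vec))


def theta_loss(true_sc, pred_sc) -> float:
    """Mean angular cost ``1 - cos_sim(true, pred)`` over a batch.

    Both arguments are arrays of shape (n, 2).  True vectors come from
    :func:`encode_time`; predicted vectors may have any nonzero
    magnitude (the cost is scale invariant).  Range [0, 2].
    """
    true_sc = np.asarray(true_sc, dtype=float).reshape(-1, 2)
    pred_sc = np.asarray(pred_sc, dtype=float).reshape(-1, 2)
    if true_sc.shape != pred_sc.shape or true_sc.shape[0] < 1:
        raise ValueError("batches must be equal-length and non-empty")
    tn = np.linalg.norm(true_sc, axis=1)
    pn = np.linalg.norm(pred_sc, axis=1)
    sim = (true_sc * pred_sc).sum(axis=1) / np.maximum(tn * pn, EPS_NORM)
    return float(np.mean(1.0 - sim))


def theta_loss_grad(true_sc, pred_sc) -> np.ndarray:
    """Gradient of :func:`theta_loss` w.r.t. the predicted vectors.

    For a sample with true unit direction u and prediction p,
    d/dp [1 - u.p/(|u||p|)] = -(u/(|u||p|)) + (u.p) p / (|u| |p|^3),
    averaged over the batch.
    """
    true_sc = np.asarray(true_sc, dtype=float).reshape(-1, 2)
    pred_sc = np.asarray(pred_sc, dtype=float).reshape(-1, 2)
    n = true_sc.shape[0]
    tn = np.linalg.norm(true_sc, axis=1, keepdims=True)
    pn = np.maximum(np.linalg.norm(pred_sc, axis=1, keepdims=True), EPS_NORM)
    dot = (true_sc * pred_sc).sum(axis=1, keepdims=True)
    grad = -true_sc / (tn * pn) + dot * pred_sc / (tn * pn**3)
    return grad / n


def mean_absolute_circular_error(pred, true) -> float:
    """MAE in minutes of predicted vs true times on the 1440-min circle."""
    return float(np.mean(np.abs(signed_circular_error(pred, true))))


def median_absolute_circular_error(pred, true) -> float:
    """MdAE in minutes of predicted vs true times."""
    return float(np.median(np.abs(signed_circular_error(pred, true))))
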