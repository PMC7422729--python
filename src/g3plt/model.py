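"""Core probability model.

The G3PLT (general three-parameter logistic model with time) extends the
classical 3PL item response model by adding an extra exponential term for
the transformed response time to the logistic denominator:

    p_ij = c_j + (1 - c_j) / (1 + exp(-D a_j (theta_i - b_j)) + exp(-t*_ij))

where ``theta_i`` is the examinee's latent ability, ``a_j``/``b_j``/``c_j``
are the item discrimination, difficulty and guessing parameters, ``D`` is
the usual logistic scaling constant, and ``t*_ij`` is a standardized
log response time shifted by a test-level weight W.  Large ``t*`` removes
the time term and recovers the plain 3PL; ``t* -> -inf`` drives the
probability down to the guessing floor ``c_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ItemParams",
    "TimeTransform",
    "TimeMatrix",
    "ResponseMatrix",
    "transform_times",
    "response_probability",
    "response_probability_3pl",
    "ability_given_probability",
    "time_given_probability",
    "log_likelihood",
]

# exp() argument clamp and probability clamp used throughout the package
_EXP_CLIP = 700.0
_P_EPS = 1e-12


@dataclass
class ItemParams:
    """Per-item discrimination, difficulty and guessing triples.

    Parameters
    ----------
    a : array-like
        Discrimination, strictly positive.
    b : array-like
        Difficulty on the ability scale.
    c : array-like
        Guessing probability (lower asymptote), in ``[0, 1)``.
    D : float
        Logistic scaling constant, default 1.7.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    D: float = 1.7

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if not (self.a.shape == self.b.shape == self.c.shape):
            raise ValueError("a, b, c must have equal length")
        if np.any(self.a <= 0):
            raise ValueError("discrimination parameters must be positive")
        if np.any((self.c < 0) | (self.c >= 1)):
            raise ValueError("guessing parameters must lie in [0, 1)")
        if self.D <= 0:
            raise ValueError("D must be positive")

    @property
    def J(self) -> int:
        return self.a.size


@dataclass
class TimeTransform:
    """Metadata of the log-time standardization ``t* = (log t - mu_t)/sigma_t + W``."""

    mu_t: float
    sigma_t: float
    W: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_t <= 0:
            raise ValueError("sigma_t must be positive")
        if not (0.0 <= self.W <= 8.0):
            raise ValueError("time weight W must lie in [0, 8]")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        return (np.log(raw) - self.mu_t) / self.sigma_t + self.W


@dataclass
class TimeMatrix:
    """Raw and/or transformed response times for N examinees by J items."""

    transformed: np.ndarray
    raw: Optional[np.ndarray] = None
    transform: Optional[TimeTransform] = None

    def __post_init__(self) -> None:
        self.transformed = np.asarray(self.transformed, dtype=float)
        if not np.all(np.isfinite(self.transformed)):
            raise ValueError("transformed times must be finite")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)
            if np.any(self.raw <= 0):
                raise ValueError("raw times must be strictly positive")


@dataclass
class ResponseMatrix:
    """Binary correctness indicators, 1 = correct."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("responses must be 0/1 (1 = correct)")
        self.y = self.y.astype(np.int8)

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]


def transform_times(raw, mu_t="auto", sigma_t="auto", W: float = 0.0):
    """Standardize log response times and add the time weight.

    ``t*_ij = (log t_ij - mu_t) / sigma_t + W`` with natural logs.  With
    ``mu_t="auto"``/``sigma_t="auto"`` the location and scale are the mean
    and SD of the pooled log-times of the whole matrix, so the standardized
    part of ``t*`` is mean-zero, unit-SD.

    Returns
    -------
    (transformed, TimeTransform)
    """
    raw = np.asarray(raw, dtype=float)
    bad = np.argwhere(~(raw > 0))
    if bad.size:
        i, j = (int(v) for v in bad[0])
        raise ValueError(f"nonpositive response time at cell ({i}, {j})")
    logs = np.log(raw)
    if mu_t == "auto":
        mu_t = float(logs.mean())
    if sigma_t == "auto":
        sigma_t = float(logs.std(ddof=0))
        if sigma_t == 0:
            raise ValueError("constant response times: sigma_t would be zero")
    tf = TimeTransform(mu_t=float(mu_t), sigma_t=float(sigma_t), W=float(W))
    return tf.apply(raw), tf


def _kernel(theta, items: ItemParams, t_star):
    """Denominator terms: exp(-D a (theta - b)) [+ exp(-t*)].

    ``theta`` may be scalar or length-N; broadcasting yields N x J.
    ``t_star`` may be None (3PL), scalar, length-J or N x J.
    """
    theta = np.asarray(theta, dtype=float)
    z = items.D * items.a * (np.atleast_1d(theta)[:, None] - items.b)
    denom = 1.0 + np.exp(np.clip(-z, -_EXP_CLIP, _EXP_CLIP))
    if t_star is not None:
        t_star = np.asarray(t_star, dtype=float)
        denom = denom + np.exp(np.clip(-t_star, -_EXP_CLIP, _EXP_CLIP))
    return denom


def response_probability(theta, items: ItemParams, t_star):
    """Correct-response probability under the G3PLT model.

    Vectorized over persons x items: returns an array broadcast from
    ``theta`` (scalar or length N) against the J items, with ``t_star``
    scalar, length-J, or N x J.  Strictly increasing in ``theta`` and in
    ``t_star``; bounded in ``(c_j, 1)``.
    """
    denom = _kernel(theta, items, t_star)
    p = items.c + (1.0 - items.c) / denom
    return p[0] if np.isscalar(theta) or np.ndim(theta) == 0 else p


def response_probability_3pl(theta, items: ItemParams):
    """Plain 3PL correct-response probability (the ``t* -> +inf`` limit)."""
    return response_probability(theta, items, None)


def ability_given_probability(items: ItemParams, p):
    """Invert the 3PL curve: the ability at which the no-time-pressure
    (large ``t*``) response probability equals ``p``.

    ``theta = b - log((1 - p)/(p - c)) / (D a)``; requires ``c < p < 1``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= items.c) or np.any(p >= 1):
        raise ValueError("probability must lie strictly between c and 1")
    return items.b - np.log((1.0 - p) / (p - items.c)) / (items.D * items.a)


def time_given_probability(items: ItemParams, p):
    """Transformed-time horizontal asymptote of the equiprobability curve.

    As ability grows without bound the probability tends to
    ``c + (1-c)/(1 + exp(-t*))``; solving for ``t*`` at probability ``p``
    gives ``t* = -log((1 - p)/(p - c))``; requires ``c < p < 1``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= items.c) or np.any(p >= 1):
        raise ValueError("probability must lie strictly between c and 1")
    return -np.log((1.0 - p) / (p - items.c))


def cell_log_likelihood(y, theta, items: ItemParams, t_star):
    """N x J matrix of Bernoulli log-pmf terms, probabilities clipped."""
    y = np.asarray(y)
    p = np.clip(_prob_matrix(theta, items, t_star), _P_EPS, 1.0 - _P_EPS)
    return np.where(y == 1, np.log(p), np.log1p(-p))


def _prob_matrix(theta, items: ItemParams, t_star):
    """N x J probability matrix (always 2-D)."""
    denom = _kernel(np.atleast_1d(theta), items, t_star)
    return items.c + (1.0 - items.c) / denom


def log_likelihood(y, theta, items: ItemParams, t_star=None) -> float:
    """Joint Bernoulli log-likelihood of a response matrix.

    ``t_star=None`` gives the plain-3PL likelihood.  Accepts a
    :class:`ResponseMatrix` or a raw 0/1 array.
    """
    if isinstance(y, ResponseMatrix):
        y = y.y
    y = np.asarray(y)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if y.ndim != 2 or y.shape != (theta.size, items.J):
        raise ValueError(
            f"shape mismatch: y {y.shape}, expected ({theta.size}, {items.J})"
        )
    if t_star is not None:
        t_star = np.asarray(t_star, dtype=float)
        if t_star.ndim == 2 and t_star.shape != y.shape:
            raise ValueError("t_star shape does not match responses")
    return float(cell_log_likelihood(y, theta, items, t_star).sum())
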