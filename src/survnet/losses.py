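"""The three task losses and their weighted combination.

Sign conventions: every loss here is a *minimization* target (negative
log-likelihoods for the classification and Cox terms), so the combined
objective ``alpha*cox + beta*classification + gamma*reconstruction`` is
minimized directly by gradient descent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .network import ArchitectureConfig

logger = logging.getLogger(__name__)

#: clamp for probabilities before taking logs
PROB_EPS = 1e-7


class NoEventsError(ValueError):
    """Raised when a batch contains no observed events.

    The Cox partial likelihood is undefined without events; use larger
    batches or event-stratified batching.
    """


@dataclass(frozen=True)
class LossWeights:
    """Coefficients balancing the three tasks, plus the classification horizon."""

    alpha: float = 0.2
    beta: float = 1.0
    gamma: float = 3.0
    horizon_T: float = 36.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.horizon_T <= 0:
            raise ValueError("horizon_T must be positive")


@dataclass(frozen=True)
class ClassificationTargets:
    """Binary survived-past-horizon labels ``d`` with validity mask ``delta``.

    ``delta[i] = 0`` exactly when subject i was censored before the horizon
    (its label is unknowable); ``d`` is only meaningful where ``delta = 1``.
    """

    d: np.ndarray
    delta: np.ndarray


def reconstruction_loss(X: np.ndarray, X_star: np.ndarray, R: np.ndarray) -> float:
    """Incomplete-aware half mean squared error over observed entries.

    ``(1/2n) * sum_i ||r_i * (x*_i - x_i)||^2``: missing entries (``R=0``)
    contribute nothing and receive exactly zero gradient.
    """
    X = np.asarray(X, dtype=float)
    X_star = np.asarray(X_star, dtype=float)
    R = np.asarray(R, dtype=float)
    if not (X.shape == X_star.shape == R.shape):
        raise ValueError(
            f"shape mismatch: X {X.shape}, X_star {X_star.shape}, R {R.shape}"
        )
    n = X.shape[0]
    diff = R * (X_star - X)
    return float((diff ** 2).sum() / (2.0 * n))


def reconstruction_loss_grad(
    X: np.ndarray, X_star: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Gradient of :func:`reconstruction_loss` w.r.t. ``X_star``."""
    n = X.shape[0]
    return R * (X_star - X) / n


def classification_targets(
    t: np.ndarray, s: np.ndarray, horizon_T: float
) -> ClassificationTargets:
    """Label rows for the fixed-horizon survival classification task.

    ``d = 1`` where ``t >= T`` (survived to the horizon; the boundary
    ``t == T`` counts as survived), ``d = 0`` where death was observed
    before the horizon.  Rows censored before the horizon get
    ``delta = 0`` and are ignored by the loss.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    delta = np.where((t < horizon_T) & (s == 0), 0.0, 1.0)
    d = (t >= horizon_T).astype(float)
    return ClassificationTargets(d=d, delta=delta)


def classification_loss(a_c: np.ndarray, targets: ClassificationTargets) -> float:
    """Masked binary cross-entropy over horizon-labelable rows.

    Normalized by the number of valid rows; returns 0 (with a warning) when
    no row is labelable.  Probabilities are clamped to ``[eps, 1-eps]``.
    """
    a_c = np.asarray(a_c, dtype=float)
    d, delta = targets.d, targets.delta
    if a_c.shape != d.shape:
        raise ValueError(f"shape mismatch: a_c {a_c.shape}, targets {d.shape}")
    n_valid = delta.sum()
    if n_valid == 0:
        logger.warning("classification loss: no valid rows in batch")
        return 0.0
    p = np.clip(a_c, PROB_EPS, 1.0 - PROB_EPS)
    ll = delta * (d * np.log(p) + (1.0 - d) * np.log(1.0 - p))
    return float(-ll.sum() / n_valid)


def classification_loss_grad(
    a_c: np.ndarray, targets: ClassificationTargets
) -> np.ndarray:
    """Gradient of :func:`classification_loss` w.r.t. ``a_c``; zero on masked rows."""
    d, delta = targets.d, targets.delta
    n_valid = delta.sum()
    if n_valid == 0:
        return np.zeros_like(np.asarray(a_c, dtype=float))
    p = np.clip(a_c, PROB_EPS, 1.0 - PROB_EPS)
    return delta * (-d / p + (1.0 - d) / (1.0 - p)) / n_valid


def _risk_matrix(t: np.ndarray) -> np.ndarray:
    # risk_matrix[i, j] = 1 iff t_j >= t_i (Breslow: ties share the risk set)
    return (t[None, :] >= t[:, None]).astype(float)


def cox_loss(
    p_x: np.ndarray, t: np.ndarray, s: np.ndarray, normalize: bool = True
) -> float:
    """Negative (mean) log partial likelihood of the Cox model.

    ``-(1/D) sum_{i: s_i=1} [p_i - log sum_{j: t_j >= t_i} exp(p_j)]`` with
    Breslow tie handling and a stable log-sum-exp.  ``normalize=False``
    returns the raw negative sum instead of the event-count mean.
    """
    p_x = np.asarray(p_x, dtype=float)
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (p_x.shape == t.shape == s.shape):
        raise ValueError("p_x, t, s must share shape")
    events = np.flatnonzero(s == 1)
    if events.size == 0:
        raise NoEventsError(
            "no events in batch; use larger batches or event-stratified batching"
        )
    total = 0.0
    for i in events:
        at_risk = p_x[t >= t[i]]
        total += p_x[i] - logsumexp(at_risk)
    loss = -total
    if normalize:
        loss /= events.size
    return float(loss)


def cox_loss_grad(
    p_x: np.ndarray, t: np.ndarray, s: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Gradient of :func:`cox_loss` w.r.t. ``p_x``."""
    p_x = np.asarray(p_x, dtype=float)
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    events = np.flatnonzero(s == 1)
    if events.size == 0:
        raise NoEventsError("no events in batch")
    grad = -s.astype(float).copy()
    for i in events:
        mask = t >= t[i]
        w = np.exp(p_x[mask] - logsumexp(p_x[mask]))
        grad[mask] += w
    if normalize:
        grad /= events.size
    return grad


def total_loss(
    cox: float,
    classification: float,
    reconstruction: float,
    weights: LossWeights,
    arch: ArchitectureConfig,
) -> float:
    """Weighted multi-task objective; disabled modules contribute exactly zero."""
    total = weights.alpha * cox
    if arch.use_classification:
        total += weights.beta * classification
    if arch.use_reconstruction:
        total += weights.gamma * reconstruction
    return float(total)
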