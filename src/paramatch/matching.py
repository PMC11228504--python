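"""Permutation machinery: hard matching, Sinkhorn relaxation, Gumbel noise.

Within each species the candidate pairing is encoded as a permutation
matrix obtained from a real square "parameterization" matrix X via the
matching operator M(X) = argmax_P <P, X> (a maximum-weight linear
assignment).  M is piecewise constant, so gradient-based optimization uses
the Sinkhorn operator — iterated row/column normalization of exp(X/tau) —
as a doubly stochastic relaxation, combined with a straight-through
estimator: the forward pass consumes the hard permutation while gradients
flow through the soft one.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._tape import Var, asvar, exp as texp, logsumexp, straight_through

__all__ = [
    "matching_operator",
    "sinkhorn_operator",
    "add_gumbel_noise",
    "hard_soft_bridge",
]

#: relative magnitude of the random tie-breaking perturbation
_TIE_BREAK = 1e-9
#: noise-scale floor used when the matrix entries have zero spread
NOISE_FLOOR = 1e-3


def _check_square(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix entries must be finite")
    return X


def matching_operator(X: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Hard matching M(X): the permutation matrix maximizing <P, X>.

    Solved exactly with the Hungarian algorithm.  When `rng` is given, ties
    are broken by adding an infinitesimal random perturbation before
    solving; the perturbation is far below the resolution of any genuine
    score difference.
    """
    X = _check_square(X)
    n = X.shape[0]
    if rng is not None:
        scale = max(np.abs(X).max(), 1.0) * _TIE_BREAK
        X = X + rng.standard_normal(X.shape) * scale
    rows, cols = linear_sum_assignment(X, maximize=True)
    P = np.zeros((n, n))
    P[rows, cols] = 1.0
    return P


def sinkhorn_operator(X, tau: float = 1.0, n_iter: int = 20):
    """Doubly stochastic relaxation: Sinkhorn normalization of exp(X/tau).

    Computed in the log domain for stability.  Accepts a plain ndarray
    (returns an ndarray) or a tape :class:`Var` (returns a Var whose
    gradients backpropagate through every normalization sweep).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    is_var = isinstance(X, Var)
    Z = asvar(X) * (1.0 / tau)
    _check_square(Z.data)
    for _ in range(n_iter):
        Z = Z - logsumexp(Z, axis=1, keepdims=True)
        Z = Z - logsumexp(Z, axis=0, keepdims=True)
    S = texp(Z)
    return S if is_var else S.data


def add_gumbel_noise(X: np.ndarray, global_factor: float, rng: np.random.Generator) -> np.ndarray:
    """Add scaled i.i.d. standard Gumbel noise to X.

    The scale is 0.1 times the sample standard deviation of the entries of
    X, times `global_factor` (tied to the learning-rate schedule upstream).
    A zero-spread matrix (e.g. the all-zero initialization) falls back to a
    small floor so that the subsequent hard matching is a uniformly random
    permutation — ties are broken randomly rather than lexicographically.
    """
    X = _check_square(X)
    if global_factor == 0:
        return X.copy()
    sd = X.std()
    scale = 0.1 * global_factor * (sd if sd > 0 else NOISE_FLOOR)
    return X + scale * rng.gumbel(size=X.shape)


def hard_soft_bridge(
    X,
    tau: float = 1.0,
    n_iter: int = 20,
    rng: np.random.Generator | None = None,
) -> Var:
    """Forward-hard / backward-soft permutation.

    The returned Var carries the exact permutation M(X) as its value, while
    its gradients with respect to X are those of the Sinkhorn relaxation
    (value + soft - detached soft).
    """
    Xv = asvar(X)
    soft = sinkhorn_operator(Xv, tau=tau, n_iter=n_iter)
    hard = matching_operator(Xv.data, rng=rng)
    return straight_through(soft, hard)
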