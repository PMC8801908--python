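"""Categorical-simplex numerics: log-sum-exp, softmax and Böhning's bound.

A categorical variable with ``M + 1`` mutually exclusive categories is stored
with ``M`` explicit channels; the last (reference) category is implicit and
carries the residual probability mass.  The reference category has a fixed
zero logit, so the log-partition function is ``lse(eta) = ln(1 + sum exp eta)``
rather than the usual all-channel log-sum-exp.

Böhning's bound replaces the softmax Hessian ``diag(rho) - rho rho^T`` with the
fixed matrix ``A = (I_M - 11^T/(M+1)) / 2``, which dominates every true Hessian
in the Loewner order.  The resulting quadratic majoriser of ``lse`` is what
turns the multinomial-PCA E- and M-steps into closed-form Gaussian updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np


__all__ = [
    "SimplexField",
    "lse",
    "softmax_simplex",
    "bohning_hessian",
    "bohning_bound",
]


@dataclass
class SimplexField:
    """An array of per-site scores over ``M`` explicit categories.

    ``values`` has the category axis last; the reference category is implicit.
    Depending on context the entries are probabilities (each in ``[0, 1]``,
    per-site sum at most 1) or one-hot / soft observation data with the same
    constraints.
    """

    values: np.ndarray
    n_categories_explicit: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_categories_explicit < 1:
            raise ValueError("need at least one explicit category")
        if self.values.shape[-1] != self.n_categories_explicit:
            raise ValueError(
                f"last axis has size {self.values.shape[-1]}, expected "
                f"{self.n_categories_explicit}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite simplex scores")

    @property
    def residual(self) -> np.ndarray:
        """Mass of the implicit reference category at each site."""
        return 1.0 - self.values.sum(axis=-1)

    def check_simplex(self, tol: float = 1e-6) -> None:
        """Raise if any site leaves the probability simplex."""
        v = self.values
        if v.min() < -tol or v.max() > 1.0 + tol:
            raise ValueError("entries outside [0, 1]")
        s = v.sum(axis=-1)
        if s.max() > 1.0 + tol:
            raise ValueError("per-site sum exceeds 1")


def _check_finite(eta: np.ndarray) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return eta


def lse(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    """``ln(1 + sum_m exp(eta_m))`` along ``axis``, numerically stable.

    The shift is ``max(0, max eta)`` so that the implicit zero logit of the
    reference category takes part in the stabilisation.
    """
    eta = _check_finite(eta)
    c = np.maximum(np.max(eta, axis=axis, keepdims=True), 0.0)
    # exp(-c) is the shifted contribution of the implicit zero logit
    s = np.exp(eta - c).sum(axis=axis, keepdims=True) + np.exp(-c)
    out = (c + np.log(s)).squeeze(axis)
    return out if out.ndim else float(out)


def softmax_simplex(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with an implicit zero-logit reference: ``exp(eta - lse(eta))``.

    The returned explicit probabilities sum to at most 1 per site; the
    residual ``1 - sum`` is the reference-category probability.
    """
    eta = _check_finite(eta)
    l = np.asarray(lse(eta, axis=axis))
    return np.exp(eta - np.expand_dims(l, axis))


@lru_cache(maxsize=None)
def _bohning_cached(m: int) -> np.ndarray:
    a = 0.5 * (np.eye(m) - np.full((m, m), 1.0 / (m + 1)))
    a.setflags(write=False)
    return a


def bohning_hessian(m: int) -> np.ndarray:
    """Böhning's fixed curvature matrix ``A = (I_M - 11^T/(M+1)) / 2``.

    Symmetric positive definite, and ``A - (diag(rho) - rho rho^T)`` is PSD for
    every point ``rho`` on the simplex, which is what makes the quadratic
    expansion an upper bound of ``lse``.
    """
    if m < 1:
        raise ValueError("M must be >= 1")
    return _bohning_cached(int(m))


def bohning_bound(eta: np.ndarray, eta_hat: np.ndarray) -> float:
    """Quadratic upper bound of ``lse(eta)`` expanded around ``eta_hat``.

    ``lse(eta_hat) + (eta - eta_hat)^T rho_hat
    + (eta - eta_hat)^T A (eta - eta_hat) / 2`` with
    ``rho_hat = softmax_simplex(eta_hat)``.  Touches ``lse`` (value and
    gradient) at ``eta = eta_hat``.
    """
    eta = _check_finite(eta)
    eta_hat = _check_finite(eta_hat)
    if eta.shape != eta_hat.shape:
        raise ValueError("eta and eta_hat must have the same shape")
    m = eta.shape[-1]
    a = bohning_hessian(m)
    d = eta - eta_hat
    rho_hat = softmax_simplex(eta_hat)
    return float(
        lse(eta_hat)
        + d @ rho_hat
        + 0.5 * d @ a @ d
    )
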