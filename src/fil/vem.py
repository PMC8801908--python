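"""Per-patch variational EM for the joint multinomial-PCA model.

Each patch holds categorical data ``f`` for one or two channel sets (tissue
image and anatomical labels), modelled per voxel ``i`` and subject ``n`` as

    f_ni ~ Cat(softmax(W_i z_n + mu_i)),    z_n ~ N(z0, P0^{-1}),

with the two channel sets sharing the latent vector ``z_n``.  The E-step
updates the Gaussian posterior ``q(z_n) = N(z_hat_n, V_n)`` and the M-step
point-updates the means ``mu`` and bases ``W``; both are closed-form Gaussian
solves because the log-sum-exp in the categorical log-likelihood is majorised
by Böhning's quadratic bound.

Observation weights enter every sum: ``subject_weights`` (``u_n``, used for
translation-augmentation replicates) multiply sums over subjects, and
``voxel_weights`` (``w_ni``, Jacobian determinants of the spatial
normalisation, and zero on padding) multiply each voxel's contribution to
gradients and Hessians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .simplex import bohning_hessian, lse, softmax_simplex

__all__ = [
    "PatchData",
    "PatchBasis",
    "LatentPosterior",
    "ConditionalPrior",
    "estep_update",
    "mstep_mu",
    "mstep_W",
    "elbo",
]


@dataclass
class PatchData:
    """Observed categorical data for one patch and one channel set.

    ``f`` is (N subjects, I voxels, M explicit categories); soft values in
    [0, 1] are accepted wherever one-hot data is.
    """

    f: np.ndarray
    subject_weights: Optional[np.ndarray] = None
    voxel_weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 3:
            raise ValueError("f must be (N, I, M)")
        n = self.f.shape[0]
        if self.subject_weights is None:
            self.subject_weights = np.ones(n)
        else:
            self.subject_weights = np.asarray(self.subject_weights, dtype=float)
            if self.subject_weights.shape != (n,) or np.any(
                ~np.isfinite(self.subject_weights)
            ) or np.any(self.subject_weights < 0):
                raise ValueError("subject_weights must be finite, >= 0, length N")
        if self.voxel_weights is not None:
            self.voxel_weights = np.asarray(self.voxel_weights, dtype=float)
            if self.voxel_weights.shape != self.f.shape[:2] or np.any(
                ~np.isfinite(self.voxel_weights)
            ) or np.any(self.voxel_weights < 0):
                raise ValueError("voxel_weights must be finite, >= 0, shape (N, I)")

    @property
    def n_subjects(self) -> int:
        return self.f.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.f.shape[1]

    @property
    def n_categories(self) -> int:
        return self.f.shape[2]


@dataclass
class PatchBasis:
    """Mean ``mu`` (I, M) and basis functions ``W`` (I, M, K) for one channel set."""

    W: np.ndarray
    mu: np.ndarray
    channel_set: str = "image"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.W.ndim != 3 or self.mu.ndim != 2:
            raise ValueError("W must be (I, M, K) and mu (I, M)")
        if self.W.shape[:2] != self.mu.shape:
            raise ValueError("W and mu disagree on (I, M)")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.mu))):
            raise ValueError("non-finite basis")

    @property
    def n_components(self) -> int:
        return self.W.shape[2]


@dataclass
class LatentPosterior:
    """Gaussian posterior ``q(z) = N(z_hat, V)`` for one subject at one patch."""

    z_hat: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.z_hat = np.asarray(self.z_hat, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        k = self.z_hat.shape[0] if self.z_hat.ndim else 0
        if self.V.shape != (k, k):
            raise ValueError("V must be K x K")

    @property
    def second_moment(self) -> np.ndarray:
        """E[z z^T] = z_hat z_hat^T + V."""
        return np.outer(self.z_hat, self.z_hat) + self.V


@dataclass
class ConditionalPrior:
    """Gaussian prior ``z ~ N(z0, P0^{-1})`` supplied by the patch CRF."""

    z0: np.ndarray
    P0: np.ndarray

    def __post_init__(self) -> None:
        self.z0 = np.asarray(self.z0, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        k = self.z0.shape[-1] if self.z0.ndim else 0
        if self.P0.shape != (k, k):
            raise ValueError("P0 must be K x K")


def spd_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``a x = b`` for SPD ``a``; one jitter retry before giving up."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        return np.zeros_like(np.asarray(b, dtype=float))
    try:
        c = scipy.linalg.cho_factor(a, lower=True)
    except scipy.linalg.LinAlgError:
        k = a.shape[0]
        jitter = 1e-8 * np.trace(a) / k
        try:
            c = scipy.linalg.cho_factor(a + jitter * np.eye(k), lower=True)
        except scipy.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("system not positive definite") from err
    return scipy.linalg.cho_solve(c, b)


def spd_inv(a: np.ndarray) -> np.ndarray:
    """SPD inverse, symmetrised."""
    if a.size == 0:
        return a.copy()
    inv = spd_solve(a, np.eye(a.shape[0]))
    return 0.5 * (inv + inv.T)


def _eta_hat(basis: PatchBasis, z: np.ndarray) -> np.ndarray:
    """Linear predictor (I, M) at one subject's latent estimate."""
    if basis.n_components == 0:
        return basis.mu.copy()
    return basis.W @ z + basis.mu


# ---------------------------------------------------------------------------
# E-step


def estep_update(
    channels: Sequence[tuple[PatchData, PatchBasis]],
    prior: ConditionalPrior,
    z_prev: np.ndarray,
    subject: int,
) -> LatentPosterior:
    """One Böhning-bounded E-step for one subject at one patch.

    The quadratic substitute problem expanded about
    ``eta_hat = W z_prev + mu`` has the closed-form maximiser

        V = (P0 + sum_i w_i W_i^T A W_i)^{-1}
        z_hat = V (P0 z0 + sum_i w_i W_i^T (f_i - rho_hat_i
                                            + A (eta_hat_i - mu_i)))

    where the voxel sum runs over every channel set supplied (image and
    labels in training; image only at test time) and ``w_i`` is that
    subject's voxel weight.
    """
    z_prev = np.asarray(z_prev, dtype=float)
    k = z_prev.shape[0]
    if k == 0:
        return LatentPosterior(np.zeros(0), np.zeros((0, 0)))
    prec = prior.P0.copy()
    rhs = prior.P0 @ prior.z0
    for data, basis in channels:
        if basis.n_components != k:
            raise ValueError("channel sets disagree on K")
        m = data.n_categories
        a = bohning_hessian(m)
        w = (
            np.ones(data.n_voxels)
            if data.voxel_weights is None
            else data.voxel_weights[subject]
        )
        eta = _eta_hat(basis, z_prev)
        rho = softmax_simplex(eta)
        r = data.f[subject] - rho + (eta - basis.mu) @ a
        wmat = basis.W  # (I, M, K)
        prec = prec + np.einsum("i,imk,mp,ipl->kl", w, wmat, a, wmat, optimize=True)
        rhs = rhs + np.einsum("i,im,imk->k", w, r, wmat, optimize=True)
    v = spd_inv(prec)
    z_hat = v @ rhs
    return LatentPosterior(z_hat, v)


def _estep_batch(
    channels: Sequence[tuple[PatchData, PatchBasis]],
    prior_P0: np.ndarray,
    z0: np.ndarray,
    z_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Vectorised E-step over all subjects.

    ``z0`` is (N, K) (per-subject CRF prior means), ``z_prev`` (N, K).
    Returns ``(Z, V, shared)`` where ``V`` is (K, K) if no voxel weights were
    supplied (the posterior covariance is then subject-independent) else
    (N, K, K).
    """
    n, k = z_prev.shape
    if k == 0:
        return np.zeros((n, 0)), np.zeros((0, 0)), True
    shared = all(d.voxel_weights is None for d, _ in channels)
    rhs = z0 @ prior_P0.T
    if shared:
        prec = prior_P0.copy()
    else:
        prec = np.broadcast_to(prior_P0, (n, k, k)).copy()
    for data, basis in channels:
        a = bohning_hessian(data.n_categories)
        eta = np.einsum("imk,nk->nim", basis.W, z_prev, optimize=True) + basis.mu
        rho = softmax_simplex(eta)
        r = data.f - rho + (eta - basis.mu) @ a
        if data.voxel_weights is None:
            # (K, K) term broadcasts over subjects when prec is (N, K, K)
            prec += np.einsum("imk,mp,ipl->kl", basis.W, a, basis.W, optimize=True)
            rhs += np.einsum("nim,imk->nk", r, basis.W, optimize=True)
        else:
            w = data.voxel_weights
            prec += np.einsum(
                "ni,imk,mp,ipl->nkl", w, basis.W, a, basis.W, optimize=True
            )
            rhs += np.einsum("ni,nim,imk->nk", w, r, basis.W, optimize=True)
    if shared:
        v = spd_inv(prec)
        z = rhs @ v.T
    else:
        v = np.linalg.inv(prec)
        v = 0.5 * (v + np.swapaxes(v, -1, -2))
        z = np.einsum("nkl,nl->nk", v, rhs, optimize=True)
    return z, v, shared


# ---------------------------------------------------------------------------
# M-step


def _weights(data: PatchData) -> np.ndarray:
    """Combined (N, I) weight u_n * w_ni."""
    u = data.subject_weights[:, None]
    if data.voxel_weights is None:
        return np.broadcast_to(u, data.f.shape[:2])
    return u * data.voxel_weights


def _mstep_mu_arrays(
    f: np.ndarray, uw: np.ndarray, w: np.ndarray, mu: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Array core of the mean update; ``uw`` is the combined (N, I) weight."""
    m = f.shape[2]
    a = bohning_hessian(m)
    ntilde = uw.sum(axis=0)  # (I,)
    if np.all(ntilde == 0):
        raise ValueError("no effective data in patch")
    if w.shape[2]:
        eta = np.einsum("imk,nk->nim", w, z, optimize=True) + mu
    else:
        eta = np.broadcast_to(mu, f.shape)
    rho = softmax_simplex(eta)
    g = f - rho + mu @ a  # mu = eta_hat - W z
    s = np.einsum("ni,nim->im", uw, g, optimize=True)
    ok = ntilde > 0
    mu_new = mu.copy()
    # pad voxels (all weights zero) keep their mean; they cannot bias the fit
    mu_new[ok] = np.linalg.solve(a, (s[ok] / ntilde[ok, None]).T).T
    return mu_new


def mstep_mu(
    patch: PatchData, basis: PatchBasis, latents: Sequence[LatentPosterior]
) -> np.ndarray:
    """One bound-based update of the per-voxel means ``mu``.

    ``mu_i = (Ntilde_i A)^{-1} sum_n u_n w_ni (f_ni - rho_hat_ni
                                               + A (eta_hat_ni - W_i z_n))``
    with ``eta_hat = W z_hat + mu`` at the current estimates and
    ``Ntilde_i = sum_n u_n w_ni``.  Voxels with no effective data keep their
    current mean; if the whole patch has none, that is an error.
    """
    z = np.stack([l.z_hat for l in latents]) if latents else np.zeros((0, basis.n_components))
    if z.shape[0] != patch.n_subjects:
        raise ValueError("one latent posterior per subject required")
    return _mstep_mu_arrays(patch.f, _weights(patch), basis.W, basis.mu, z)


def _w_prior_precision(m: int) -> np.ndarray:
    """Per-column Gaussian prior precision on W: ``I_M + 11^T/(M+1)``."""
    return np.eye(m) + np.full((m, m), 1.0 / (m + 1))


def _mstep_W_arrays(
    f: np.ndarray,
    u: np.ndarray,
    vox_w: Optional[np.ndarray],
    w: np.ndarray,
    mu: np.ndarray,
    z: np.ndarray,
    v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Array core of the basis update; ``v`` is (K, K) shared or (N, K, K)."""
    n_vox, m, k = w.shape
    if k == 0:
        return w.copy(), np.zeros((0, 0))
    a = bohning_hessian(m)
    eta = np.einsum("imk,nk->nim", w, z, optimize=True) + mu
    rho = softmax_simplex(eta)
    g = f - rho + (eta - mu) @ a
    prior = np.kron(np.eye(k), _w_prior_precision(m))
    if vox_w is None:
        s = np.einsum("n,nk,nl->kl", u, z, z, optimize=True)
        s += u.sum() * v if v.ndim == 2 else np.einsum("n,nkl->kl", u, v, optimize=True)
        h = np.kron(s, a) + prior
        rhs = np.einsum("nk,nim->ikm", z * u[:, None], g, optimize=True)
        vecw = spd_solve(h, rhs.reshape(n_vox, k * m).T).T  # (I, KM)
    else:
        uw = u[:, None] * vox_w  # (N, I)
        s = np.einsum("ni,nk,nl->ikl", uw, z, z, optimize=True)
        if v.ndim == 2:
            s += uw.sum(axis=0)[:, None, None] * v
        else:
            s += np.einsum("ni,nkl->ikl", uw, v, optimize=True)
        h = np.einsum("ikl,mp->ikmlp", s, a).reshape(n_vox, k * m, k * m)
        h = h + prior
        rhs = np.einsum("ni,nk,nim->ikm", uw, z, g,
                        optimize=True).reshape(n_vox, k * m)
        vecw = np.linalg.solve(h, rhs[..., None])[..., 0]
    w_new = vecw.reshape(n_vox, k, m).transpose(0, 2, 1)  # vec index = k*M + m
    return np.ascontiguousarray(w_new), h


def mstep_W(
    patch: PatchData, basis: PatchBasis, latents: Sequence[LatentPosterior]
) -> tuple[np.ndarray, np.ndarray]:
    """One bound-based update of the basis functions ``W``.

    Working on ``vec(W_i)`` (column-major, category index fastest):

        H_i = sum_n u_n w_ni (z_n z_n^T + V_n) (x) A + I_K (x) (I_M + 11^T/(M+1))
        vec(W_i) = H_i^{-1} sum_n u_n w_ni z_n (x) (f_ni - rho_hat_ni
                                                    + A (eta_hat_ni - mu_i))

    The Gaussian prior on the basis columns keeps ``H_i`` positive definite
    even with no data.  Returns ``(W_new, H)`` where ``H`` is (I, KM, KM) or,
    when voxel weights are absent, the shared (KM, KM) matrix.
    """
    if basis.n_components == 0:
        return basis.W.copy(), np.zeros((0, 0))
    z = np.stack([l.z_hat for l in latents])
    v = np.stack([l.V for l in latents])
    return _mstep_W_arrays(
        patch.f, patch.subject_weights, patch.voxel_weights,
        basis.W, basis.mu, z, v,
    )


# ---------------------------------------------------------------------------
# Evidence lower bound


def _gauss_kl(z_hat, v, z0, p0) -> float:
    """KL( N(z_hat, V) || N(z0, P0^{-1}) )."""
    k = z_hat.shape[0]
    if k == 0:
        return 0.0
    d = z_hat - z0
    _, ld_p0 = np.linalg.slogdet(p0)
    _, ld_v = np.linalg.slogdet(v)
    return 0.5 * (np.trace(p0 @ v) + d @ p0 @ d - k - ld_p0 - ld_v)


def elbo(
    channels: Sequence[tuple[PatchData, PatchBasis]],
    latents: Sequence[LatentPosterior],
    prior: ConditionalPrior | Sequence[ConditionalPrior],
) -> float:
    """Evidence lower bound for one patch, Böhning-bounded at the current fit.

    The expected categorical log-likelihood term replaces ``E_q[lse(eta)]``
    with the bound expanded at ``eta_bar = W z_hat + mu``; at its own
    expansion point the bound's displacement terms vanish, leaving
    ``lse(eta_bar) + tr(A W V W^T)/2``.  Adds ``-KL[q(z) || p(z | z0, P0)]``
    and the Gaussian log-prior over the basis columns.  Because each E/M
    update maximises a surrogate that touches this function at the current
    estimate, its value is non-decreasing along the update sequence.
    """
    priors = prior if isinstance(prior, (list, tuple)) else None
    total = 0.0
    n = channels[0][0].n_subjects
    u = channels[0][0].subject_weights
    for data, basis in channels:
        m = data.n_categories
        a = bohning_hessian(m)
        z = np.stack([l.z_hat for l in latents]) if basis.n_components else np.zeros((n, 0))
        eta = (
            np.einsum("imk,nk->nim", basis.W, z, optimize=True) + basis.mu
            if basis.n_components
            else np.broadcast_to(basis.mu, data.f.shape)
        )
        ll = np.einsum("nim,nim->ni", data.f, eta) - lse(eta)
        if basis.n_components:
            aw = np.einsum("mp,ipk->imk", a, basis.W, optimize=True)
            for idx, lat in enumerate(latents):
                t = np.einsum("imk,kl,iml->i", aw, lat.V, basis.W, optimize=True)
                ll[idx] -= 0.5 * t
        uw = _weights(data)
        total += float((uw * ll).sum())
        # Gaussian prior over basis columns, constants included
        if basis.n_components:
            prec = _w_prior_precision(m)
            _, ld = np.linalg.slogdet(prec)
            quad = np.einsum("imk,mp,ipk->", basis.W, prec, basis.W, optimize=True)
            ncol = basis.W.shape[0] * basis.n_components
            total += 0.5 * ncol * (ld - m * np.log(2 * np.pi)) - 0.5 * quad
    for idx, lat in enumerate(latents):
        p = priors[idx] if priors is not None else prior
        total -= u[idx] * _gauss_kl(lat.z_hat, lat.V, p.z0, p.P0)
    return float(total)
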