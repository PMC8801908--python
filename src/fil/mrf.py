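"""Conditional random field coupling the latent variables of adjacent patches.

The joint vector ``x_n = [z_n; y_n]`` of a patch's latents and the
concatenated latents of its (up to six) face neighbours is modelled as
``x_n ~ N(0, P^{-1})`` with a Wishart prior/posterior on the precision ``P``.
The Wishart posterior ``W(Psi, nu)`` induces, through ``E[P] = nu Psi``, a
subject-specific conditional Gaussian prior on ``z_n`` given the neighbour
means — the empirical prior consumed by the per-patch E-step.  Patches are
updated in a red-black (checkerboard) order so that every update conditions
only on neighbours whose latents are held fixed within the sweep, which makes
the mean-field scheme valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .vem import ConditionalPrior, LatentPosterior, spd_inv

__all__ = [
    "NEIGHBOUR_OFFSETS",
    "NeighbourSummary",
    "MRFPosterior",
    "MRFPriorConfig",
    "red_black_schedule",
    "neighbour_ids",
    "gather_neighbours",
    "wishart_update",
    "conditional_prior",
]

# fixed layout order of the face neighbours
NEIGHBOUR_OFFSETS = (
    (-1, 0, 0),
    (1, 0, 0),
    (0, -1, 0),
    (0, 1, 0),
    (0, 0, -1),
    (0, 0, 1),
)


@dataclass
class NeighbourSummary:
    """Concatenated neighbour posterior means and block-diagonal covariance."""

    y_hat: np.ndarray  # (K_y,)
    U: np.ndarray  # (K_y, K_y) block diagonal
    layout: list  # ordered [(neighbour patch id, K_j), ...]


@dataclass
class MRFPosterior:
    """Wishart posterior ``W(Psi, nu)`` over the joint precision of [z; y].

    ``k_self`` is the dimension of the patch's own latents; the remaining
    ``K_y`` rows/columns follow the neighbour layout order.
    """

    Psi: np.ndarray
    nu: float
    k_self: int
    layout: list

    def __post_init__(self) -> None:
        self.Psi = np.asarray(self.Psi, dtype=float)
        k_total = self.Psi.shape[0]
        if self.Psi.shape != (k_total, k_total):
            raise ValueError("Psi must be square")
        if self.nu < 0:
            raise ValueError("nu must be non-negative")

    @property
    def k_total(self) -> int:
        return self.Psi.shape[0]

    @property
    def Psi_zz(self) -> np.ndarray:
        return self.Psi[: self.k_self, : self.k_self]

    @property
    def Psi_zy(self) -> np.ndarray:
        return self.Psi[: self.k_self, self.k_self:]

    def expected_precision(self) -> np.ndarray:
        """E[P] = nu * Psi."""
        return self.nu * self.Psi


@dataclass
class MRFPriorConfig:
    """Wishart prior settings: ``Psi0^{-1} = I nu0 v0``.

    ``nu0`` is either a number (the ``scaled`` policy) or one of
    ``"improper_1"`` (``nu0 = 1``, an improper prior) and
    ``"least_informative"`` (``nu0 = K_total + 0.01``, the least informative
    proper prior, tracking the pruned dimension).
    """

    nu0: float | str = "least_informative"
    v0: float = 1.0

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if isinstance(self.nu0, str):
            if self.nu0 not in ("improper_1", "least_informative"):
                raise ValueError(f"unknown nu0 policy {self.nu0!r}")
        elif self.nu0 <= 0:
            raise ValueError("numeric nu0 must be > 0")

    def resolve_nu0(self, k_total: int) -> float:
        if self.nu0 == "improper_1":
            return 1.0
        if self.nu0 == "least_informative":
            return k_total + 0.01
        return float(self.nu0)

    def psi0_inv(self, k_total: int) -> np.ndarray:
        return np.eye(k_total) * (self.resolve_nu0(k_total) * self.v0)


def red_black_schedule(grid_dims: Sequence[int]) -> tuple[list[int], list[int]]:
    """Split the patch grid into red (even parity) and black patch-id lists.

    Patch ids are flat indices with x fastest.  No two patches of the same
    colour are face-adjacent, so each colour class can be updated in parallel
    while conditioning on the other.
    """
    gx, gy, gz = (int(d) for d in grid_dims)
    if gx < 1 or gy < 1 or gz < 1:
        raise ValueError("grid dims must be positive")
    red, black = [], []
    for pz in range(gz):
        for py in range(gy):
            for px in range(gx):
                pid = px + gx * (py + gy * pz)
                (red if (px + py + pz) % 2 == 0 else black).append(pid)
    return red, black


def neighbour_ids(pid: int, grid_dims: Sequence[int]) -> list[int]:
    """Flat ids of the existing face neighbours in fixed layout order."""
    gx, gy, gz = (int(d) for d in grid_dims)
    px = pid % gx
    py = (pid // gx) % gy
    pz = pid // (gx * gy)
    out = []
    for dx, dy, dz in NEIGHBOUR_OFFSETS:
        qx, qy, qz = px + dx, py + dy, pz + dz
        if 0 <= qx < gx and 0 <= qy < gy and 0 <= qz < gz:
            out.append(qx + gx * (qy + gy * qz))
    return out


def gather_neighbours(
    pid: int,
    grid_dims: Sequence[int],
    latents: Sequence[LatentPosterior],
) -> NeighbourSummary:
    """Concatenate one subject's neighbour posteriors in layout order.

    Boundary patches concatenate only their existing neighbours, giving a
    smaller ``K_y``.
    """
    ids = neighbour_ids(pid, grid_dims)
    means, covs, layout = [], [], []
    for q in ids:
        lat = latents[q]
        means.append(lat.z_hat)
        covs.append(lat.V)
        layout.append((q, lat.z_hat.shape[0]))
    y = np.concatenate(means) if means else np.zeros(0)
    u = scipy.linalg.block_diag(*covs) if covs else np.zeros((0, 0))
    return NeighbourSummary(y_hat=y, U=u, layout=layout)


def wishart_update(
    z_hat: np.ndarray,
    v: np.ndarray,
    y_hat: np.ndarray,
    u_blocks: np.ndarray,
    subject_weights: Optional[np.ndarray],
    config: MRFPriorConfig,
    k_self: int,
    layout: list,
) -> MRFPosterior:
    """Conjugate Wishart update of the joint-precision posterior.

    Inputs are stacked over subjects: ``z_hat`` (N, K), ``v`` (K, K) shared or
    (N, K, K), ``y_hat`` (N, K_y), ``u_blocks`` likewise shared or batched.

        Psi = ( sum_n u_n S_n + Psi0^{-1} )^{-1},   nu = sum_n u_n + nu0,

    with ``S_n = E[[z;y][z;y]^T]`` assembled from the posterior means and the
    covariance blocks ``V_n`` (self) and ``U_n`` (neighbours; the cross block
    uses the means only because the mean field factorises over patches).
    """
    z_hat = np.atleast_2d(np.asarray(z_hat, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    n = z_hat.shape[0]
    u_n = (
        np.ones(n)
        if subject_weights is None
        else np.asarray(subject_weights, dtype=float)
    )
    k = z_hat.shape[1]
    ky = y_hat.shape[1]
    k_total = k + ky
    nu0 = config.resolve_nu0(k_total)
    nu = float(u_n.sum() + nu0)
    if isinstance(config.nu0, (int, float)) or config.nu0 == "least_informative":
        if nu < k_total:
            raise ValueError(
                f"nu = {nu} < K_total = {k_total}: improper posterior under a "
                "proper-prior policy"
            )
    x = np.concatenate([z_hat, y_hat], axis=1)  # (N, K_total)
    s = np.einsum("n,nk,nl->kl", u_n, x, x, optimize=True)
    v = np.asarray(v, dtype=float)
    u_blocks = np.asarray(u_blocks, dtype=float)
    if v.ndim == 2:
        s[:k, :k] += u_n.sum() * v
    else:
        s[:k, :k] += np.einsum("n,nkl->kl", u_n, v, optimize=True)
    if u_blocks.ndim == 2:
        s[k:, k:] += u_n.sum() * u_blocks
    else:
        s[k:, k:] += np.einsum("n,nkl->kl", u_n, u_blocks, optimize=True)
    psi = spd_inv(s + config.psi0_inv(k_total))
    return MRFPosterior(Psi=psi, nu=nu, k_self=k, layout=list(layout))


def conditional_prior(post: MRFPosterior, neigh: NeighbourSummary) -> ConditionalPrior:
    """Gaussian prior on a patch's latents given its neighbours' means.

    ``P0 = nu Psi_zz`` and ``z0 = -Psi_zz^{-1} Psi_zy y_hat``.
    """
    ky = post.k_total - post.k_self
    if neigh.y_hat.shape[0] != ky:
        raise ValueError("neighbour summary does not match the posterior layout")
    p0 = post.nu * post.Psi_zz
    if post.k_self == 0:
        return ConditionalPrior(np.zeros(0), np.zeros((0, 0)))
    try:
        c = scipy.linalg.cho_factor(post.Psi_zz, lower=True)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular Psi_zz block") from err
    z0 = -scipy.linalg.cho_solve(c, post.Psi_zy @ neigh.y_hat)
    return ConditionalPrior(z0=z0, P0=p0)


def conditional_prior_means(post: MRFPosterior, y_hat: np.ndarray) -> np.ndarray:
    """Batched ``z0`` for stacked neighbour means ``y_hat`` (N, K_y)."""
    if post.k_self == 0:
        return np.zeros((y_hat.shape[0], 0))
    sol = np.linalg.solve(post.Psi_zz, post.Psi_zy)
    return -(y_hat @ sol.T)
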