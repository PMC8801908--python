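"""Training loop: red-black sweeps of patch-wise variational EM, per-patch
label-category reduction, translation augmentation, and ARD pruning.

Each outer iteration first refreshes every patch's empirical latent prior
from its neighbours (the CRF), then runs the per-patch EM sub-iterations in a
red-black order, then updates the Wishart posteriors over the joint patch /
neighbour precisions, and on schedule prunes latent components that no longer
contribute to the fit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import CategoricalVolume, one_hot, tile
from .model import PatchModel, TrainConfig, TrainedModel
from .mrf import (
    MRFPosterior,
    conditional_prior_means,
    neighbour_ids,
    red_black_schedule,
    wishart_update,
)
from .vem import (
    ConditionalPrior,
    LatentPosterior,
    PatchBasis,
    PatchData,
    _estep_batch,
    _mstep_W_arrays,
    _mstep_mu_arrays,
    elbo,
)

__all__ = [
    "reduce_label_categories",
    "augmentation_offsets",
    "prune",
    "train",
]

logger = logging.getLogger("fil")

_MU_CLAMP = float(np.log(1e4))


def reduce_label_categories(
    full: np.ndarray,
    codes: np.ndarray,
    weights: Optional[np.ndarray] = None,
    background: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only the label categories a patch actually contains.

    ``full`` is (N, I, C) soft label mass with one channel per global code
    (``codes``, ascending); ``weights`` (N, I) are the combined subject and
    voxel weights.  Returns ``(subset, f_local)`` where ``subset`` lists the
    global codes with nonzero weighted mass in the patch, ordered ascending
    with the background code rotated last to serve as the patch-local
    reference, and ``f_local`` is (N, I, M2) over ``subset[:-1]``.

    A patch containing only background yields a single-category subset
    (local M2 = 0).
    """
    codes = np.asarray(codes, dtype=int)
    if background is None:
        background = int(codes.min())
    if weights is None:
        mass = full.sum(axis=(0, 1))
    else:
        mass = np.einsum("ni,nic->c", weights, full, optimize=True)
    present = codes[mass > 0]
    if background not in present:
        # guarantee a reference category even for pathological patches
        present = np.append(present, background)
    subset = np.concatenate([present[present != background],
                             [background]]).astype(int)
    idx = np.searchsorted(codes, subset[:-1])
    return subset, np.ascontiguousarray(full[:, :, idx])


def augmentation_offsets(
    radius: float, sd: float = 2.0
) -> list[tuple[tuple[int, int, int], float]]:
    """Integer translations within ``radius`` with Gaussian weights.

    Offsets are all ``d`` in Z^3 with ``||d||_2 <= radius``; each carries
    weight proportional to ``exp(-||d||^2 / (2 sd^2))``, renormalised to sum
    to one over the offsets.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return [((0, 0, 0), 1.0)]
    if sd <= 0:
        raise ValueError("sd must be > 0")
    r = int(np.floor(radius))
    offsets, weights = [], []
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                d2 = dx * dx + dy * dy + dz * dz
                if d2 <= radius * radius:
                    offsets.append((dx, dy, dz))
                    weights.append(np.exp(-0.5 * d2 / sd**2))
    w = np.array(weights)
    w /= w.sum()
    return [(o, float(wi)) for o, wi in zip(offsets, w)]


def _shift(vol: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Translate the content of ``vol`` by integer voxels, zero-filling."""
    out = np.zeros_like(vol)
    src, dst = [], []
    for ax, dd in enumerate(d):
        n = vol.shape[ax]
        if abs(dd) >= n:
            return out
        if dd >= 0:
            dst.append(slice(dd, n))
            src.append(slice(0, n - dd))
        else:
            dst.append(slice(0, n + dd))
            src.append(slice(-dd, n))
    out[tuple(dst)] = vol[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# Trainer state


@dataclass
class _PatchState:
    data_image: PatchData
    data_label: PatchData
    basis_image: PatchBasis
    basis_label: PatchBasis
    Z: np.ndarray  # (N_eff, K)
    V: np.ndarray  # (K, K) shared or (N_eff, K, K)
    mrf: MRFPosterior
    label_subset: np.ndarray

    @property
    def k(self) -> int:
        return self.Z.shape[1]

    @property
    def channels(self):
        return ((self.data_image, self.basis_image),
                (self.data_label, self.basis_label))

    def v_batched(self) -> np.ndarray:
        if self.V.ndim == 3:
            return self.V
        return np.broadcast_to(self.V, (self.Z.shape[0],) + self.V.shape)

    def latents(self) -> list[LatentPosterior]:
        vb = self.v_batched()
        return [LatentPosterior(self.Z[n], vb[n]) for n in range(self.Z.shape[0])]


def _init_mu(f: np.ndarray, uw: np.ndarray) -> np.ndarray:
    """Weighted empirical per-voxel log-odds, clamped to +-log(1e4)."""
    tot = uw.sum(axis=0)  # (I,)
    num = np.einsum("ni,nim->im", uw, f, optimize=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = num / tot[:, None]
        p_ref = 1.0 - p.sum(axis=1)
        mu = np.log(p) - np.log(p_ref)[:, None]
    mu[~np.isfinite(mu)] = np.nan_to_num(
        mu[~np.isfinite(mu)], nan=0.0, posinf=_MU_CLAMP, neginf=-_MU_CLAMP
    )
    mu[tot == 0] = 0.0
    return np.clip(mu, -_MU_CLAMP, _MU_CLAMP)


def _as_values(vol) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(vol, CategoricalVolume):
        return vol.values, vol.affine
    arr = np.asarray(vol, dtype=float)
    return arr, np.eye(4)


def _labels_to_full(labels: Sequence, codes: np.ndarray) -> list[np.ndarray]:
    """Represent every subject's labels as soft mass over all global codes
    (ascending channel order, per-voxel sum 1)."""
    out = []
    for lab in labels:
        if isinstance(lab, CategoricalVolume):
            if lab.codes is None:
                raise ValueError("soft label volumes need a code table")
            full = np.concatenate([lab.values, lab.residual[..., None]], axis=-1)
            chan = np.zeros(full.shape[:3] + (codes.size,))
            pos = np.searchsorted(codes, lab.codes)
            chan[..., pos] = full
            out.append(chan)
        else:
            arr = np.asarray(lab)
            out.append((arr[..., None] == codes).astype(float))
    return out


def _global_label_codes(labels: Sequence) -> np.ndarray:
    codes: set[int] = set()
    for lab in labels:
        if isinstance(lab, CategoricalVolume):
            if lab.codes is None:
                raise ValueError("soft label volumes need a code table")
            codes.update(int(c) for c in lab.codes)
        else:
            codes.update(int(c) for c in np.unique(np.asarray(lab)))
    return np.array(sorted(codes), dtype=int)


def _init_mrf(k_self: int, layout, config: TrainConfig) -> MRFPosterior:
    k_total = k_self + sum(kj for _, kj in layout)
    nu0 = config.mrf.resolve_nu0(k_total)
    psi0 = np.eye(k_total) / (nu0 * config.mrf.v0) if k_total else np.zeros((0, 0))
    return MRFPosterior(Psi=psi0, nu=nu0, k_self=k_self, layout=list(layout))


def _gather_y(states: list[_PatchState], pid: int, grid) -> np.ndarray:
    ids = neighbour_ids(pid, grid)
    if not ids:
        return np.zeros((states[pid].Z.shape[0], 0))
    return np.concatenate([states[q].Z for q in ids], axis=1)


def _gather_u_blocks(states: list[_PatchState], pid: int, grid):
    """Block-diagonal neighbour covariance; shared (K_y, K_y) when possible."""
    ids = neighbour_ids(pid, grid)
    n = states[pid].Z.shape[0]
    ks = [states[q].k for q in ids]
    ky = sum(ks)
    if all(states[q].V.ndim == 2 for q in ids):
        u = np.zeros((ky, ky))
        at = 0
        for q, kq in zip(ids, ks):
            u[at:at + kq, at:at + kq] = states[q].V
            at += kq
        return u
    u = np.zeros((n, ky, ky))
    at = 0
    for q, kq in zip(ids, ks):
        u[:, at:at + kq, at:at + kq] = states[q].v_batched()
        at += kq
    return u


def _update_patch(state: _PatchState, y: np.ndarray, config: TrainConfig,
                  trace: Optional[list] = None) -> None:
    """EM sub-iterations for one patch with the CRF prior held fixed."""
    post = state.mrf
    p0 = post.nu * post.Psi_zz
    z0 = conditional_prior_means(post, y)
    for _ in range(config.em_subiters):
        if state.k:
            for _ in range(config.estep_repeats):
                state.Z, state.V, _ = _estep_batch(state.channels, p0, z0, state.Z)
        for _ in range(config.mstep_repeats):
            for data, basis in state.channels:
                uw = data.subject_weights[:, None] * (
                    data.voxel_weights
                    if data.voxel_weights is not None
                    else np.ones((1, data.n_voxels))
                )
                basis.mu = _mstep_mu_arrays(data.f, uw, basis.W, basis.mu, state.Z)
                if state.k:
                    basis.W, _ = _mstep_W_arrays(
                        data.f, data.subject_weights, data.voxel_weights,
                        basis.W, basis.mu, state.Z, state.V,
                    )
        if trace is not None:
            priors = [ConditionalPrior(z0[n], p0) for n in range(z0.shape[0])]
            trace.append(elbo(state.channels, state.latents(), priors))


def _patch_elbo(state: _PatchState, y: np.ndarray) -> float:
    post = state.mrf
    p0 = post.nu * post.Psi_zz
    z0 = conditional_prior_means(post, y)
    priors = [ConditionalPrior(z0[n], p0) for n in range(z0.shape[0])]
    return elbo(state.channels, state.latents(), priors)


# ---------------------------------------------------------------------------
# Pruning


def prune(states: list[_PatchState], grid_dims, tol: float) -> None:
    """Rotate each patch's latent space to principal axes and drop dead ones.

    The rotation comes from the eigendecomposition of the (weighted) latent
    second moment — equivalently the SVD of the stacked z-hat matrix — and is
    applied to z, V and (inversely) to both bases, which leaves every model
    prediction unchanged.  A component is dropped when its share of the
    post-rotation weighted latent variance times the squared basis norm falls
    below ``tol`` of the patch total.  The Wishart posteriors are rebuilt at
    the new dimensions by congruent rotation-then-drop of Psi; nu is kept.
    """
    rotations: list[np.ndarray] = []
    keeps: list[np.ndarray] = []
    for st in states:
        k = st.k
        if k == 0:
            rotations.append(np.zeros((0, 0)))
            keeps.append(np.zeros(0, dtype=bool))
            continue
        u = st.data_image.subject_weights
        s = np.einsum("n,nk,nl->kl", u, st.Z, st.Z, optimize=True)
        lam, r = np.linalg.eigh(s)
        order = np.argsort(lam)[::-1]
        lam, r = np.maximum(lam[order], 0.0), r[:, order]
        w1 = np.einsum("imk,kl->iml", st.basis_image.W, r, optimize=True)
        w2 = np.einsum("imk,kl->iml", st.basis_label.W, r, optimize=True)
        usum = u.sum()
        var = lam / usum if usum > 0 else lam
        bnorm = (w1**2).sum(axis=(0, 1)) + (w2**2).sum(axis=(0, 1))
        contrib = var * bnorm
        total = contrib.sum()
        keep = contrib >= tol * total if total > 0 else np.zeros(k, dtype=bool)
        st.Z = st.Z @ r
        if st.V.ndim == 2:
            st.V = r.T @ st.V @ r
        else:
            st.V = np.einsum("kl,nlm,mp->nkp", r.T, st.V, r, optimize=True)
        st.basis_image.W = np.ascontiguousarray(w1)
        st.basis_label.W = np.ascontiguousarray(w2)
        rotations.append(r)
        keeps.append(keep)
    # rebuild Wishart posteriors congruently, then select kept components
    for pid, st in enumerate(states):
        layout = st.mrf.layout
        blocks = [rotations[pid]] + [rotations[q] for q, _ in layout]
        masks = [keeps[pid]] + [keeps[q] for q, _ in layout]
        at = 0
        dim = st.mrf.k_total
        qmat = np.zeros((dim, dim))
        for b in blocks:
            kq = b.shape[0]
            qmat[at:at + kq, at:at + kq] = b.T  # z' = R^T z blockwise
            at += kq
        psi = qmat @ st.mrf.Psi @ qmat.T
        sel = np.concatenate(masks) if masks else np.zeros(0, dtype=bool)
        psi = psi[np.ix_(sel, sel)]
        new_layout = [(q, int(keeps[q].sum())) for q, _ in layout]
        st.mrf = MRFPosterior(Psi=psi, nu=st.mrf.nu,
                              k_self=int(keeps[pid].sum()), layout=new_layout)
    # finally drop the components from the per-patch arrays
    for pid, st in enumerate(states):
        keep = keeps[pid]
        if keep.size == 0:
            continue
        st.Z = np.ascontiguousarray(st.Z[:, keep])
        if st.V.ndim == 2:
            st.V = np.ascontiguousarray(st.V[np.ix_(keep, keep)])
        else:
            st.V = np.ascontiguousarray(st.V[:, keep][:, :, keep])
        st.basis_image.W = np.ascontiguousarray(st.basis_image.W[:, :, keep])
        st.basis_label.W = np.ascontiguousarray(st.basis_label.W[:, :, keep])


# ---------------------------------------------------------------------------
# Training


def train(
    images: Sequence,
    labels: Sequence,
    weights: Optional[Sequence[np.ndarray]] = None,
    config: Optional[TrainConfig] = None,
    trace: Optional[dict] = None,
) -> TrainedModel:
    """Fit the factorisation model to paired image / label volumes.

    ``images`` are (X, Y, Z, M1) simplex arrays or :class:`CategoricalVolume`;
    ``labels`` are 3D integer label volumes or soft
    :class:`CategoricalVolume` with a code table; ``weights`` are optional 3D
    voxel-weight volumes (Jacobian determinants), one per subject, applied to
    both channel sets.  Deterministic given ``config.seed``.

    ``trace``, when a dict is supplied, is filled with per-sub-iteration
    ELBO values (diagnostics).
    """
    config = config or TrainConfig()
    if len(images) == 0 or len(images) != len(labels):
        raise ValueError("need equally many image and label volumes")
    img_values, affine = _as_values(images[0])
    vol_dims = img_values.shape[:3]
    m1 = img_values.shape[3]
    all_values = []
    for im in images:
        v, _ = _as_values(im)
        if v.shape[:3] != vol_dims or v.shape[3] != m1:
            raise ValueError("image volumes disagree on dimensions")
        all_values.append(v)
    codes = _global_label_codes(labels)
    full_labels = _labels_to_full(labels, codes)
    for fl in full_labels:
        if fl.shape[:3] != vol_dims:
            raise ValueError("label volumes disagree on dimensions")
    if weights is not None:
        weights = [np.asarray(w, dtype=float) for w in weights]
        for w in weights:
            if w.shape != tuple(vol_dims):
                raise ValueError("weight volumes disagree on dimensions")

    offsets = augmentation_offsets(config.aug_radius, config.aug_sd)
    patch_size = config.patch_size
    n = len(images)

    f1_parts, fl_parts, w_parts, u_list = [], [], [], []
    grid = None
    have_weights = False
    for s in range(n):
        base_w = np.ones(vol_dims) if weights is None else weights[s]
        for (dx, dy, dz), uo in offsets:
            d = (dx, dy, dz)
            img_s = _shift(all_values[s], d) if d != (0, 0, 0) else all_values[s]
            lab_s = _shift(full_labels[s], d) if d != (0, 0, 0) else full_labels[s]
            w_s = _shift(base_w, d) if d != (0, 0, 0) else base_w
            p1, grid = tile(img_s, patch_size)
            pl, _ = tile(lab_s, patch_size)
            pw, _ = tile(w_s, patch_size)
            f1_parts.append(p1)
            fl_parts.append(pl)
            w_parts.append(pw)
            u_list.append(uo)
            if not np.all(pw == 1.0):
                have_weights = True
    f1 = np.stack(f1_parts)      # (N_eff, P, I, M1)
    fl = np.stack(fl_parts)      # (N_eff, P, I, C)
    wv = np.stack(w_parts) if have_weights else None  # (N_eff, P, I)
    u = np.asarray(u_list)
    del f1_parts, fl_parts, w_parts
    n_patches = f1.shape[1]

    rng = np.random.default_rng(config.seed)
    k0 = config.k_max
    states: list[_PatchState] = []
    for pid in range(n_patches):
        vw = wv[:, pid] if wv is not None else None
        uw = u[:, None] * (vw if vw is not None else np.ones((1, f1.shape[2])))
        subset, f2 = reduce_label_categories(fl[:, pid], codes, weights=uw)
        di = PatchData(f1[:, pid], subject_weights=u, voxel_weights=vw)
        dl = PatchData(f2, subject_weights=u, voxel_weights=vw)
        b1 = PatchBasis(
            rng.normal(0.0, 0.01, size=(di.n_voxels, m1, k0)),
            _init_mu(di.f, uw), "image",
        )
        b2 = PatchBasis(
            rng.normal(0.0, 0.01, size=(dl.n_voxels, dl.n_categories, k0)),
            _init_mu(dl.f, uw), "label",
        )
        states.append(_PatchState(
            data_image=di, data_label=dl, basis_image=b1, basis_label=b2,
            Z=np.zeros((di.n_subjects, k0)), V=np.eye(k0),
            mrf=None, label_subset=subset,  # type: ignore[arg-type]
        ))
    for pid, st in enumerate(states):
        layout = [(q, states[q].k) for q in neighbour_ids(pid, grid)]
        st.mrf = _init_mrf(st.k, layout, config)

    red, black = red_black_schedule(grid)
    if trace is not None:
        trace.setdefault("elbo_subiters", [])
    for outer in range(config.outer_iters):
        sweep_times = []
        for colour in (red, black):
            t0 = time.perf_counter()
            for pid in colour:
                st = states[pid]
                y = _gather_y(states, pid, grid)
                sub_trace = [] if trace is not None else None
                _update_patch(st, y, config, trace=sub_trace)
                if sub_trace is not None:
                    trace["elbo_subiters"].append(sub_trace)
            sweep_times.append(time.perf_counter() - t0)
        for pid, st in enumerate(states):
            y = _gather_y(states, pid, grid)
            ub = _gather_u_blocks(states, pid, grid)
            st.mrf = wishart_update(
                st.Z, st.V if st.V.ndim == 3 else st.V, y, ub,
                st.data_image.subject_weights, config.mrf,
                st.k, [(q, states[q].k) for q in neighbour_ids(pid, grid)],
            )
        if config.prune_every and (outer + 1) % config.prune_every == 0:
            prune(states, grid, config.prune_tol)
        mean_k = float(np.mean([st.k for st in states]))
        total_elbo = sum(
            _patch_elbo(st, _gather_y(states, pid, grid))
            for pid, st in enumerate(states)
        )
        logger.info(
            "outer=%d elbo=%.6e mean_K=%.2f sweep_red=%.2fs sweep_black=%.2fs",
            outer + 1, total_elbo, mean_k, sweep_times[0], sweep_times[1],
        )

    patches = [
        PatchModel(
            basis_image=st.basis_image,
            basis_label=st.basis_label,
            mrf=st.mrf,
            label_subset=st.label_subset,
        )
        for st in states
    ]
    return TrainedModel(
        patch_size=patch_size,
        grid_dims=grid,
        vol_dims=vol_dims,
        n_image_categories=m1,
        label_codes=codes,
        patches=patches,
        config=config,
        affine=affine,
    )
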