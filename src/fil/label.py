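"""Applying a trained model to an unseen categorical image.

Encoding estimates each patch's latent mean by iterating a fixed-point update
that is algebraically the Böhning-bounded E-step re-expressed through
pre-computed matrices:

    z* <- B1 f* + B0 y* + B2 z* - B1 softmax(W z* + mu)

where ``f*`` is the flattened image patch, ``y*`` the concatenated latent
means of the neighbouring patches, and B0, B1, B2 derive from the trained
image basis and the CRF Wishart posterior.  Patches are swept in red-black
order with all latents initialised to zero.  Decoding then maps the latents
through the label basis, ``softmax(W2 z* + mu2)`` per voxel, back onto the
global label codes; the same machinery with the image basis synthesises a
subject-specific template.  Only the image channel set is used for encoding;
the label basis enters only at decode time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import CategoricalVolume, pad_dims, tile, untile
from .model import TrainedModel
from .mrf import neighbour_ids, red_black_schedule
from .simplex import bohning_hessian, softmax_simplex
from .vem import spd_inv

__all__ = [
    "ApplyConfig",
    "EncoderCache",
    "build_encoder_cache",
    "encode_iterate",
    "encode",
    "decode",
    "synthesize_template",
    "hard_label",
    "apply_model",
]


@dataclass
class ApplyConfig:
    """Schedule for the recurrent encoding: red-black sweeps over the patch
    grid, with a few fixed-point iterations per patch per sweep."""

    sweeps: int = 10
    inner_iters: int = 5
    hard: bool = False
    sample: bool = False  # draw z* ~ N(z_hat, V) instead of using the mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweeps < 1 or self.inner_iters < 1:
            raise ValueError("sweeps and inner_iters must be positive")


@dataclass
class _PatchCache:
    V: np.ndarray        # (K, K)
    B0: np.ndarray       # (K, K_y)
    B1: np.ndarray       # (K, I*M1)
    B2: np.ndarray       # (K, K)
    W: np.ndarray        # (I*M1, K) stacked, voxel-major
    mu: np.ndarray       # (I*M1,)


@dataclass
class EncoderCache:
    patches: list[_PatchCache]
    grid_dims: tuple[int, int, int]


def _stacked(basis) -> tuple[np.ndarray, np.ndarray]:
    i, m, k = basis.W.shape
    return basis.W.reshape(i * m, k), basis.mu.reshape(i * m)


def build_encoder_cache(
    model: TrainedModel, voxel_weights: Optional[np.ndarray] = None
) -> EncoderCache:
    """Pre-compute the per-patch encoder matrices.

    ``V = (nu Psi_zz + W^T (I (x) A) W)^{-1}``, ``B0 = -V Psi_zy nu``,
    ``B1 = V W^T`` and ``B2 = V W^T (I (x) A) W``, all from the image basis
    and the CRF posterior only — independent of any target image.  When a
    per-voxel weight volume for the target is supplied (tiled to
    (P, I)), the weights enter every voxel sum exactly as in training and
    the cache becomes subject-specific.
    """
    m1 = model.n_image_categories
    a = bohning_hessian(m1)
    caches = []
    for pid, p in enumerate(model.patches):
        w, mu = _stacked(p.basis_image)
        i = p.basis_image.W.shape[0]
        k = p.n_components
        # (I (x) A) W stacked voxel-major, unweighted
        aw = np.einsum("mp,ipk->imk", a, p.basis_image.W,
                       optimize=True).reshape(i * m1, k)
        if voxel_weights is not None:
            # voxel weights enter once, on the W^T side of every sum over i
            w_weighted = w * np.repeat(voxel_weights[pid], m1)[:, None]
        else:
            w_weighted = w
        vinv = p.mrf.nu * p.mrf.Psi_zz + w_weighted.T @ aw
        v = spd_inv(vinv)
        b1 = v @ w_weighted.T
        b2 = b1 @ aw
        b0 = -(v @ p.mrf.Psi_zy) * p.mrf.nu
        caches.append(_PatchCache(V=v, B0=b0, B1=b1, B2=b2, W=w, mu=mu))
    return EncoderCache(patches=caches, grid_dims=model.grid_dims)


def encode_iterate(
    f_star: np.ndarray,
    y_hat: np.ndarray,
    z_hat: np.ndarray,
    cache: _PatchCache,
    n_categories: int,
) -> np.ndarray:
    """One fixed-point update of a patch's latent mean."""
    if z_hat.shape[0] == 0:
        return z_hat
    eta = (cache.W @ z_hat + cache.mu).reshape(-1, n_categories)
    rho = softmax_simplex(eta).reshape(-1)
    return cache.B1 @ f_star + cache.B0 @ y_hat + cache.B2 @ z_hat - cache.B1 @ rho


def encode(
    model: TrainedModel,
    image: np.ndarray | CategoricalVolume,
    voxel_weights: Optional[np.ndarray] = None,
    config: Optional[ApplyConfig] = None,
    cache: Optional[EncoderCache] = None,
) -> list[np.ndarray]:
    """Estimate per-patch latent means for a target categorical image.

    Latents start at zero and are refined over ``config.sweeps`` red-black
    sweeps with ``config.inner_iters`` fixed-point iterations per patch.
    Returns one latent vector per patch.  Deterministic.
    """
    config = config or ApplyConfig()
    values = image.values if isinstance(image, CategoricalVolume) else np.asarray(image, dtype=float)
    if values.shape[:3] != model.vol_dims:
        raise ValueError(
            f"image dims {values.shape[:3]} do not match model {model.vol_dims}"
        )
    if values.shape[3] != model.n_image_categories:
        raise ValueError("image has the wrong number of categories")
    m1 = model.n_image_categories
    patches, grid = tile(values, model.patch_size)
    if grid != model.grid_dims:
        raise ValueError("patch grid mismatch")
    w_patches = None
    if voxel_weights is not None:
        vw = np.asarray(voxel_weights, dtype=float)
        if vw.shape != model.vol_dims:
            raise ValueError("weight volume dims mismatch")
        # tiling zero-pads, so padded voxels keep weight zero as in training
        w_patches, _ = tile(vw, model.patch_size)
    elif pad_dims(model.vol_dims, model.patch_size) != model.vol_dims:
        w_patches, _ = tile(np.ones(model.vol_dims), model.patch_size)
    if cache is None:
        cache = build_encoder_cache(model, voxel_weights=w_patches)
    f_flat = [patches[pid].reshape(-1) for pid in range(len(model.patches))]
    zs = [np.zeros(p.n_components) for p in model.patches]
    red, black = red_black_schedule(grid)
    for _ in range(config.sweeps):
        for colour in (red, black):
            for pid in colour:
                if model.patches[pid].n_components == 0:
                    continue
                ids = neighbour_ids(pid, grid)
                y = (
                    np.concatenate([zs[q] for q in ids])
                    if ids else np.zeros(0)
                )
                z = zs[pid]
                pc = cache.patches[pid]
                for _ in range(config.inner_iters):
                    z = encode_iterate(f_flat[pid], y, z, pc, m1)
                zs[pid] = z
    return zs


def _reconstruct(zs, model, which: str) -> np.ndarray:
    """Per-voxel softmax reconstruction from one channel set's basis."""
    out_patches = []
    for pid, p in enumerate(model.patches):
        basis = p.basis_image if which == "image" else p.basis_label
        i, m, k = basis.W.shape
        eta = (basis.W @ zs[pid] + basis.mu) if k else basis.mu
        rho = softmax_simplex(eta)
        full = np.concatenate([rho, (1.0 - rho.sum(axis=-1))[:, None]], axis=-1)
        out_patches.append(full)
    return out_patches


def decode(zs: Sequence[np.ndarray], model: TrainedModel) -> np.ndarray:
    """Decode latents into a probabilistic label map.

    Returns (X, Y, Z, C) with one channel per global label code (ascending
    order, per-voxel sum 1).  Each patch's local categories are mapped back
    to the global codes through its label subset.
    """
    codes = model.label_codes
    c = codes.size
    n_vox = int(np.prod(model.patch_size))
    prob_patches = np.zeros((len(model.patches), n_vox, c))
    locals_ = _reconstruct(zs, model, "label")
    for pid, p in enumerate(model.patches):
        pos = np.searchsorted(codes, p.label_subset)
        prob_patches[pid][:, pos] = locals_[pid]
    vol = untile(prob_patches, model.grid_dims, model.patch_size,
                 out_dims=model.vol_dims)
    return vol


def synthesize_template(zs: Sequence[np.ndarray], model: TrainedModel) -> np.ndarray:
    """Subject-specific tissue template: (X, Y, Z, M1 + 1) probabilities.

    The softmax reconstruction of the image channel set at the encoded
    latents; intended as the moving target for an external registration
    refinement.  The last channel is the reference-category residual.
    """
    locals_ = _reconstruct(zs, model, "image")
    patches = np.stack(locals_)
    return untile(patches, model.grid_dims, model.patch_size,
                  out_dims=model.vol_dims)


def hard_label(prob: np.ndarray, codes: Optional[np.ndarray] = None) -> np.ndarray:
    """Most probable label per voxel; ties broken by the lowest code."""
    prob = np.asarray(prob, dtype=float)
    idx = np.argmax(prob, axis=-1)  # first max: lowest channel wins ties
    if codes is None:
        return idx
    codes = np.asarray(codes)
    return codes[idx]


def apply_model(
    model: TrainedModel,
    image: np.ndarray | CategoricalVolume,
    voxel_weights: Optional[np.ndarray] = None,
    config: Optional[ApplyConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode then decode a target image.

    Returns ``(prob, codes)``: the (X, Y, Z, C) probabilistic label map and
    the global code per channel.  With ``config.hard`` the first element is
    the 3D integer hard labelling instead.  With ``config.sample`` the
    decode uses a draw from N(z_hat, V) rather than the posterior mean.
    """
    config = config or ApplyConfig()
    cache = None
    zs = encode(model, image, voxel_weights=voxel_weights, config=config,
                cache=cache)
    if config.sample:
        rng = np.random.default_rng(config.seed)
        cache = build_encoder_cache(model, voxel_weights=None)
        zs = [
            z + np.linalg.cholesky(pc.V) @ rng.standard_normal(z.shape[0])
            if z.size else z
            for z, pc in zip(zs, cache.patches)
        ]
    prob = decode(zs, model)
    if config.hard:
        return hard_label(prob, model.label_codes), model.label_codes
    return prob, model.label_codes
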