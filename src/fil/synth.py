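"""Synthetic paired tissue/label volumes from the model's own generative
process, plus Dice-overlap evaluation.

The generator samples, per patch, smooth mean and basis fields for both
channel sets; per subject, a latent field over the patch grid from a
first-order Gaussian autoregression (so latents of neighbouring patches are
correlated — structure the trained CRF should then detect); and emits hard
categorical draws from ``Cat(softmax(W z + mu))`` at every voxel.  Ground
truth (bases, means and latents) is retained so that recovery can be scored
by predictive Dice overlap and principal angles between latent subspaces —
never by elementwise basis comparison, which is meaningless under the
rotation ambiguity of any factor model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.ndimage

from .io import tile, untile
from .label import ApplyConfig, apply_model, hard_label
from .model import TrainedModel
from .simplex import softmax_simplex

__all__ = ["SynthConfig", "SynthDataset", "generate", "dice", "recovery_report"]


@dataclass
class SynthConfig:
    """Conditions of the synthetic study.

    ``m1`` / ``m2`` count explicit categories (one more category, the
    reference, is implicit: label code 0 is the background / reference).
    ``smoothness`` in [0, 1) is the latent correlation between face-adjacent
    patches; ``basis_scale`` sets the total latent-driven logit standard
    deviation per voxel; ``mu_scale`` the spread of the mean logits.
    """

    dims: tuple[int, int, int] = (16, 16, 16)
    patch_size: tuple[int, int, int] = (4, 4, 4)
    m1: int = 2
    m2: int = 4
    k_true: int = 3
    n_subjects: int = 120
    smoothness: float = 0.6
    basis_scale: float = 2.0
    mu_scale: float = 1.0
    field_fwhm: float = 4.0  # voxels; spatial smoothness of mu and W fields
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.patch_size = tuple(int(p) for p in self.patch_size)
        if any(d % p for d, p in zip(self.dims, self.patch_size)):
            raise ValueError("dims must be multiples of patch_size")
        if not 0 <= self.smoothness < 1:
            raise ValueError("smoothness must be in [0, 1)")
        if self.k_true < 0 or self.n_subjects < 1:
            raise ValueError("invalid k_true or n_subjects")


@dataclass
class SynthDataset:
    """Sampled volumes plus the generating ground truth."""

    config: SynthConfig
    images: list[np.ndarray]        # (X, Y, Z, M1) one-hot, reference implicit
    labels: list[np.ndarray]        # (X, Y, Z) int codes, 0 = background
    mu_image: np.ndarray            # (P, I, M1)
    mu_label: np.ndarray            # (P, I, M2)
    w_image: np.ndarray             # (P, I, M1, K)
    w_label: np.ndarray             # (P, I, M2, K)
    z: np.ndarray                   # (N, P, K)
    grid_dims: tuple[int, int, int] = (0, 0, 0)

    @property
    def label_codes(self) -> np.ndarray:
        return np.arange(self.config.m2 + 1)


def _smooth_field(rng, dims, shape_tail, fwhm) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian fields over the volume."""
    sigma = fwhm / np.sqrt(8 * np.log(2))
    out = rng.standard_normal(dims + shape_tail)
    for idx in np.ndindex(shape_tail):
        sl = (slice(None),) * 3 + idx
        sm = scipy.ndimage.gaussian_filter(out[sl], sigma, mode="wrap")
        sd = sm.std()
        out[sl] = sm / sd if sd > 0 else sm
    return out


def _ar_latents(rng, n, grid, k, rho) -> np.ndarray:
    """First-order Gaussian autoregression of z over the patch grid.

    Separable AR(1) along each grid axis with coefficient ``rho``; marginal
    variance 1, face-neighbour correlation ``rho``.
    """
    gx, gy, gz = grid
    z = rng.standard_normal((n, gx, gy, gz, k))
    if rho > 0:
        c = np.sqrt(1.0 - rho * rho)
        for ax in (1, 2, 3):
            z = np.moveaxis(z, ax, 1)
            for j in range(1, z.shape[1]):
                z[:, j] = rho * z[:, j - 1] + c * z[:, j]
            z = np.moveaxis(z, 1, ax)
    # flatten grid x fastest to match the patch ordering
    return z.transpose(0, 3, 2, 1, 4).reshape(n, gx * gy * gz, k)


def _sample_categorical(rng, prob_full: np.ndarray) -> np.ndarray:
    """Sample category indices from (…, C) probabilities (C sums to 1)."""
    c = prob_full.shape[-1]
    cum = np.cumsum(prob_full, axis=-1)
    u = rng.random(prob_full.shape[:-1] + (1,))
    return np.minimum((u > cum).sum(axis=-1), c - 1)


def generate(config: Optional[SynthConfig] = None) -> SynthDataset:
    """Sample a dataset from the patch-factorisation generative process."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    dims, ps = config.dims, config.patch_size
    m1, m2, k = config.m1, config.m2, config.k_true

    mu1_vol = config.mu_scale * _smooth_field(rng, dims, (m1,), config.field_fwhm)
    mu2_vol = config.mu_scale * _smooth_field(rng, dims, (m2,), config.field_fwhm)
    scale = config.basis_scale / np.sqrt(max(k, 1))
    w1_vol = scale * _smooth_field(rng, dims, (m1, k), config.field_fwhm)
    w2_vol = scale * _smooth_field(rng, dims, (m2, k), config.field_fwhm)

    mu1, grid = tile(mu1_vol, ps)
    mu2, _ = tile(mu2_vol, ps)
    w1 = tile(w1_vol.reshape(dims + (m1 * k,)), ps)[0].reshape(-1, int(np.prod(ps)), m1, k)
    w2 = tile(w2_vol.reshape(dims + (m2 * k,)), ps)[0].reshape(-1, int(np.prod(ps)), m2, k)

    n = config.n_subjects
    z = _ar_latents(rng, n, grid, k, config.smoothness)

    eta1 = np.einsum("pimk,npk->npim", w1, z, optimize=True) + mu1  # (N,P,I,M1)
    eta2 = np.einsum("pimk,npk->npim", w2, z, optimize=True) + mu2
    rho1 = softmax_simplex(eta1)
    rho2 = softmax_simplex(eta2)
    full1 = np.concatenate([rho1, (1 - rho1.sum(-1))[..., None]], axis=-1)
    full2 = np.concatenate([rho2, (1 - rho2.sum(-1))[..., None]], axis=-1)

    cat1 = _sample_categorical(rng, full1)  # index m1 = reference
    cat2 = _sample_categorical(rng, full2)

    images, labels = [], []
    eye1 = np.eye(m1 + 1)[:, :m1]  # one-hot, reference row all-zero
    for s in range(n):
        img_patches = eye1[cat1[s]]  # (P, I, M1)
        images.append(untile(img_patches, grid, ps, out_dims=dims))
        # label codes: explicit categories are 1..M2, reference/background 0
        code_patches = np.where(cat2[s] < m2, cat2[s] + 1, 0)
        labels.append(untile(code_patches, grid, ps, out_dims=dims).astype(int))
    return SynthDataset(
        config=config, images=images, labels=labels,
        mu_image=mu1, mu_label=mu2, w_image=w1, w_label=w2, z=z,
        grid_dims=grid,
    )


def true_label_probabilities(ds: SynthDataset, subject: int) -> np.ndarray:
    """Generative label probabilities (X, Y, Z, M2 + 1) for one subject,
    channels ordered by global code (0..M2)."""
    eta = np.einsum("pimk,pk->pim", ds.w_label, ds.z[subject], optimize=True) + ds.mu_label
    rho = softmax_simplex(eta)
    full = np.concatenate([(1 - rho.sum(-1))[..., None], rho], axis=-1)  # code order
    return untile(full, ds.grid_dims, ds.config.patch_size, out_dims=ds.config.dims)


def dice(
    a: np.ndarray, b: np.ndarray, classes: Optional[Sequence[int]] = None
) -> tuple[dict[int, float], float]:
    """Dice-Sørensen overlap per class and its mean.

    ``2 |A_c ∩ B_c| / (|A_c| + |B_c|)`` for each class ``c``; classes absent
    from both volumes are reported as NaN and excluded from the mean.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("volumes must have the same dimensions")
    if classes is None:
        classes = np.union1d(np.unique(a), np.unique(b))
    per_class: dict[int, float] = {}
    vals = []
    for c in classes:
        na = int((a == c).sum())
        nb = int((b == c).sum())
        if na + nb == 0:
            per_class[int(c)] = float("nan")
            continue
        inter = int(((a == c) & (b == c)).sum())
        d = 2.0 * inter / (na + nb)
        per_class[int(c)] = d
        vals.append(d)
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_class, mean


def _principal_angles(w_true: np.ndarray, w_est: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spaces of two stacked
    basis matrices."""
    if w_true.shape[1] == 0 or w_est.shape[1] == 0:
        return np.array([])
    return scipy.linalg.subspace_angles(w_true, w_est)


def recovery_report(
    dataset: SynthDataset,
    model: TrainedModel,
    heldout: Sequence[int],
    baseline: Optional[TrainedModel] = None,
    apply_config: Optional[ApplyConfig] = None,
) -> dict:
    """Score a trained model against the generative ground truth.

    Reports mean held-out hard-label DSC (and the same for a K = 0
    majority-voting baseline when supplied), mean principal angles between
    the true and estimated per-patch joint bases, and the mean held-out
    reconstruction log-likelihood of the predicted label probabilities.
    """
    apply_config = apply_config or ApplyConfig()
    out: dict = {}

    def _mean_dsc(m: TrainedModel) -> float:
        scores = []
        for s in heldout:
            prob, codes = apply_model(m, dataset.images[s], config=apply_config)
            pred = hard_label(prob, codes)
            _, mean = dice(pred, dataset.labels[s])
            scores.append(mean)
        return float(np.mean(scores))

    out["dsc_model"] = _mean_dsc(model)
    if baseline is not None:
        out["dsc_baseline"] = _mean_dsc(baseline)

    angles = []
    for pid, p in enumerate(model.patches):
        if p.n_components == 0 or dataset.config.k_true == 0:
            continue
        i = p.basis_image.W.shape[0]
        k_est = p.n_components
        w_est = np.concatenate([
            p.basis_image.W.reshape(i * dataset.config.m1, k_est),
            _label_rows(p, dataset).reshape(-1, k_est),
        ])
        w_true = np.concatenate([
            dataset.w_image[pid].reshape(-1, dataset.config.k_true),
            dataset.w_label[pid].reshape(-1, dataset.config.k_true),
        ])
        ang = _principal_angles(w_true, w_est)
        if ang.size:
            angles.append(ang.mean())
    out["mean_principal_angle"] = float(np.mean(angles)) if angles else float("nan")

    loglik = []
    eps = 1e-12
    for s in heldout:
        prob, codes = apply_model(model, dataset.images[s], config=apply_config)
        onehot_idx = np.searchsorted(codes, dataset.labels[s])
        p_true = np.take_along_axis(prob, onehot_idx[..., None], axis=-1)[..., 0]
        loglik.append(float(np.log(p_true + eps).mean()))
    out["mean_label_loglik"] = float(np.mean(loglik))
    return out


def _label_rows(p, dataset: SynthDataset) -> np.ndarray:
    """Estimated label basis rows aligned to the generator's explicit
    categories (codes 1..M2); rows for codes the patch dropped are zero."""
    m2 = dataset.config.m2
    i, m_loc, k = p.basis_label.W.shape
    out = np.zeros((i, m2, k))
    for j, code in enumerate(p.label_subset[:-1]):
        if 1 <= code <= m2:
            out[:, code - 1, :] = p.basis_label.W[:, j, :]
    return out
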