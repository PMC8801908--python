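"""Scikit-learn-style estimator wrapping training and labelling.

The estimator treats each training example as a pair of spatially
normalised volumes: a categorical tissue image (X, Y, Z, M1 explicit
channels) and an anatomical label map (3D integer codes).  ``fit`` learns
the per-patch factorisation, ``predict`` hard-labels unseen images,
``predict_proba`` returns probabilistic label maps, and ``transform``
exposes the encoded per-patch latents.  The class composes with sklearn's
``get_params`` / ``set_params`` / ``clone`` machinery.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .label import ApplyConfig, apply_model, decode, encode, hard_label
from .model import TrainConfig
from .mrf import MRFPriorConfig
from .synth import dice
from .train import train

__all__ = ["FactorisationLabeller"]


class FactorisationLabeller(BaseEstimator):
    """Patch-wise multinomial-PCA label propagation.

    Parameters mirror the training schedule: ``n_components`` is the
    per-patch latent budget (``K``; 0 gives the mean-only majority-voting
    model), ``aug_radius`` / ``aug_sd`` control translation augmentation,
    and ``nu0`` / ``v0`` the Wishart prior of the patch-coupling CRF.

    Attributes
    ----------
    model_ : TrainedModel
        The fitted patch-grid model.
    label_codes_ : ndarray
        Global label codes seen during fit (ascending).
    grid_dims_ : tuple
        Patch-grid dimensions.
    """

    def __init__(
        self,
        patch_size: tuple[int, int, int] = (4, 4, 4),
        n_components: int = 24,
        outer_iters: int = 4,
        em_subiters: int = 5,
        estep_repeats: int = 5,
        mstep_repeats: int = 5,
        prune_every: int = 2,
        prune_tol: float = 1e-6,
        aug_radius: float = 3.0,
        aug_sd: float = 2.0,
        nu0: float | str = "least_informative",
        v0: float = 1.0,
        sweeps: int = 10,
        inner_iters: int = 5,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.n_components = n_components
        self.outer_iters = outer_iters
        self.em_subiters = em_subiters
        self.estep_repeats = estep_repeats
        self.mstep_repeats = mstep_repeats
        self.prune_every = prune_every
        self.prune_tol = prune_tol
        self.aug_radius = aug_radius
        self.aug_sd = aug_sd
        self.nu0 = nu0
        self.v0 = v0
        self.sweeps = sweeps
        self.inner_iters = inner_iters
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            patch_size=tuple(self.patch_size),
            k_max=self.n_components,
            outer_iters=self.outer_iters,
            em_subiters=self.em_subiters,
            estep_repeats=self.estep_repeats,
            mstep_repeats=self.mstep_repeats,
            prune_every=self.prune_every,
            prune_tol=self.prune_tol,
            aug_radius=self.aug_radius,
            aug_sd=self.aug_sd,
            mrf=MRFPriorConfig(nu0=self.nu0, v0=self.v0),
            seed=self.random_state,
        )

    def _apply_config(self, hard: bool = False) -> ApplyConfig:
        return ApplyConfig(sweeps=self.sweeps, inner_iters=self.inner_iters,
                           hard=hard)

    def fit(self, X: Sequence, y: Sequence,
            voxel_weights: Optional[Sequence[np.ndarray]] = None):
        """Fit to paired image (``X``) and label (``y``) volumes."""
        self.model_ = train(X, y, weights=voxel_weights,
                            config=self._train_config())
        self.label_codes_ = self.model_.label_codes
        self.grid_dims_ = self.model_.grid_dims
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X: Sequence,
                      voxel_weights: Optional[Sequence[np.ndarray]] = None
                      ) -> list[np.ndarray]:
        """Probabilistic label maps, one (X, Y, Z, C) array per volume."""
        self._check_fitted()
        cfg = self._apply_config()
        out = []
        for i, x in enumerate(X):
            w = voxel_weights[i] if voxel_weights is not None else None
            prob, _ = apply_model(self.model_, x, voxel_weights=w, config=cfg)
            out.append(prob)
        return out

    def predict(self, X: Sequence,
                voxel_weights: Optional[Sequence[np.ndarray]] = None
                ) -> list[np.ndarray]:
        """Hard label volumes (most probable code per voxel)."""
        return [
            hard_label(p, self.label_codes_)
            for p in self.predict_proba(X, voxel_weights=voxel_weights)
        ]

    def transform(self, X: Sequence) -> list[list[np.ndarray]]:
        """Encoded per-patch latent means for each volume."""
        self._check_fitted()
        cfg = self._apply_config()
        return [encode(self.model_, x, config=cfg) for x in X]

    def score(self, X: Sequence, y: Sequence) -> float:
        """Mean Dice overlap between predictions and reference labellings."""
        preds = self.predict(X)
        return float(np.mean([dice(p, np.asarray(t))[1] for p, t in zip(preds, y)]))
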