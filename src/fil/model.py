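"""Containers for training configuration and the trained patch-grid model."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .mrf import MRFPosterior, MRFPriorConfig
from .vem import PatchBasis

__all__ = ["TrainConfig", "PatchModel", "TrainedModel"]


@dataclass
class TrainConfig:
    """Training schedule and priors.

    Defaults follow the settings used for the final model fit: 4x4x4-voxel
    patches, up to 24 latent components per patch, four outer iterations each
    holding five EM sub-iterations with five E-step and five M-step repeats,
    pruning after every second outer iteration, translation augmentation up
    to a 3-voxel radius with Gaussian weighting of standard deviation 2
    voxels, and a least-informative proper Wishart prior with v0 = 1.
    """

    patch_size: tuple[int, int, int] = (4, 4, 4)
    k_max: int = 24
    outer_iters: int = 4
    em_subiters: int = 5
    estep_repeats: int = 5
    mstep_repeats: int = 5
    prune_every: int = 2
    prune_tol: float = 1e-6
    aug_radius: float = 3.0
    aug_sd: float = 2.0
    mrf: MRFPriorConfig = field(default_factory=MRFPriorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.patch_size = tuple(int(p) for p in self.patch_size)
        if any(p < 1 for p in self.patch_size) or len(self.patch_size) != 3:
            raise ValueError("patch_size must be three positive integers")
        for name in ("k_max", "outer_iters", "em_subiters", "estep_repeats",
                     "mstep_repeats", "prune_every"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aug_radius < 0:
            raise ValueError("aug_radius must be >= 0")
        if self.aug_radius > 0 and self.aug_sd <= 0:
            raise ValueError("aug_sd must be > 0 when augmenting")
        if isinstance(self.mrf, dict):
            self.mrf = MRFPriorConfig(**self.mrf)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patch_size"] = list(self.patch_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "mrf" in d and isinstance(d["mrf"], dict):
            d["mrf"] = MRFPriorConfig(**d["mrf"])
        return cls(**d)


@dataclass
class PatchModel:
    """Per-patch parameters of a trained model.

    ``label_subset`` lists the global label codes this patch encodes, with
    the patch-local reference category last; its length is the local
    M(2) + 1.  The two bases share the latent dimension K.
    """

    basis_image: PatchBasis
    basis_label: PatchBasis
    mrf: MRFPosterior
    label_subset: np.ndarray

    def __post_init__(self) -> None:
        self.label_subset = np.asarray(self.label_subset, dtype=int)
        if self.label_subset.size == 0:
            raise ValueError("label subset must be non-empty")
        if self.basis_image.n_components != self.basis_label.n_components:
            raise ValueError("channel sets disagree on K")

    @property
    def n_components(self) -> int:
        return self.basis_image.n_components


@dataclass
class TrainedModel:
    """A trained patch-grid factorisation model.

    ``label_codes`` are all global label codes seen in training, sorted
    ascending (decoded probability channels follow this order).
    ``vol_dims`` are the unpadded input volume dimensions; the patch grid
    tiles the zero-padded volume.
    """

    patch_size: tuple[int, int, int]
    grid_dims: tuple[int, int, int]
    vol_dims: tuple[int, int, int]
    n_image_categories: int
    label_codes: np.ndarray
    patches: list[PatchModel]
    config: TrainConfig
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.patch_size = tuple(int(p) for p in self.patch_size)
        self.grid_dims = tuple(int(g) for g in self.grid_dims)
        self.vol_dims = tuple(int(v) for v in self.vol_dims)
        self.label_codes = np.asarray(self.label_codes, dtype=int)
        self.affine = np.asarray(self.affine, dtype=float)
        if len(self.patches) != int(np.prod(self.grid_dims)):
            raise ValueError("patch list does not match grid dims")

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def components_per_patch(self) -> np.ndarray:
        return np.array([p.n_components for p in self.patches])
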