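import numpy as np
import pytest

from fil.io import one_hot
from fil.model import PatchModel, TrainedModel, TrainConfig
from fil.mrf import MRFPosterior, neighbour_ids
from fil.synth import SynthConfig, SynthDataset, generate
from fil.vem import PatchBasis


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset() -> SynthDataset:
    """A small synthetic cohort shared across tests (8^3, 8 patches)."""
    return generate(SynthConfig(dims=(8, 8, 8), n_subjects=40, seed=7))


def model_from_truth(ds: SynthDataset) -> TrainedModel:
    """Wrap the generator's ground-truth parameters as a TrainedModel."""
    cfg = ds.config
    grid = ds.grid_dims
    k = cfg.k_true
    patches = []
    for pid in range(int(np.prod(grid))):
        layout = [(q, k) for q in neighbour_ids(pid, grid)]
        k_total = k + sum(kj for _, kj in layout)
        mrf = MRFPosterior(
            Psi=np.eye(k_total) / max(k_total + 1, 1),
            nu=float(k_total + 1),
            k_self=k,
            layout=layout,
        )
        patches.append(PatchModel(
            basis_image=PatchBasis(ds.w_image[pid], ds.mu_image[pid], "image"),
            basis_label=PatchBasis(ds.w_label[pid], ds.mu_label[pid], "label"),
            mrf=mrf,
            label_subset=np.concatenate([np.arange(1, cfg.m2 + 1), [0]]),
        ))
    return TrainedModel(
        patch_size=cfg.patch_size,
        grid_dims=grid,
        vol_dims=cfg.dims,
        n_image_categories=cfg.m1,
        label_codes=np.arange(cfg.m2 + 1),
        patches=patches,
        config=TrainConfig(patch_size=cfg.patch_size, k_max=k, aug_radius=0.0),
    )
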