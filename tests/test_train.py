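"""Training loop: category reduction, augmentation, pruning, determinism."""

import numpy as np
import pytest

from fil.label import ApplyConfig, apply_model, decode, hard_label
from fil.model import TrainConfig
from fil.mrf import MRFPriorConfig, neighbour_ids
from fil.simplex import softmax_simplex
from fil.synth import SynthConfig, generate
from fil.train import (
    _init_mrf,
    _PatchState,
    augmentation_offsets,
    prune,
    reduce_label_categories,
    train,
)
from fil.vem import PatchBasis, PatchData


class TestReduceLabelCategories:
    def test_background_only_patch(self):
        codes = np.array([0, 17, 53])
        full = np.zeros((3, 4, 3))
        full[:, :, 0] = 1.0  # everything background
        subset, f = reduce_label_categories(full, codes)
        np.testing.assert_array_equal(subset, [0])
        assert f.shape == (3, 4, 0)

    def test_subset_mapping(self):
        codes = np.array([0, 17, 53])
        full = np.zeros((2, 2, 3))
        full[0, :, 1] = 1.0   # code 17
        full[1, 0, 2] = 1.0   # code 53
        full[1, 1, 0] = 1.0   # background
        subset, f = reduce_label_categories(full, codes)
        np.testing.assert_array_equal(subset, [17, 53, 0])
        assert f.shape == (2, 2, 2)
        np.testing.assert_array_equal(f[0, :, 0], [1.0, 1.0])  # 17 -> local 0
        np.testing.assert_array_equal(f[1, :, 1], [1.0, 0.0])  # 53 -> local 1

    def test_mass_conservation(self, rng):
        codes = np.arange(5)
        full = rng.dirichlet(np.ones(5), size=(6, 8))
        full[:, :, 3] = 0.0  # code 3 absent from the patch
        subset, f = reduce_label_categories(full, codes)
        assert 3 not in subset
        for j, code in enumerate(subset[:-1]):
            np.testing.assert_allclose(
                f[:, :, j].sum(), full[:, :, code].sum(), atol=1e-12)

    def test_zero_weight_subjects_ignored(self):
        codes = np.array([0, 1, 2])
        full = np.zeros((2, 1, 3))
        full[0, :, 1] = 1.0
        full[1, :, 2] = 1.0
        w = np.array([[1.0], [0.0]])  # second subject carries no weight
        subset, _ = reduce_label_categories(full, codes, weights=w)
        assert 2 not in subset


class TestAugmentationOffsets:
    def test_radius_zero(self):
        assert augmentation_offsets(0.0) == [((0, 0, 0), 1.0)]

    @pytest.mark.parametrize("radius,count", [(1.5, 19), (3.0, 123)])
    def test_offset_counts(self, radius, count):
        offs = augmentation_offsets(radius, sd=2.0)
        assert len(offs) == count

    def test_weights_normalised_and_gaussian(self):
        offs = augmentation_offsets(2.0, sd=1.5)
        w = np.array([wi for _, wi in offs])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        centre = dict((o, wi) for o, wi in offs)
        ratio = centre[(1, 0, 0)] / centre[(0, 0, 0)]
        assert ratio == pytest.approx(np.exp(-0.5 / 1.5**2), abs=1e-12)

    def test_all_offsets_within_radius(self):
        for (d, _w) in augmentation_offsets(2.5, sd=2.0):
            assert np.linalg.norm(d) <= 2.5


def _toy_states(rng, k=3, n=15, grid=(2, 1, 1)):
    cfg = TrainConfig(patch_size=(2, 2, 1), k_max=k, aug_radius=0.0)
    states = []
    for pid in range(int(np.prod(grid))):
        i, m1, m2 = 4, 2, 2
        f1 = np.eye(m1 + 1)[:, :m1][rng.integers(0, m1 + 1, size=(n, i))]
        f2 = np.eye(m2 + 1)[:, :m2][rng.integers(0, m2 + 1, size=(n, i))]
        states.append(_PatchState(
            data_image=PatchData(f1),
            data_label=PatchData(f2),
            basis_image=PatchBasis(rng.normal(0, 0.5, (i, m1, k)),
                                   rng.normal(0, 0.5, (i, m1))),
            basis_label=PatchBasis(rng.normal(0, 0.5, (i, m2, k)),
                                   rng.normal(0, 0.5, (i, m2))),
            Z=rng.normal(size=(n, k)),
            V=np.eye(k) * 0.1,
            mrf=None,
            label_subset=np.array([1, 2, 0]),
        ))
    for pid, st in enumerate(states):
        layout = [(q, k) for q in neighbour_ids(pid, grid)]
        st.mrf = _init_mrf(k, layout, cfg)
    return states, grid


class TestPrune:
    def test_rotation_preserves_predictions(self, rng):
        states, grid = _toy_states(rng)
        before = [
            softmax_simplex(np.einsum("imk,nk->nim", st.basis_image.W, st.Z)
                            + st.basis_image.mu)
            for st in states
        ]
        prune(states, grid, tol=0.0)  # rotate only, drop nothing
        assert all(st.k == 3 for st in states)
        for st, b in zip(states, before):
            after = softmax_simplex(
                np.einsum("imk,nk->nim", st.basis_image.W, st.Z)
                + st.basis_image.mu)
            np.testing.assert_allclose(after, b, atol=1e-10)

    def test_latents_orthogonal_after_prune(self, rng):
        states, grid = _toy_states(rng)
        prune(states, grid, tol=0.0)
        for st in states:
            gram = st.Z.T @ st.Z
            off = gram - np.diag(np.diag(gram))
            assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_dead_component_dropped(self, rng):
        states, grid = _toy_states(rng)
        for st in states:
            st.Z[:, -1] = 0.0
            st.basis_image.W[:, :, -1] = 0.0
            st.basis_label.W[:, :, -1] = 0.0
        prune(states, grid, tol=1e-6)
        assert all(st.k == 2 for st in states)
        for st in states:
            assert st.mrf.k_self == 2
            assert st.mrf.k_total == 2 + sum(kj for _, kj in st.mrf.layout)
            np.linalg.cholesky(st.mrf.Psi)

    def test_k_never_increases(self, rng):
        states, grid = _toy_states(rng)
        ks = [st.k for st in states]
        prune(states, grid, tol=1e-3)
        assert all(st.k <= k0 for st, k0 in zip(states, ks))


@pytest.fixture(scope="module")
def tiny_training():
    ds = generate(SynthConfig(dims=(8, 8, 8), n_subjects=20, seed=3))
    cfg = TrainConfig(k_max=4, outer_iters=2, aug_radius=0.0, seed=5)
    return ds, cfg, train(ds.images[:16], ds.labels[:16], config=cfg)


class TestTrain:
    def test_deterministic_given_seed(self, tiny_training):
        ds, cfg, model = tiny_training
        model2 = train(ds.images[:16], ds.labels[:16], config=cfg)
        for p, q in zip(model.patches, model2.patches):
            np.testing.assert_array_equal(p.basis_image.W, q.basis_image.W)
            np.testing.assert_array_equal(p.basis_label.mu, q.basis_label.mu)
            np.testing.assert_array_equal(p.mrf.Psi, q.mrf.Psi)

    def test_patch_grid_covers_volume(self, tiny_training):
        _, _, model = tiny_training
        assert model.grid_dims == (2, 2, 2)
        assert model.vol_dims == (8, 8, 8)

    def test_k_respects_budget(self, tiny_training):
        _, cfg, model = tiny_training
        assert (model.components_per_patch() <= cfg.k_max).all()

    def test_elbo_nondecreasing_within_subiterations(self):
        ds = generate(SynthConfig(dims=(8, 8, 8), n_subjects=10, seed=11))
        cfg = TrainConfig(k_max=3, outer_iters=1, aug_radius=0.0, seed=1,
                          prune_every=0)
        trace: dict = {}
        train(ds.images, ds.labels, config=cfg, trace=trace)
        assert trace["elbo_subiters"]
        for series in trace["elbo_subiters"]:
            diffs = np.diff(series)
            floor = -1e-6 * np.abs(np.asarray(series[:-1]))
            assert (diffs >= floor).all()

    def test_mismatched_inputs_rejected(self, tiny_training):
        ds, cfg, _ = tiny_training
        with pytest.raises(ValueError):
            train(ds.images[:3], ds.labels[:2], config=cfg)
        with pytest.raises(ValueError):
            train([], [], config=cfg)


@pytest.fixture(scope="module")
def k0_model():
    ds = generate(SynthConfig(dims=(8, 8, 8), n_subjects=25, seed=9))
    cfg = TrainConfig(k_max=0, outer_iters=4, aug_radius=0.0, seed=2)
    return ds, train(ds.images, ds.labels, config=cfg)


class TestMajorityVotingBaseline:
    """K = 0 collapses the model to per-voxel weighted label frequencies."""

    def test_decode_matches_label_frequencies(self, k0_model):
        ds, model = k0_model
        zs = [np.zeros(0)] * model.n_patches
        prob = decode(zs, model)
        counts = np.zeros(prob.shape)
        for lab in ds.labels:
            counts += (lab[..., None] == model.label_codes)
        freq = counts / counts.sum(axis=-1, keepdims=True)
        # boundary frequencies (0 or 1) are only reached asymptotically by
        # the bound-based updates; interior ones must match tightly
        interior = (freq > 0.05) & (freq < 0.95)
        np.testing.assert_allclose(prob[interior], freq[interior], atol=2e-3)
        np.testing.assert_allclose(prob, freq, atol=1e-2)

    def test_hard_labels_are_modal_training_labels(self, k0_model):
        ds, model = k0_model
        prob, codes = apply_model(model, ds.images[0], config=ApplyConfig())
        pred = hard_label(prob, codes)
        counts = np.zeros(prob.shape)
        for lab in ds.labels:
            counts += (lab[..., None] == model.label_codes)
        modal = model.label_codes[np.argmax(counts, axis=-1)]
        # ignore voxels where the vote is tied to within the mu tolerance
        top2 = np.sort(counts, axis=-1)[..., -2:]
        clear = top2[..., 1] > top2[..., 0]
        assert (pred[clear] == modal[clear]).all()

    def test_prediction_independent_of_target_image(self, k0_model):
        ds, model = k0_model
        p1, _ = apply_model(model, ds.images[0])
        p2, _ = apply_model(model, ds.images[1])
        np.testing.assert_array_equal(p1, p2)


class TestAugmentedTraining:
    def test_augmented_run_trains_and_labels(self):
        ds = generate(SynthConfig(dims=(8, 8, 8), n_subjects=6, seed=13))
        cfg = TrainConfig(k_max=2, outer_iters=1, aug_radius=1.0, aug_sd=2.0,
                          seed=4)
        model = train(ds.images[:5], ds.labels[:5], config=cfg)
        prob, _ = apply_model(model, ds.images[5])
        np.testing.assert_allclose(prob.sum(axis=-1), 1.0, atol=1e-9)

    def test_weighted_replicates_equal_duplicated_subjects(self, rng):
        # {x with weight 2} must train exactly like {x, x} with weight 1 each
        from fil.vem import LatentPosterior, mstep_W, mstep_mu

        f = np.eye(3)[:, :2][rng.integers(0, 3, size=(1, 4))]
        basis = PatchBasis(rng.normal(0, 0.5, (4, 2, 2)),
                           rng.normal(size=(4, 2)))
        lat1 = [LatentPosterior(np.array([0.3, -0.2]), 0.2 * np.eye(2))]
        once = PatchData(f, subject_weights=np.array([2.0]))
        twice = PatchData(np.repeat(f, 2, axis=0))
        mu_a = mstep_mu(once, basis, lat1)
        mu_b = mstep_mu(twice, basis, lat1 * 2)
        np.testing.assert_allclose(mu_a, mu_b, atol=1e-10)
        w_a, _ = mstep_W(once, basis, lat1)
        w_b, _ = mstep_W(twice, basis, lat1 * 2)
        np.testing.assert_allclose(w_a, w_b, atol=1e-10)


class TestPaddedVolumes:
    def test_non_multiple_dims_are_padded_with_zero_weight(self):
        ds = generate(SynthConfig(dims=(8, 8, 8), n_subjects=10, seed=21))
        imgs = [im[:5, :8, :8] for im in ds.images]
        labs = [la[:5, :8, :8] for la in ds.labels]
        cfg = TrainConfig(k_max=2, outer_iters=1, aug_radius=0.0, seed=6)
        model = train(imgs, labs, config=cfg)
        assert model.grid_dims == (2, 2, 2)
        assert model.vol_dims == (5, 8, 8)
        prob, codes = apply_model(model, imgs[0])
        assert prob.shape[:3] == (5, 8, 8)
        np.testing.assert_allclose(prob.sum(axis=-1), 1.0, atol=1e-9)
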