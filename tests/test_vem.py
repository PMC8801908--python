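"""Per-patch variational E- and M-steps against brute-force oracles."""

import numpy as np
import pytest
import scipy.optimize

from fil.simplex import bohning_hessian, bohning_bound, lse, softmax_simplex
from fil.vem import (
    ConditionalPrior,
    LatentPosterior,
    PatchBasis,
    PatchData,
    elbo,
    estep_update,
    mstep_W,
    mstep_mu,
)


def _random_channel(rng, n, i, m, k, soft=False):
    if soft:
        f = rng.dirichlet(np.ones(m + 1), size=(n, i))[..., :m]
    else:
        idx = rng.integers(0, m + 1, size=(n, i))
        f = np.eye(m + 1)[:, :m][idx]
    data = PatchData(f)
    basis = PatchBasis(rng.normal(0, 0.7, (i, m, k)), rng.normal(0, 0.7, (i, m)))
    return data, basis


def _bounded_objective(z, channels, prior, z_prev, subject):
    """The quadratic substitute objective the E-step maximises (oracle)."""
    val = -0.5 * (z - prior.z0) @ prior.P0 @ (z - prior.z0)
    for data, basis in channels:
        w = (np.ones(data.n_voxels) if data.voxel_weights is None
             else data.voxel_weights[subject])
        for i in range(data.n_voxels):
            eta = basis.W[i] @ z + basis.mu[i]
            eta_hat = basis.W[i] @ z_prev + basis.mu[i]
            val += w[i] * (data.f[subject, i] @ eta
                           - bohning_bound(eta, eta_hat))
    return val


class TestEstep:
    def test_prior_only_when_w_zero(self, rng):
        k = 3
        data, basis = _random_channel(rng, 2, 4, 2, k)
        basis.W = np.zeros_like(basis.W)
        prior = ConditionalPrior(rng.normal(size=k), np.diag([2.0, 1.0, 4.0]))
        post = estep_update([(data, basis)], prior, np.zeros(k), subject=0)
        np.testing.assert_allclose(post.z_hat, prior.z0, atol=1e-12)
        np.testing.assert_allclose(post.V, np.linalg.inv(prior.P0), atol=1e-12)

    @pytest.mark.parametrize("k,m,i", [(1, 1, 1), (2, 2, 3), (3, 1, 4)])
    def test_matches_numeric_maximiser(self, rng, k, m, i):
        data, basis = _random_channel(rng, 1, i, m, k)
        prior = ConditionalPrior(rng.normal(size=k) * 0.5,
                                 np.eye(k) + 0.1 * np.ones((k, k)))
        z_prev = rng.normal(size=k) * 0.3
        post = estep_update([(data, basis)], prior, z_prev, subject=0)
        res = scipy.optimize.minimize(
            lambda z: -_bounded_objective(z, [(data, basis)], prior, z_prev, 0),
            np.zeros(k), method="BFGS", options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(post.z_hat, res.x, atol=1e-6)

    def test_stationarity_residual(self, rng):
        # the solution must zero the gradient of the substitute objective
        k = 2
        channels = [_random_channel(rng, 1, 5, 2, k),
                    _random_channel(rng, 1, 5, 3, k)]
        prior = ConditionalPrior(np.zeros(k), np.eye(k))
        z_prev = rng.normal(size=k)
        post = estep_update(channels, prior, z_prev, subject=0)
        eps = 1e-6
        for j in range(k):
            e = np.zeros(k)
            e[j] = eps
            g = (_bounded_objective(post.z_hat + e, channels, prior, z_prev, 0)
                 - _bounded_objective(post.z_hat - e, channels, prior, z_prev, 0)
                 ) / (2 * eps)
            assert abs(g) < 1e-8

    def test_covariance_shrinks_with_voxels(self, rng):
        # Loewner monotone: V(I voxels) - V(I+1 voxels) is PSD
        k = 3
        data, basis = _random_channel(rng, 1, 6, 2, k)
        prior = ConditionalPrior(np.zeros(k), np.eye(k))
        sub_data = PatchData(data.f[:, :5])
        sub_basis = PatchBasis(basis.W[:5], basis.mu[:5])
        v_small = estep_update([(sub_data, sub_basis)], prior, np.zeros(k), 0).V
        v_full = estep_update([(data, basis)], prior, np.zeros(k), 0).V
        assert np.linalg.eigvalsh(v_small - v_full).min() >= -1e-12

    def test_k_zero_returns_empty(self, rng):
        data, basis = _random_channel(rng, 1, 4, 2, 0)
        prior = ConditionalPrior(np.zeros(0), np.zeros((0, 0)))
        post = estep_update([(data, basis)], prior, np.zeros(0), 0)
        assert post.z_hat.shape == (0,)

    def test_voxel_weights_scale_information(self, rng):
        # doubling every voxel weight doubles the data precision term
        k = 2
        data, basis = _random_channel(rng, 1, 4, 2, k)
        prior = ConditionalPrior(np.zeros(k), np.eye(k))
        v1 = estep_update([(data, basis)], prior, np.zeros(k), 0).V
        data2 = PatchData(data.f, voxel_weights=2 * np.ones((1, 4)))
        v2 = estep_update([(data2, basis)], prior, np.zeros(k), 0).V
        expected = np.linalg.inv(
            prior.P0 + 2 * (np.linalg.inv(v1) - prior.P0))
        np.testing.assert_allclose(v2, expected, atol=1e-10)


class TestMstepMu:
    def test_fixed_point_when_residual_zero(self):
        # one categorical voxel whose data frequency already matches softmax(mu)
        mu = np.array([[0.4]])
        p = softmax_simplex(mu)[0, 0]
        f = np.array([[[p]], [[p]]])  # soft data equal to the model mean
        data = PatchData(f)
        basis = PatchBasis(np.zeros((1, 1, 0)), mu)
        lat = [LatentPosterior(np.zeros(0), np.zeros((0, 0)))] * 2
        np.testing.assert_allclose(mstep_mu(data, basis, lat), mu, atol=1e-12)

    def test_converges_to_logit_of_frequency(self):
        # W = 0: iterated updates solve ML for a categorical proportion
        p = 0.3
        f = np.array([[[1.0]]] * 3 + [[[0.0]]] * 7)
        data = PatchData(f)
        basis = PatchBasis(np.zeros((1, 1, 0)), np.zeros((1, 1)))
        lat = [LatentPosterior(np.zeros(0), np.zeros((0, 0)))] * 10
        for _ in range(60):
            basis.mu = mstep_mu(data, basis, lat)
        assert basis.mu[0, 0] == pytest.approx(np.log(p / (1 - p)), abs=1e-8)

    def test_subject_weight_scale_invariance(self, rng):
        data, basis = _random_channel(rng, 4, 3, 2, 2)
        z = rng.normal(size=(4, 2))
        lat = [LatentPosterior(z[n], 0.1 * np.eye(2)) for n in range(4)]
        mu1 = mstep_mu(data, basis, lat)
        scaled = PatchData(data.f, subject_weights=np.full(4, 3.7))
        mu2 = mstep_mu(scaled, basis, lat)
        np.testing.assert_allclose(mu1, mu2, atol=1e-12)

    def test_no_data_errors(self):
        data = PatchData(np.zeros((2, 1, 1)), voxel_weights=np.zeros((2, 1)))
        basis = PatchBasis(np.zeros((1, 1, 0)), np.zeros((1, 1)))
        lat = [LatentPosterior(np.zeros(0), np.zeros((0, 0)))] * 2
        with pytest.raises(ValueError):
            mstep_mu(data, basis, lat)


def _w_objective(w_flat, data, mu, z, v, w_prev, k, m):
    """Bounded expected complete-data log-likelihood + log prior (oracle)."""
    w = w_flat.reshape(m, k)
    a = np.asarray(bohning_hessian(m))
    val = 0.0
    for n in range(data.f.shape[0]):
        eta_hat = w_prev @ z[n] + mu
        eta_bar = w @ z[n] + mu
        d = eta_bar - eta_hat
        rho_hat = softmax_simplex(eta_hat)
        # E over q(z): quadratic term picks up tr(A W V W^T)
        val += (data.f[n, 0] @ eta_bar
                - (lse(eta_hat) + d @ rho_hat + 0.5 * d @ a @ d
                   + 0.5 * np.trace(a @ w @ v @ w.T)))
    prec = np.eye(m) + np.ones((m, m)) / (m + 1)
    for kk in range(k):
        val -= 0.5 * w[:, kk] @ prec @ w[:, kk]
    return val


class TestMstepW:
    def test_shrinks_to_zero_without_data(self, rng):
        data, basis = _random_channel(rng, 1, 2, 2, 2)
        zero = PatchData(data.f, subject_weights=np.zeros(1))
        lat = [LatentPosterior(rng.normal(size=2), np.eye(2))]
        w_new, _ = mstep_W(zero, basis, lat)
        np.testing.assert_allclose(w_new, 0.0, atol=1e-12)

    def test_hessian_spd(self, rng):
        data, basis = _random_channel(rng, 5, 3, 2, 2)
        z = rng.normal(size=(5, 2))
        lat = [LatentPosterior(z[n], 0.3 * np.eye(2)) for n in range(5)]
        _, h = mstep_W(data, basis, lat)
        assert np.allclose(h, h.T)
        assert np.linalg.eigvalsh(h).min() > 0

    @pytest.mark.parametrize("k,m", [(1, 1), (2, 2)])
    def test_matches_numeric_maximiser(self, rng, k, m):
        data, basis = _random_channel(rng, 6, 1, m, k)
        z = rng.normal(size=(6, k))
        v = 0.2 * np.eye(k)
        lat = [LatentPosterior(z[n], v) for n in range(6)]
        w_new, _ = mstep_W(data, basis, lat)
        res = scipy.optimize.minimize(
            lambda wf: -_w_objective(wf, data, basis.mu[0], z, v,
                                     basis.W[0], k, m),
            np.zeros(m * k), method="BFGS", options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(w_new[0], res.x.reshape(m, k), atol=1e-6)


class TestElbo:
    def _setup(self, rng, n=12, i=6, m=2, k=2):
        channels = [_random_channel(rng, n, i, m, k),
                    _random_channel(rng, n, i, 3, k)]
        prior = ConditionalPrior(np.zeros(k), np.eye(k))
        lat = [LatentPosterior(np.zeros(k), np.eye(k)) for _ in range(n)]
        return channels, prior, lat

    def test_monotone_under_em_updates(self, rng):
        channels, prior, lat = self._setup(rng)
        values = []
        for _ in range(8):
            lat = [
                estep_update(channels, prior, lat[n].z_hat, n)
                for n in range(len(lat))
            ]
            values.append(elbo(channels, lat, prior))
            for data, basis in channels:
                basis.mu = mstep_mu(data, basis, lat)
                basis.W, _ = mstep_W(data, basis, lat)
            values.append(elbo(channels, lat, prior))
        diffs = np.diff(values)
        assert (diffs >= -1e-8 * np.abs(values[:-1])).all()

    def test_k_zero_is_weighted_loglik(self, rng):
        n, i, m = 5, 4, 2
        data, _ = _random_channel(rng, n, i, m, 0)
        basis = PatchBasis(np.zeros((i, m, 0)), rng.normal(size=(i, m)))
        prior = ConditionalPrior(np.zeros(0), np.zeros((0, 0)))
        lat = [LatentPosterior(np.zeros(0), np.zeros((0, 0)))] * n
        val = elbo([(data, basis)], lat, prior)
        eta = np.broadcast_to(basis.mu, data.f.shape)
        expected = (np.einsum("nim,nim->ni", data.f, eta) - lse(eta)).sum()
        assert val == pytest.approx(expected, abs=1e-10)

    def test_close_to_monte_carlo_estimate(self, rng):
        # 1-voxel, K=1 instance with a tight posterior: the bounded ELBO must
        # sit just below the sampled evidence integrand, within MC error
        k, m = 1, 1
        data, basis = _random_channel(rng, 1, 1, m, k)
        prior = ConditionalPrior(np.zeros(k), np.eye(k))
        lat = [LatentPosterior(np.array([0.3]), np.array([[0.01]]))]
        val = elbo([(data, basis)], lat, prior)
        draws = 200_000
        zs = lat[0].z_hat + np.sqrt(lat[0].V[0, 0]) * rng.standard_normal(draws)
        eta = basis.W[0] @ zs[None, :] + basis.mu[0][:, None]  # (M, S)
        ll = data.f[0, 0] @ eta - np.log1p(np.exp(eta).sum(axis=0))
        kl = 0.5 * (lat[0].V[0, 0] + lat[0].z_hat[0] ** 2 - 1
                    - np.log(lat[0].V[0, 0]))
        prec = 1 + 1 / (m + 1)
        logp_w = 0.5 * (np.log(prec) - np.log(2 * np.pi)) \
            - 0.5 * prec * basis.W[0, 0, 0] ** 2
        mc = ll.mean() - kl + logp_w
        se = ll.std() / np.sqrt(draws)
        assert val <= mc + 4 * se
        assert abs(val - mc) < 0.01
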