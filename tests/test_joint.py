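"""Joint-covariance reconstruction and Gaussian sampling."""

import numpy as np
import pytest

from gaussdyn import (
    CorrelationMatrix,
    MarginalSet,
    correlation_standardize,
    coupling_from_joint,
    JointGaussian,
    joint_factor,
    make_chain,
    marginals_from_joint,
    predict_to_ensemble,
    reconstruct_joint,
    sample_conformations,
)
from tests.conftest import random_spd, random_correlation


def _random_marginals(rng, n):
    return MarginalSet(covs=np.stack([random_spd(rng) for _ in range(n)]))


class TestReconstructJoint:
    def test_identity_correlation_gives_block_diagonal(self, rng):
        m = _random_marginals(rng, 4)
        sigma = reconstruct_joint(m, CorrelationMatrix(values=np.eye(4)))
        from scipy.linalg import block_diag

        assert np.allclose(sigma, block_diag(*m.covs), atol=1e-12)

    def test_two_residue_identity_marginals_expansion(self):
        rho = 0.6
        m = MarginalSet(covs=np.stack([np.eye(3), np.eye(3)]))
        ct = CorrelationMatrix(values=np.array([[1.0, rho], [rho, 1.0]]))
        sigma = reconstruct_joint(m, ct)
        expected = np.block([
            [np.eye(3), rho * np.eye(3)],
            [rho * np.eye(3), np.eye(3)],
        ])
        assert np.allclose(sigma, expected, atol=1e-12)

    def test_diagonal_blocks_preserve_marginals_exactly(self, rng):
        n = 6
        m = _random_marginals(rng, n)
        ct = CorrelationMatrix(values=random_correlation(rng, n))
        sigma = reconstruct_joint(m, ct)
        for i in range(n):
            assert np.abs(sigma[3 * i:3 * i + 3, 3 * i:3 * i + 3] - m.covs[i]).max() < 1e-12

    def test_spd_closure_on_random_draws(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            m = _random_marginals(rng, n)
            ct = CorrelationMatrix(values=random_correlation(rng, n))
            sigma = reconstruct_joint(m, ct)
            assert np.allclose(sigma, sigma.T, atol=1e-10)
            assert np.linalg.eigvalsh(sigma).min() > 0

    def test_indefinite_correlation_errors_with_repair_hint(self, rng):
        m = _random_marginals(rng, 3)
        bad = np.array([
            [1.0, 0.9, -0.9],
            [0.9, 1.0, 0.9],
            [-0.9, 0.9, 1.0],
        ])
        ct = CorrelationMatrix(values=bad)
        with pytest.raises(ValueError, match="repair"):
            reconstruct_joint(m, ct)
        sigma = reconstruct_joint(m, ct, repair=True)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestJointFactor:
    def test_identity_correlation_gives_blockdiag_factors(self, rng):
        m = _random_marginals(rng, 3)
        L = joint_factor(m, CorrelationMatrix(values=np.eye(3)))
        from scipy.linalg import block_diag

        expected = block_diag(*[np.linalg.cholesky(c) for c in m.covs])
        assert np.allclose(L.matrix, expected, atol=1e-8)

    def test_matches_reconstruction_and_dense_cholesky(self, rng):
        for n in (2, 5, 11, 20):
            m = _random_marginals(rng, n)
            ct = CorrelationMatrix(values=random_correlation(rng, n))
            L = joint_factor(m, ct)
            sigma = reconstruct_joint(m, ct)
            assert np.abs(L.covariance() - sigma).max() < 1e-10
            dense = np.linalg.cholesky(sigma)
            assert np.abs(dense - L.matrix).max() < 1e-8

    def test_kronecker_mixed_product_identity(self, rng):
        # (A (x) I)(B (x) I) = AB (x) I on the correlation factor's square
        n = 4
        ct = random_correlation(rng, n)
        K = np.linalg.cholesky(ct)
        KI = np.kron(K, np.eye(3))
        assert np.allclose(KI @ KI.T, np.kron(K @ K.T, np.eye(3)), atol=1e-12)


class TestSampling:
    def test_degenerate_factor_collapses_to_mean(self):
        from gaussdyn import JointFactor

        L = JointFactor(matrix=1e-12 * np.eye(6))
        mu = np.arange(6.0)
        ens = sample_conformations(mu, L, T=10, seed=0)
        assert np.abs(ens.coords.reshape(10, 6) - mu).max() < 1e-5

    def test_seed_determinism(self, rng):
        m = _random_marginals(rng, 3)
        ct = CorrelationMatrix(values=random_correlation(rng, 3))
        L = joint_factor(m, ct)
        mu = np.zeros(9)
        a = sample_conformations(mu, L, T=7, seed=5)
        b = sample_conformations(mu, L, T=7, seed=5)
        c = sample_conformations(mu, L, T=7, seed=6)
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    def test_cross_correlation_of_correlated_pair(self):
        rho = 0.8
        m = MarginalSet(covs=np.stack([np.eye(3), np.eye(3)]))
        ct = CorrelationMatrix(values=np.array([[1.0, rho], [rho, 1.0]]))
        L = joint_factor(m, ct)
        ens = sample_conformations(np.zeros(6), L, T=50_000, seed=3)
        x1 = ens.coords[:, 0, 0]
        x2 = ens.coords[:, 1, 0]
        r = np.corrcoef(x1, x2)[0, 1]
        assert 0.77 < r < 0.83

    def test_sampler_covariance_converges(self, rng):
        m = _random_marginals(rng, 2)
        ct = CorrelationMatrix(values=np.array([[1.0, 0.5], [0.5, 1.0]]))
        L = joint_factor(m, ct)
        ens = sample_conformations(np.zeros(6), L, T=50_000, seed=9)
        emp = np.cov(ens.coords.reshape(-1, 6), rowvar=False)
        sigma = L.covariance()
        assert np.linalg.norm(emp - sigma, 2) / np.linalg.norm(sigma, 2) < 0.05


class TestPredictToEnsemble:
    def test_tiny_marginals_stay_at_input(self):
        chain = make_chain(10, seed=1)
        m = MarginalSet(covs=np.repeat(1e-6 * np.eye(3)[None], 10, axis=0))
        ct = CorrelationMatrix(values=np.eye(10))
        ens = predict_to_ensemble(chain, m, ct, T=20, seed=0)
        rmsd = np.sqrt(np.mean(np.sum(
            (ens.coords - chain.ca_coords) ** 2, axis=-1), axis=1))
        assert rmsd.max() < 0.01

    def test_default_t_is_250(self):
        chain = make_chain(6, seed=2)
        m = MarginalSet(covs=np.repeat(np.eye(3)[None], 6, axis=0))
        ct = CorrelationMatrix(values=np.eye(6))
        ens = predict_to_ensemble(chain, m, ct, seed=0)
        assert ens.n_frames == 250

    def test_identity_marginals_rmsf_sqrt3(self):
        chain = make_chain(8, seed=3)
        m = MarginalSet(covs=np.repeat(np.eye(3)[None], 8, axis=0))
        ct = CorrelationMatrix(values=np.eye(8))
        ens = predict_to_ensemble(chain, m, ct, T=30_000, seed=0)
        mean = ens.coords.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((ens.coords - mean) ** 2, axis=-1), axis=0))
        assert np.allclose(rmsf, np.sqrt(3.0), rtol=0.03)


class TestInFamilyRoundTrip:
    def test_extract_then_reconstruct_is_exact(self, ground_truth30):
        marginals, ctilde, joint = ground_truth30
        jg = JointGaussian(mean=joint.mean, cov=joint.cov)
        m2 = marginals_from_joint(jg)
        ct2 = correlation_standardize(coupling_from_joint(jg))
        rec = reconstruct_joint(m2, ct2)
        assert np.abs(rec - joint.cov).max() < 1e-10

    def test_end_to_end_sampling_round_trip(self, chain30, ground_truth30):
        """Sample from ground truth, re-extract labels, compare."""
        from gaussdyn import EnsembleGaussianModel, rmsf_from_marginals

        marginals, ctilde, joint = ground_truth30
        L = joint_factor(marginals, ctilde)
        ens = sample_conformations(joint.mean, L, T=20_000, seed=17)
        labels = EnsembleGaussianModel(ens, chain30).fit()
        true_rmsf = rmsf_from_marginals(marginals)
        assert np.abs(labels.rmsf - true_rmsf).max() / true_rmsf.mean() < 0.05
        assert np.abs(
            labels.correlation.values - ctilde.values
        ).max() < 0.05
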