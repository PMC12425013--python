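"""Gaussian label extraction: superposition, joint, marginals, coupling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaussdyn import (
    CouplingMatrix,
    Ensemble,
    EnsembleGaussianModel,
    JointGaussian,
    align_ensemble,
    correlation_standardize,
    coupling_from_joint,
    empirical_joint,
    kabsch_superpose,
    marginals_from_joint,
    rmsf_from_marginals,
)
from tests.conftest import random_spd


def _random_cloud(rng, n=10):
    return rng.standard_normal((n, 3)) * 3.0


class TestKabsch:
    def test_exact_rigid_copy_has_zero_rmsd(self, rng):
        ref = _random_cloud(rng)
        Q = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ Q.T + np.array([1.0, 2.0, 3.0])
        R, t, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_mirror_image_keeps_proper_rotation(self, rng):
        ref = np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.3, 0.4, 1.5],
        ])  # chiral
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        R, t, rmsd = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1

    def test_matches_scipy_align_vectors_oracle(self, rng):
        """Independent oracle: scipy's Kabsch implementation."""
        for _ in range(10):
            ref = _random_cloud(rng)
            mobile = _random_cloud(rng)
            R, t, rmsd = kabsch_superpose(mobile, ref)
            rot, rssd = Rotation.align_vectors(
                ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
            )
            assert np.allclose(R, rot.as_matrix(), atol=1e-6)
            assert rmsd == pytest.approx(rssd / np.sqrt(len(ref)), abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestAlignEnsemble:
    def test_rigid_copies_align_exactly(self, rng, chain30):
        ref = chain30.ca_coords
        frames = []
        for _ in range(5):
            Q = Rotation.random(rng=rng).as_matrix()
            frames.append(ref @ Q.T + rng.standard_normal(3) * 10)
        aligned = align_ensemble(Ensemble(coords=np.array(frames)), chain30)
        assert aligned.aligned
        assert np.abs(aligned.coords - ref).max() < 1e-6

    def test_idempotence(self, rng, chain30):
        noisy = chain30.ca_coords + 0.2 * rng.standard_normal((4, 30, 3))
        once = align_ensemble(Ensemble(coords=noisy), chain30)
        twice = align_ensemble(once, chain30)
        assert np.abs(once.coords - twice.coords).max() < 1e-8

    def test_rmsd_never_increases(self, rng, chain30):
        ref = chain30.ca_coords
        raw = ref + rng.standard_normal((6, 30, 3))
        aligned = align_ensemble(Ensemble(coords=raw), chain30)
        for t in range(6):
            before = np.sqrt(np.mean(np.sum((raw[t] - ref) ** 2, axis=1)))
            after = np.sqrt(np.mean(np.sum((aligned.coords[t] - ref) ** 2, axis=1)))
            assert after <= before + 1e-10

    def test_size_mismatch(self, chain30):
        with pytest.raises(ValueError):
            align_ensemble(Ensemble(coords=np.zeros((2, 4, 3))), chain30)


class TestEmpiricalJoint:
    def test_identical_frames_give_zero_covariance(self, chain30):
        coords = np.repeat(chain30.ca_coords[None], 3, axis=0)
        joint = empirical_joint(Ensemble(coords=coords, aligned=True))
        assert np.allclose(joint.cov, 0.0)
        assert np.allclose(joint.mean, chain30.ca_coords.ravel())

    def test_single_residue_hand_computation(self):
        # impossible to build via Structure (N >= 2), so use raw arrays:
        # two frames of a 2-residue chain, second residue static
        coords = np.array([
            [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]],
            [[2.0, 0.0, 0.0], [5.0, 0.0, 0.0]],
        ])
        joint = empirical_joint(Ensemble(coords=coords, aligned=True))
        assert np.allclose(joint.mean[:3], [1.0, 0.0, 0.0])
        # unbiased T-1 denominator: var = ((0-1)^2 + (2-1)^2) / 1 = 2
        assert joint.cov[0, 0] == pytest.approx(2.0)
        cov_rest = joint.cov.copy()
        cov_rest[0, 0] = 0.0
        assert np.allclose(cov_rest, 0.0)

    def test_monte_carlo_consistency(self, rng):
        d = 6  # two residues
        true_cov = random_spd(rng, d=d)
        mu = rng.standard_normal(d)
        x = rng.multivariate_normal(mu, true_cov, size=100_000)
        ens = Ensemble(coords=x.reshape(-1, 2, 3), aligned=True)
        joint = empirical_joint(ens)
        err = np.linalg.norm(joint.cov - true_cov, 2) / np.linalg.norm(true_cov, 2)
        assert err < 0.05

    def test_requires_aligned_and_two_frames(self, chain30):
        ens = Ensemble(coords=np.repeat(chain30.ca_coords[None], 2, axis=0))
        with pytest.raises(ValueError, match="aligned"):
            empirical_joint(ens)
        one = Ensemble(coords=chain30.ca_coords[None], aligned=True)
        with pytest.raises(ValueError, match="at least 2"):
            empirical_joint(one)


class TestMarginalsAndCoupling:
    def test_identity_joint_gives_identity_marginals(self):
        joint = JointGaussian(mean=np.zeros(6), cov=np.eye(6))
        m = marginals_from_joint(joint)
        assert np.allclose(m.covs, np.eye(3))

    def test_block_diagonal_blocks_recovered(self, rng):
        blocks = [random_spd(rng) for _ in range(3)]
        from scipy.linalg import block_diag

        joint = JointGaussian(mean=np.zeros(9), cov=block_diag(*blocks))
        m = marginals_from_joint(joint)
        for i in range(3):
            assert np.allclose(m.covs[i], blocks[i])

    def test_marginals_match_monte_carlo_marginalization(self, rng):
        """Numerical-marginalization oracle on an N=2 joint."""
        cov = random_spd(rng, d=6)
        joint = JointGaussian(mean=np.zeros(6), cov=cov)
        m = marginals_from_joint(joint)
        x = rng.multivariate_normal(np.zeros(6), cov, size=200_000)
        for i in range(2):
            emp = np.cov(x[:, 3 * i:3 * i + 3], rowvar=False)
            assert np.linalg.norm(emp - m.covs[i], 2) < 0.05 * np.linalg.norm(
                m.covs[i], 2
            )

    def test_constant_block_mean_pooling(self):
        cov = np.full((6, 6), 2.0) + 4.0 * np.eye(6)
        joint = JointGaussian(mean=np.zeros(6), cov=cov)
        C = coupling_from_joint(joint)
        # off-diagonal block is all twos -> mean 2
        assert C.values[0, 1] == pytest.approx(2.0)

    def test_identity_block_gives_one_third(self):
        joint = JointGaussian(mean=np.zeros(6), cov=np.eye(6))
        C = coupling_from_joint(joint)
        assert C.values[0, 0] == pytest.approx(1.0 / 3.0)

    def test_matches_naive_double_loop(self, rng):
        n = 5
        cov = random_spd(rng, d=3 * n)
        joint = JointGaussian(mean=np.zeros(3 * n), cov=cov)
        C = coupling_from_joint(joint)
        for i in range(n):
            for j in range(n):
                block = cov[3 * i:3 * i + 3, 3 * j:3 * j + 3]
                assert C.values[i, j] == pytest.approx(block.mean(), abs=1e-12)

    def test_trace3_pooling_switch(self, rng):
        cov = random_spd(rng, d=6)
        joint = JointGaussian(mean=np.zeros(6), cov=cov)
        C = coupling_from_joint(joint, pool="trace3")
        assert C.values[0, 0] == pytest.approx(np.trace(cov[:3, :3]) / 3.0)


class TestRmsfAndCorrelation:
    @pytest.mark.parametrize(
        "sigma,expected",
        [
            (np.eye(3), np.sqrt(3.0)),
            (np.diag([1.0, 4.0, 9.0]), np.sqrt(14.0)),
            (np.zeros((3, 3)), 0.0),
        ],
    )
    def test_rmsf_closed_forms(self, sigma, expected):
        from gaussdyn import MarginalSet

        rmsf = rmsf_from_marginals(MarginalSet(covs=sigma[None]))
        assert rmsf[0] == pytest.approx(expected, abs=1e-12)

    def test_unit_diagonal_input_unchanged(self, rng, correlation_factory):
        Ct = correlation_factory(rng, 5)
        C = CouplingMatrix(values=4.0 * Ct)  # sigma^2 * correlation
        out = correlation_standardize(C)
        assert np.allclose(out.values, Ct, atol=1e-12)

    def test_two_by_two_hand_example(self):
        C = CouplingMatrix(values=np.array([[4.0, 2.0], [2.0, 1.0]]))
        out = correlation_standardize(C)
        assert np.allclose(out.values, 1.0)

    def test_cauchy_schwarz_makes_clipping_noop(self, rng):
        for _ in range(20):
            C = CouplingMatrix(values=random_spd(rng, d=6))
            vals = C.values
            s = np.sqrt(np.diag(vals))
            raw = vals / np.outer(s, s)
            assert np.max(np.abs(raw)) <= 1.0 + 1e-10
            out = correlation_standardize(C)
            assert np.allclose(out.values, 0.5 * (raw + raw.T), atol=1e-10)

    def test_nonpositive_diagonal_errors(self):
        with pytest.raises(ValueError, match="positive"):
            correlation_standardize(
                CouplingMatrix(values=np.array([[0.0, 0.0], [0.0, 1.0]]))
            )


class TestEnsembleGaussianModel:
    def test_rmsf_matches_direct_coordinate_computation(self, rng, chain30):
        coords = chain30.ca_coords + 0.5 * rng.standard_normal((400, 30, 3))
        ens = Ensemble(coords=coords, aligned=True)  # skip alignment on purpose
        labels = EnsembleGaussianModel(ens, chain30).fit()
        mean = coords.mean(axis=0)
        direct = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=-1), axis=0))
        # T vs T-1 denominators differ by sqrt(T/(T-1)) ~ 0.1%
        assert np.allclose(labels.rmsf, direct, rtol=5e-3)

    def test_summary_mentions_size(self, rng, chain30):
        coords = chain30.ca_coords + 0.2 * rng.standard_normal((10, 30, 3))
        labels = EnsembleGaussianModel(Ensemble(coords=coords), chain30).fit()
        assert "30" in labels.summary()
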