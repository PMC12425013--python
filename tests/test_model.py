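"""Dynamics predictor: symmetry suite, SPD guarantees, training behavior."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaussdyn import (
    GaussianDynamicsModel,
    ModelConfig,
    Structure,
    frames_from_backbone,
    make_chain,
    rmsf_from_marginals,
)
from gaussdyn.model import DynamicsNetwork, DynamicsResults
from gaussdyn.autodiff import Tensor
from gaussdyn.nn import encode_sequence


def _tiny_config(**kw):
    base = dict(hidden_dim=16, num_ipa_blocks=1, num_pair_blocks=1,
                pair_dim=16, n_heads=2, epochs=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def _rigid_copy(s, Q, b):
    return Structure(
        sequence=s.sequence,
        ca_coords=s.ca_coords @ Q.T + b,
        n_coords=s.n_coords @ Q.T + b,
        c_coords=s.c_coords @ Q.T + b,
    )


@pytest.fixture(scope="module")
def chain():
    return make_chain(18, seed=5)


@pytest.fixture(scope="module")
def network(chain):
    return DynamicsNetwork(_tiny_config(head="both"))


class TestEmbedding:
    def test_deterministic(self, network, chain):
        a = network.embed_sequence(chain.sequence).data
        b = network.embed_sequence(chain.sequence).data
        assert np.array_equal(a, b)

    def test_single_position_change_is_local_before_mixing(self):
        # the residue-type one-hot differs in exactly one row
        a = encode_sequence("ACDEF")
        b = encode_sequence("ACDEG")
        diff_rows = np.nonzero(np.any(a != b, axis=1))[0]
        assert list(diff_rows) == [4]

    def test_shape_contract(self, network, chain):
        h = network.embed_sequence(chain.sequence)
        assert h.shape == (chain.n_residues, 16)

    def test_unknown_letter_warns_and_maps_to_unknown(self):
        with pytest.warns(UserWarning, match="unrecognized"):
            oh = encode_sequence("AB")
        assert oh[1, -1] == 1.0


class TestSymmetrySuite:
    def test_h_invariant_under_rigid_motion(self, network, chain, rng):
        Q = Rotation.random(rng=rng).as_matrix()
        b = rng.standard_normal(3) * 10
        _, h0 = network.forward(chain)
        _, h1 = network.forward(_rigid_copy(chain, Q, b))
        assert np.abs(h0.data - h1.data).max() < 1e-5

    def test_marginals_equivariant_coupling_and_rmsf_invariant(self, network, chain, rng):
        Q = Rotation.random(rng=rng).as_matrix()
        b = rng.standard_normal(3) * 5
        out0, _ = network.forward(chain)
        out1, _ = network.forward(_rigid_copy(chain, Q, b))
        s0, s1 = out0["marginals"].data, out1["marginals"].data
        assert np.abs(np.einsum("ab,ibc,dc->iad", Q, s0, Q) - s1).max() < 1e-5
        assert np.abs(out0["coupling"].data - out1["coupling"].data).max() < 1e-5
        r0 = np.sqrt(np.trace(s0, axis1=-2, axis2=-1))
        r1 = np.sqrt(np.trace(s1, axis1=-2, axis2=-1))
        assert np.abs(r0 - r1).max() < 1e-6

    def test_geometry_sensitivity(self, network, chain):
        other = make_chain(18, seed=99)
        same_seq = Structure(
            sequence=chain.sequence,
            ca_coords=other.ca_coords,
            n_coords=other.n_coords,
            c_coords=other.c_coords,
        )
        _, h0 = network.forward(chain)
        _, h1 = network.forward(same_seq)
        assert np.abs(h0.data - h1.data).max() > 1e-3

    def test_positional_features_break_permutation_equivariance(self, chain):
        """With positional features on (the configured default), relabeling
        residues changes h: position along the chain is a real feature."""
        net = DynamicsNetwork(_tiny_config(head="marginal", use_positional=True,
                                           use_density=False))
        frames = frames_from_backbone(chain)
        h = net.ipa_encode(net.embed_sequence(chain.sequence), frames)
        perm = np.arange(chain.n_residues)[::-1].copy()
        permuted = Structure(
            sequence="".join(chain.sequence[i] for i in perm),
            ca_coords=chain.ca_coords[perm],
            n_coords=chain.n_coords[perm],
            c_coords=chain.c_coords[perm],
        )
        frames_p = frames_from_backbone(permuted)
        h_p = net.ipa_encode(net.embed_sequence(permuted.sequence), frames_p)
        assert np.abs(h_p.data - h.data[perm]).max() > 1e-3


class TestSPDByConstruction:
    def test_random_weight_networks_emit_spd(self, chain):
        for seed in range(25):
            net = DynamicsNetwork(_tiny_config(head="both", seed=seed))
            out, _ = net.forward(chain)
            s = 0.5 * (out["marginals"].data + out["marginals"].data.transpose(0, 2, 1))
            assert np.linalg.eigvalsh(s).min() > 0
            c = 0.5 * (out["coupling"].data + out["coupling"].data.T)
            assert np.linalg.eigvalsh(c).min() > 0

    def test_pairwise_white_box_composition(self, chain):
        """C equals L L^T with L assembled from the raw z outputs."""
        net = DynamicsNetwork(_tiny_config(head="pairwise"))
        frames = frames_from_backbone(chain)
        h = net.ipa_encode(
            net.embed_sequence(chain.sequence, ca_coords=chain.ca_coords), frames
        )
        C = net.pairwise_head(h).data
        # recompute z through the same readout path
        from gaussdyn.autodiff import concatenate

        n = chain.n_residues
        D = net.config.hidden_dim
        zero = Tensor(np.zeros((n, n, D)))
        f = net.pair_proj(concatenate([h.reshape(n, 1, D) + zero,
                                       h.reshape(1, n, D) + zero], axis=-1))
        for blk in net.pair_blocks:
            f = blk(f)
        z = net.z_mlp(f).data.reshape(n, n)
        from gaussdyn.model import DIAG_EPS

        softplus_diag = (np.log1p(np.exp(-np.abs(np.diag(z))))
                         + np.maximum(np.diag(z), 0.0)) + DIAG_EPS
        L = np.tril(z, k=-1) + np.diag(softplus_diag)
        assert np.allclose(C, L @ L.T, atol=1e-10)

    def test_gradient_finite_at_zero_raw_parameters(self):
        """Softplus smoothness: d(loss)/d(a) is finite at a = 0."""
        from gaussdyn.autodiff import spd_log
        from gaussdyn import spd as spd_mod

        a = Tensor(np.zeros((1, 6)), requires_grad=True)
        masks = np.zeros((6, 3, 3))
        for slot, (i, j) in enumerate([(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]):
            masks[slot, i, j] = 1.0
        L = None
        for slot in range(6):
            entry = a[:, slot]
            if slot in (0, 2, 5):
                entry = entry.softplus()
            term = entry.reshape(1, 1, 1) * Tensor(masks[slot])
            L = term if L is None else L + term
        sigma = L @ L.mT
        target = spd_mod.matrix_log(2.0 * np.eye(3))[None]
        d = spd_log(sigma) - Tensor(target)
        (d * d).sum().backward()
        assert np.all(np.isfinite(a.grad))


class TestTraining:
    @pytest.fixture(scope="class")
    def small_dataset(self):
        from gaussdyn import SyntheticSpec
        from gaussdyn.synthetic import generate_protein

        spec = SyntheticSpec(n_proteins=6, length_range=(12, 16),
                             ensemble_size=200, seed=8, n_test=2)
        items = [generate_protein(spec, 1000 + k) for k in range(6)]
        return [(it["structure"],
                 {"marginals": it["labels"].marginals,
                  "coupling": it["labels"].coupling}) for it in items]

    def test_loss_decreases(self, small_dataset):
        cfg = _tiny_config(head="marginal", epochs=8)
        res = GaussianDynamicsModel(small_dataset[:4], config=cfg).fit()
        assert res.train_loss[-1] < res.train_loss[0]

    def test_same_seed_reproduces_loss_curve(self, small_dataset):
        cfg = _tiny_config(head="marginal", epochs=3)
        r1 = GaussianDynamicsModel(small_dataset[:3], config=cfg).fit()
        r2 = GaussianDynamicsModel(small_dataset[:3], config=cfg).fit()
        assert np.array_equal(r1.train_loss, r2.train_loss)

    def test_validation_checkpoint_and_history(self, small_dataset):
        cfg = _tiny_config(head="marginal", epochs=5)
        res = GaussianDynamicsModel(small_dataset[:4], val_data=small_dataset[4:],
                                    config=cfg).fit()
        assert np.all(np.isfinite(res.val_loss))
        assert res.best_val_loss == pytest.approx(np.nanmin(res.val_loss))

    def test_memorization_on_train_item(self, small_dataset):
        """After convergence on a tiny set, a training structure's loss sits
        below the first epoch's mean."""
        cfg = _tiny_config(head="marginal", epochs=20)
        gm = GaussianDynamicsModel(small_dataset[:2], config=cfg)
        res = gm.fit()
        items = gm._prepare(small_dataset[:2])
        final = float(gm._item_loss(res.network, items[0]).data)
        assert final < res.train_loss[0]

    def test_predict_outputs_feed_rmsf(self, small_dataset):
        cfg = _tiny_config(head="both", epochs=1)
        res = GaussianDynamicsModel(small_dataset[:2], config=cfg).fit()
        pred = res.predict(small_dataset[2][0])
        rmsf = rmsf_from_marginals(pred.marginals)
        assert rmsf.shape == (small_dataset[2][0].n_residues,)
        assert np.array_equal(pred.rmsf, rmsf)

    def test_save_load_round_trip(self, small_dataset, tmp_path):
        cfg = _tiny_config(head="marginal", epochs=2)
        res = GaussianDynamicsModel(small_dataset[:2], config=cfg).fit()
        path = tmp_path / "ckpt.npz"
        res.save(path)
        back = DynamicsResults.load(path)
        s = small_dataset[2][0]
        assert np.allclose(back.predict(s).rmsf, res.predict(s).rmsf, atol=1e-12)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            GaussianDynamicsModel([], config=_tiny_config())

    def test_residue_cap_enforced(self, small_dataset):
        cfg = _tiny_config(max_residues=4)
        with pytest.raises(ValueError, match="cap"):
            GaussianDynamicsModel(small_dataset[:1], config=cfg)

    def test_summary_reports_parameters_and_seed(self, small_dataset):
        cfg = _tiny_config(head="marginal", epochs=1, seed=3)
        res = GaussianDynamicsModel(small_dataset[:2], config=cfg).fit()
        text = res.summary()
        assert "seed" in text and "3" in text
        assert f"{res.n_parameters():,}" in text


class TestConfigValidation:
    def test_rejects_bad_head(self):
        with pytest.raises(ValueError, match="head"):
            ModelConfig(head="banana")

    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=0)
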