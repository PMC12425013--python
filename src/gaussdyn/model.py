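"""The learnable dynamics predictor, statsmodels-style.

:class:`GaussianDynamicsModel` is constructed from a dataset of
``(Structure, labels)`` pairs; :meth:`~GaussianDynamicsModel.fit` trains the
network and returns a :class:`DynamicsResults` object carrying the learned
weights, the loss history, prediction, sampling and summary methods.

Architecture
------------
A per-residue sequence embedding and the residue frames feed a stack of
Invariant Point Attention blocks, producing SE(3)-invariant representations
``h``. Two readouts share this backbone:

* **marginal head** — an MLP maps each ``h_i`` to six unconstrained reals,
  assembled into a 3x3 Cholesky factor with a softplus diagonal;
  ``Sigma_local = L L^T`` is SPD by construction. The local-frame prediction
  is conjugated into global coordinates by the residue frame,
  ``Sigma_i = R_i Sigma_local R_i^T``, which makes predicted marginals
  rotation-equivariant while ``h`` stays invariant.
* **pairwise head** — pair features ``W_proj(h_i || h_j)`` pass through
  triangle-update blocks; a scalar readout fills the lower triangle of an
  N x N factor (softplus on the diagonal) and ``C = L L^T`` is the SPD
  coupling matrix.

Both heads are trained with the squared log-Frobenius discrepancy between
predicted and label covariances (mean over residues for the marginal head,
a single matrix term for the pairwise head).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import spd
from .autodiff import Tensor, concatenate, spd_log
from .labels import (
    CorrelationMatrix,
    CouplingMatrix,
    MarginalSet,
    correlation_standardize,
    rmsf_from_marginals,
)
from .nn import (
    Adam,
    DENSITY_RADII,
    IPABlock,
    Linear,
    MLP,
    Module,
    SequenceEmbedding,
    TriangleBlock,
    radial_density_features,
)
from .joint import predict_to_ensemble
from .structures import Ensemble, ResidueFrameSet, Structure, frames_from_backbone

__all__ = [
    "ModelConfig",
    "DynamicsPrediction",
    "DynamicsNetwork",
    "GaussianDynamicsModel",
    "DynamicsResults",
    "train_model",
    "predict_dynamics",
]

# scatter masks: slot k of the raw 6-vector lands at _TRIL_IDX[k] of L
_TRIL_IDX = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_DIAG_SLOTS = {0, 2, 5}

# floor added to every softplus diagonal: keeps predicted covariances
# bounded away from singular so their matrix logarithm stays defined
DIAG_EPS = 1e-4


@dataclass
class ModelConfig:
    """Hyperparameters of the dynamics predictor.

    Desk-scale defaults (hidden_dim 32, two IPA blocks) train in minutes on
    a single CPU; all sizes are free parameters.
    """

    hidden_dim: int = 32
    num_ipa_blocks: int = 2
    num_pair_blocks: int = 2
    pair_dim: int = 32
    n_heads: int = 4
    n_qk_points: int = 4
    n_v_points: int = 4
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 1
    seed: int = 0
    head: str = "marginal"  # 'marginal' | 'pairwise' | 'both'
    use_positional: bool = True
    use_density: bool = True  # radial packing features in the embedding
    weight_decay: float = 0.0
    embed_dropout: float = 0.5  # train-time dropout of identity channels
    coupling_pool: str = "mean9"
    max_residues: int = 512
    patience: int = 15  # early stopping on validation loss

    def __post_init__(self):
        for name in ("hidden_dim", "num_ipa_blocks", "num_pair_blocks",
                     "pair_dim", "n_heads", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.head not in ("marginal", "pairwise", "both"):
            raise ValueError("head must be 'marginal', 'pairwise' or 'both'")


@dataclass
class DynamicsPrediction:
    """Model outputs for one structure."""

    marginals: MarginalSet
    coupling: CouplingMatrix | None
    rmsf: np.ndarray


class DynamicsNetwork(Module):
    """Forward network: embedding -> IPA backbone -> readout heads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = config.hidden_dim
        self.embedding = SequenceEmbedding(
            D, rng, use_positional=config.use_positional,
            use_density=config.use_density,
        )
        self.ipa_blocks = [
            IPABlock(D, rng, n_heads=config.n_heads,
                     n_qk_points=config.n_qk_points, n_v_points=config.n_v_points)
            for _ in range(config.num_ipa_blocks)
        ]
        if config.head in ("marginal", "both"):
            # the readout sees the backbone output plus the raw packing
            # features: local burial is the dominant flexibility signal and
            # feeding it directly keeps the readout well-conditioned
            d_in = D + (len(DENSITY_RADII) if config.use_density else 0)
            self.marginal_mlp = MLP(d_in, 2 * D, 6, rng)
        if config.head in ("pairwise", "both"):
            dp = config.pair_dim
            self.pair_proj = Linear(2 * D, dp, rng)
            self.pair_blocks = [
                TriangleBlock(dp, rng, n_heads=config.n_heads)
                for _ in range(config.num_pair_blocks)
            ]
            self.z_mlp = MLP(dp, dp, 1, rng)

    # ----- backbone ----------------------------------------------------
    def embed_sequence(self, sequence: str, ca_coords=None,
                       dropout_rng=None) -> Tensor:
        p = self.config.embed_dropout if dropout_rng is not None else 0.0
        return self.embedding(sequence, ca_coords=ca_coords,
                              dropout_rng=dropout_rng, dropout=p)

    def ipa_encode(self, seq_repr: Tensor, frames: ResidueFrameSet) -> Tensor:
        n = frames.n_residues
        if seq_repr.shape[0] != n:
            raise ValueError("sequence representation and frames disagree on N")
        R = Tensor(frames.rotations)
        t = Tensor(frames.translations)
        h = seq_repr
        for block in self.ipa_blocks:
            h = block(h, R, t)
        return h

    # ----- heads -------------------------------------------------------
    def marginal_head(self, h: Tensor, frames: ResidueFrameSet) -> Tensor:
        """Predicted global-frame marginal covariances as a (N, 3, 3) Tensor."""
        n = h.shape[0]
        if self.config.use_density:
            g = radial_density_features(frames.translations)
            h = concatenate([h, Tensor(np.log1p(g))], axis=-1)
        raw = self.marginal_mlp(h)  # (N, 6)
        L = None
        for slot, (i, j) in enumerate(_TRIL_IDX):
            mask = np.zeros((3, 3))
            mask[i, j] = 1.0
            entry = raw[:, slot]
            if slot in _DIAG_SLOTS:
                entry = entry.softplus() + DIAG_EPS
            term = entry.reshape(n, 1, 1) * Tensor(mask)
            L = term if L is None else L + term
        sigma_local = L @ L.mT
        R = Tensor(frames.rotations)
        return R @ sigma_local @ R.mT

    def pairwise_head(self, h: Tensor) -> Tensor:
        """Predicted SPD coupling matrix as an (N, N) Tensor."""
        n = h.shape[0]
        D = self.config.hidden_dim
        zero = Tensor(np.zeros((n, n, D)))
        hi = h.reshape(n, 1, D) + zero
        hj = h.reshape(1, n, D) + zero
        f = self.pair_proj(concatenate([hi, hj], axis=-1))
        for block in self.pair_blocks:
            f = block(f)
        z = self.z_mlp(f).reshape(n, n)
        low = Tensor(np.tril(np.ones((n, n)), k=-1))
        eye = Tensor(np.eye(n))
        L = z * low + (z.softplus() + DIAG_EPS) * eye
        return L @ L.mT

    def forward(self, structure: Structure, frames: ResidueFrameSet | None = None,
                dropout_rng=None):
        if frames is None:
            frames = frames_from_backbone(structure)
        h = self.ipa_encode(
            self.embed_sequence(structure.sequence,
                                ca_coords=structure.ca_coords,
                                dropout_rng=dropout_rng),
            frames,
        )
        out = {}
        if self.config.head in ("marginal", "both"):
            out["marginals"] = self.marginal_head(h, frames)
        if self.config.head in ("pairwise", "both"):
            out["coupling"] = self.pairwise_head(h)
        return out, h


def _marginal_loss(pred: Tensor, log_target: np.ndarray) -> Tensor:
    # the same 1e-8 jitter applied to the (empirical) targets keeps the
    # matrix log defined when a prediction approaches singularity
    jit = Tensor(spd.DEFAULT_JITTER * np.eye(3))
    d = spd_log(pred + jit) - Tensor(log_target)
    return (d * d).sum(axis=(-1, -2)).mean()


def _pairwise_loss(pred: Tensor, log_target: np.ndarray) -> Tensor:
    n = pred.shape[-1]
    jit = Tensor(spd.DEFAULT_JITTER * np.eye(n))
    d = spd_log(pred + jit) - Tensor(log_target)
    # single N x N matrix term, normalized per entry so the gradient scale
    # does not grow with chain length
    return (d * d).sum() * (1.0 / n**2)


class GaussianDynamicsModel:
    """Dynamics predictor built from a labeled dataset.

    Parameters
    ----------
    train_data : list of (Structure, labels)
        ``labels`` is a mapping with a ``'marginals'`` :class:`MarginalSet`
        and/or a ``'coupling'`` :class:`CouplingMatrix`, per the configured
        head.
    val_data : list, optional
        Same format; used for early stopping and checkpoint selection.
    config : ModelConfig
    """

    def __init__(self, train_data, val_data=None, config: ModelConfig | None = None):
        if not train_data:
            raise ValueError("empty training dataset")
        self.config = config or ModelConfig()
        self.train_data = list(train_data)
        self.val_data = list(val_data) if val_data else []
        for s, _ in self.train_data + self.val_data:
            if s.n_residues > self.config.max_residues:
                raise ValueError(
                    f"structure with {s.n_residues} residues exceeds the "
                    f"configured cap of {self.config.max_residues} "
                    "(pairwise memory is O(N^2 d'))"
                )
        self._prepared = None

    def _prepare(self, data):
        """Precompute frames and matrix-log label targets per item."""
        items = []
        for structure, labels in data:
            item = {
                "structure": structure,
                "frames": frames_from_backbone(structure),
            }
            if self.config.head in ("marginal", "both"):
                m = labels["marginals"]
                item["log_marginals"] = spd.matrix_log(
                    spd.add_jitter(m.covs)
                )
            if self.config.head in ("pairwise", "both"):
                c = labels["coupling"]
                item["log_coupling"] = spd.matrix_log(spd.add_jitter(c.values))
            items.append(item)
        return items

    def _item_loss(self, network: DynamicsNetwork, item, dropout_rng=None) -> Tensor:
        out, _ = network.forward(item["structure"], item["frames"],
                                 dropout_rng=dropout_rng)
        loss = None
        if "marginals" in out:
            loss = _marginal_loss(out["marginals"], item["log_marginals"])
        if "coupling" in out:
            pl = _pairwise_loss(out["coupling"], item["log_coupling"])
            loss = pl if loss is None else loss + pl
        return loss

    def fit(self, verbose: bool = False) -> "DynamicsResults":
        cfg = self.config
        network = DynamicsNetwork(cfg)
        params = network.parameters()
        opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed + 1)
        train_items = self._prepare(self.train_data)
        val_items = self._prepare(self.val_data) if self.val_data else []

        history = []
        best_val = math.inf
        best_state = network.state()
        best_epoch = 0
        since_best = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_items))
            epoch_losses = []
            for idx in order:
                loss = self._item_loss(network, train_items[idx],
                                       dropout_rng=rng)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, item {idx}: "
                        f"{value}; try a smaller learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(value)
            train_loss = float(np.mean(epoch_losses))
            record = {"epoch": epoch, "train_loss": train_loss}
            if val_items:
                val_loss = float(np.mean(
                    [float(self._item_loss(network, it).data) for it in val_items]
                ))
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_state = network.state()
                    best_epoch = epoch
                    since_best = 0
                else:
                    since_best += 1
            else:
                best_state = network.state()
                best_epoch = epoch
            history.append(record)
            if verbose:
                msg = f"epoch {epoch:3d}  train {train_loss:.4f}"
                if "val_loss" in record:
                    msg += f"  val {record['val_loss']:.4f}"
                print(msg)
            if val_items and since_best >= cfg.patience:
                break
        network.load_state(best_state)
        return DynamicsResults(
            config=cfg,
            network=network,
            history=history,
            best_epoch=best_epoch,
            best_val_loss=best_val if val_items else None,
        )


@dataclass
class DynamicsResults:
    """Fitted predictor: weights, training history, prediction & sampling."""

    config: ModelConfig
    network: DynamicsNetwork
    history: list
    best_epoch: int = 0
    best_val_loss: float | None = None

    # ----- inference ---------------------------------------------------
    def predict(self, structure: Structure) -> DynamicsPrediction:
        out, _ = self.network.forward(structure)
        marginals = None
        coupling = None
        if "marginals" in out:
            marginals = MarginalSet(covs=spd.symmetrize(out["marginals"].data))
        if "coupling" in out:
            cv = out["coupling"].data
            coupling = CouplingMatrix(values=0.5 * (cv + cv.T))
        if marginals is None:
            # pairwise-only model: report isotropic marginals from the
            # coupling diagonal so RMSF is still defined
            diag = np.diag(coupling.values)
            marginals = MarginalSet(
                covs=np.einsum("i,ab->iab", diag, np.eye(3))
            )
        return DynamicsPrediction(
            marginals=marginals,
            coupling=coupling,
            rmsf=rmsf_from_marginals(marginals),
        )

    def predict_correlation(self, structure: Structure) -> CorrelationMatrix:
        pred = self.predict(structure)
        if pred.coupling is None:
            raise ValueError("model has no pairwise head")
        return correlation_standardize(pred.coupling)

    def sample_ensemble(
        self,
        structure: Structure,
        T: int = 250,
        seed: int = 0,
        repair: bool = False,
    ) -> Ensemble:
        """Sample an ensemble around ``structure`` from the predictions.

        Marginal-only models sample with an identity residue-residue
        correlation (independent Gaussian blobs).
        """
        pred = self.predict(structure)
        if pred.coupling is not None:
            ctilde = correlation_standardize(pred.coupling)
        else:
            ctilde = CorrelationMatrix(values=np.eye(structure.n_residues))
        return predict_to_ensemble(
            structure, pred.marginals, ctilde, T=T, seed=seed, repair=repair
        )

    # ----- reporting ---------------------------------------------------
    @property
    def train_loss(self) -> np.ndarray:
        return np.array([r["train_loss"] for r in self.history])

    @property
    def val_loss(self) -> np.ndarray:
        return np.array([r.get("val_loss", np.nan) for r in self.history])

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.network.parameters().values()))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Gaussian dynamics predictor",
            "=" * 44,
            f"head:                 {cfg.head}",
            f"hidden / pair dim:    {cfg.hidden_dim} / {cfg.pair_dim}",
            f"IPA / triangle blocks: {cfg.num_ipa_blocks} / {cfg.num_pair_blocks}",
            f"parameters:           {self.n_parameters():,}",
            f"epochs run:           {len(self.history)}",
            f"best epoch:           {self.best_epoch}",
            f"final train loss:     {self.train_loss[-1]:.4f}",
        ]
        if self.best_val_loss is not None:
            lines.append(f"best val loss:        {self.best_val_loss:.4f}")
        lines.append(f"seed:                 {cfg.seed}")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training/validation loss curves (matplotlib Axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.train_loss, label="train")
        if np.any(np.isfinite(self.val_loss)):
            ax.plot(self.val_loss, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("log-Frobenius loss")
        ax.legend()
        return ax

    # ----- persistence -------------------------------------------------
    def save(self, path) -> None:
        state = self.network.state()
        meta = {
            "config": asdict(self.config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **state,
        )

    @classmethod
    def load(cls, path) -> "DynamicsResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        network = DynamicsNetwork(cfg)
        network.load_state(state)
        return cls(
            config=cfg,
            network=network,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            best_val_loss=meta["best_val_loss"],
        )


def train_model(dataset, config: ModelConfig, val_data=None,
                verbose: bool = False) -> DynamicsResults:
    """Convenience wrapper: build a :class:`GaussianDynamicsModel` and fit."""
    return GaussianDynamicsModel(dataset, val_data=val_data, config=config).fit(
        verbose=verbose
    )


def predict_dynamics(structure: Structure, results: DynamicsResults) -> DynamicsPrediction:
    """Forward pass of a fitted model on one structure."""
    return results.predict(structure)
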