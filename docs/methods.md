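# Methods

## Gaussian view of backbone dynamics

All descriptors derive from modeling the RMSD-aligned Cα coordinates of a
conformational ensemble as a single multivariate Gaussian
`X ~ N(μ, Σ_joint)`, `X ∈ R^{3N}`. This captures second-order statistics
only: amplitudes, anisotropy and linear coupling of fluctuations around one
basin. Multi-basin kinetics, anharmonicity and time ordering are outside
the model class. Labels are extracted from an ensemble by superposing every
conformation independently onto a fixed reference (Kabsch, reflections
corrected), taking the sample mean and the **unbiased (T−1)** covariance of
the flattened coordinates, and projecting: 3×3 diagonal blocks
(`Σ_marginal(i)`), mean-pooled off-diagonal blocks (`C_ij`, arithmetic mean
of the nine block entries; a `trace3` switch is provided), `RMSF_i =
sqrt(Tr Σ_marginal(i))`, and the unit-diagonal standardization `C̃` of `C`
(clipped to [−1, 1]; the clip is a no-op for exactly SPD inputs by
Cauchy–Schwarz). Alignment is to the input reference structure, not the
iterative ensemble mean; the fixed-mean assumption (μ := input Cα) is
applied at prediction time only.

## SPD machinery

Covariances are kept on the SPD cone by construction, never by projection:

* 3×3 factors come from six unconstrained reals with a softplus diagonal
  (`softplus(x) = max(x,0) + log1p(e^{−|x|})`, no β parameter);
* the matrix logarithm uses symmetric eigendecomposition after
  symmetrizing `(M + Mᵀ)/2`, with an eigenvalue floor of 1e-12 below which
  it raises rather than silently regularizing;
* the training loss is the **squared** log-Frobenius norm; the metric
  (square-root) variant is exposed separately;
* the Bures–Wasserstein/2-Wasserstein distance is implemented as an
  evaluation metric only — log-Frobenius is the training objective
  throughout — with matrix square roots by eigendecomposition, adequate at
  the dimensions used here;
* empirical covariances receive +1e-8·I of jitter before any Cholesky or
  eigen step; Cholesky of a standardized coupling escalates jitter
  (0 → 1e-10 → 1e-6) before failing.

## Predictor

The network is implemented on a compact reverse-mode autodiff engine over
numpy (`gaussdyn.autodiff`): tape-based, float64, single-threaded,
deterministic, with one domain-specific primitive — the principal matrix
logarithm of batched SPD matrices, whose backward pass uses the
Daleckii–Krein (Loewner-matrix) closed form in the eigenbasis.

Inputs are the amino-acid sequence and per-residue rigid frames built by
Gram–Schmidt on (C−Cα, N−Cα) in the AlphaFold2 structure-module
convention; Cα-only inputs fall back to identity rotations with a warning,
which sacrifices rotation equivariance of the predicted marginals. The
embedding sums three terms: a residue-type linear embedding (strictly
per-residue), sinusoidal positional features (on by default — position
along the chain is physically meaningful, at the deliberate cost of
permutation equivariance), and a linear projection of **radial packing
features**, soft coordination numbers `Σ_j exp(−d_ij²/2r²)` at r = 5, 8,
11, 14 Å. Local packing density is the dominant structural determinant of
backbone flexibility, and providing it explicitly keeps the geometric
pathway well-conditioned at desk scale; the same features are concatenated
to the marginal readout input.

The backbone is a stack of Invariant Point Attention blocks without pair
bias (no pair representation enters the backbone). Attention logits combine
scalar query–key products with squared distances between frame-anchored 3D
points; point outputs are mapped back into each residue's local frame.
Two deliberate choices beyond the standard block:

* **Distance-weight initialization.** At initialization the attention
  points coincide with the Cα positions, so the point term contributes
  `−γ·const·d_ij²` to the logits. With γ ≈ 1 the softmax collapses onto
  self-attention and no geometric information flows. The per-head softplus
  weights are therefore initialized geometrically spread over 0.02–0.4, so
  heads start as soft neighborhood kernels with contact-scale radii.
* **Attention-mass channel.** Softmax normalization discards the *total*
  neighborhood weight, which is precisely a coordination number. Each
  head's log-sum-exp of its logits is appended to the block's output
  features.

Readouts: the marginal head predicts in the **local residue frame** and
conjugates out by `R_i` — the invariant features cannot encode global
orientation, so this is the only way predictions can co-rotate with the
structure while `h` stays invariant. The pairwise head projects
concatenated residue features to a pair representation (d′ = 32), applies
triangle-multiplicative updates (outgoing + incoming), pair-row attention
and a transition MLP (2 blocks by default), then fills the lower triangle
of an N×N factor with scalar readouts (softplus on the diagonal) and
composes `C = LLᵀ`. Pairwise memory is O(N²d′); a configurable cap
(default 512 residues) guards against accidental large inputs.

Training: Adam (lr 1e-3) with optional decoupled weight decay, batch size
1, loss averaged over residues for the marginal head and normalized per
entry for the pairwise head (applied to `C`, the labels' natural scale —
standardization to `C̃` happens downstream). Identity-like embedding
channels (residue type + position) are dropped out per residue with
probability 0.5 during training: on small corpora they are the easiest
memorization route, and removing them stochastically forces the geometric
pathway to carry the prediction. Early stopping on validation loss with
checkpoint restore; every source of randomness is seeded; the two heads
are trained as separate models sharing the same architecture up to the
readout.

## Joint reconstruction and sampling

`Σ_joint = L_marg (C̃ ⊗ I₃) L_margᵀ` with `L_marg = ⊕ L_i`. The result is
SPD for SPD inputs (congruence of an SPD matrix by a full-rank triangular
matrix) and preserves the marginals exactly because `C̃_ii = 1`. The
closed-form factor `L = L_marg (chol(C̃) ⊗ I₃)` is lower-triangular with
positive diagonal and avoids any dense 3N×3N factorization; sampling is
`x = μ + Lε`. Reconstruction is exact only for joints of this Kronecker
form whose blocks share a common shape up to scale (mean pooling then
standardizes back to the generating correlation); on general joints it is
an approximation and the package asserts only SPD-ness and marginal
preservation. A standardized *predicted* coupling can be numerically
indefinite after clipping; the default is a hard error, with an explicit
`repair` option (Higham alternating-projections nearest correlation) —
silent repair would mask model failure.

## Elastic-network baseline

Anisotropic network model with the conventional defaults (cutoff 15 Å,
spring constant γ = 1): off-diagonal blocks `−(γ/|r_ij|²) r_ij r_ijᵀ`
within the cutoff, diagonal blocks enforcing zero block-row sums. The
covariance is the pseudo-inverse over non-rigid modes, skipping exactly six
modes by count with a sanity check that the seventh eigenvalue exceeds
1e-6 of the maximum (a disconnected or near-degenerate contact network
fails loudly). No kBT/γ physical scale is applied; comparisons use
correlation-type metrics, with an optional least-squares scale fit for
absolute (RMWD-type) comparisons.

## Evaluation metrics

* RMSF Pearson correlation (undefined profiles reported as missing, never
  as zero).
* RMWD: root of the *mean* squared per-residue Gaussian 2-Wasserstein
  distance (mean inside the root); the variance-only flag drops the
  mean-difference term.
* Symmetric KL, variance contribution: zero-mean form
  `½[Tr(Q⁻¹P) + Tr(P⁻¹Q)] − 3` per residue, mirroring the variance-only
  RMWD treatment.
* Band-wise coupling correlation: Pearson r over upper-triangle entries
  with sequence separation ≤ k, cumulative in k (default k ≤ 50), main
  diagonal excluded; bands with fewer than three entries are missing.
* Ensemble metrics: within-ensemble mean pairwise Cα RMSD (per-pair
  superposition; pairs subsampled beyond 1000, seeded), RMSF correlation,
  2-Wasserstein distances between the two ensembles projected on the top-2
  principal components of the reference (or pooled) ensemble under a
  Gaussian approximation of the projected clouds, and Jaccard similarities
  of contact sets. Contacts are Cα–Cα < 8 Å with sequence separation ≥ 3;
  *weak* contacts have reference occupancy in (0.1, 0.9); *transient*
  contacts are absent in the input structure but occupied in >0.1 of
  reference frames. All thresholds are exposed as parameters.
* Cross-protein aggregation reports 25th/50th/75th percentiles with
  missing-value counts.

## Synthetic data: what it emulates and what it does not

The generator stands in for an MD-derived corpus. Chains are self-avoiding
Cα walks (bond length 3.8 Å, non-bonded floor 3.0 Å) with a centroid
attraction that makes them globular — like folded domains, and necessary
for a well-conditioned elastic network; synthetic N/C atoms at ideal local
geometry make frames well-defined. Sequences are uniform random over the
20 amino acids: sequence–structure consistency is irrelevant to the
geometric learning task at this scale, which also means the model can and
should learn to *ignore* sequence here — a real corpus would reward using
it.

Ground truth comes in two families. The **kronecker** family draws the
marginal trace from an absolute, smooth map of burial — trace =
`s_min + (s_max − s_min)·exp(−(b − b₀)/τ)` with b the soft coordination
number (Gaussian shell, r = 8 Å), b₀ = 5, τ = 4 — times a mild seeded
lognormal perturbation (σ = 0.08), with default trace range 0.25–2.25 Å²
(RMSF ≈ 0.5–1.5 Å, typical of folded backbones). Anisotropy is one
randomly oriented shape matrix per protein (eigenvalue fractions
0.45/0.33/0.22) scaled per residue. Two consequences are deliberate:
sharing the shape within a protein keeps the family isotropy-compatible,
so label extraction followed by reconstruction reproduces the joint
*exactly*; and because a globally fixed orientation is invisible to
SE(3)-invariant features, moderate anisotropy keeps the unlearnable
orientation component of the loss from swamping the learnable amplitude
signal. The residue–residue correlation is `C̃_ij = exp(−|i−j|/5)`
(positive definite by construction, mimicking coupling that decays quickly
with sequence distance). The **anm** family uses the elastic-network
covariance of the chain instead — structure-determined but outside the
Kronecker family, exercising the approximate regime.

Ensembles of T = 1000 conformations are sampled from each ground-truth
joint; labels are stored both *clean* (from the generator) and *empirical*
(re-extracted from the sampled ensemble, carrying realistic sampling
noise). Training uses the empirical labels. Datasets are written as
(structure PDB, multi-model ensemble PDB, HDF5 labels) triples with a
deterministic manifest; re-running a spec is byte-identical.

What passing tests on this family shows: the architecture can recover a
structure-determined flexibility field and coupling structure from 20
chains, the reconstruction/sampling algebra is exact where exactness is
claimed, and the pipeline is reproducible. What it does not show: accuracy
on real MD-derived labels, where flexibility depends on side-chain packing
and chemistry, anisotropy orientation is locally structured, and coupling
has long-range components.

## Problem sizes and defaults

Desk-scale defaults were chosen so the full test suite and the acceptance
script run in minutes on a single CPU: chains of 20–40 residues, 25
proteins (20 train / 5 test), T = 1000 frames, hidden dim 32, two IPA
blocks, two triangle blocks (d′ = 32, 4 heads), 60 epochs for the marginal
head and 25 for the pairwise head, ~35k parameters per model. All sizes
are configuration fields; nothing in the architecture is specific to these
values.

## Known limitations

* A single Gaussian basin: no kinetics, no multimodality.
* Predicted marginal *orientations* cannot exceed what invariant features
  plus local frames can express; on the synthetic family orientation is
  deliberately near-unidentifiable and only amplitudes are scored.
* The pairwise head is O(N²)–O(N³) in time/memory; the default residue cap
  is 512.
* Sampled conformations are raw Cα Gaussians: bond lengths and
  stereochemistry are not enforced.
* Single chains only; mmCIF and trajectory formats are out of scope.
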