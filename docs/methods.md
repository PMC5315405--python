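# Methods

## Model

The object of study is the *mechanical coupling network* of a protein
inferred from an ensemble of conformers — crystal structures of different
functional states, NMR models, or MD snapshots — reduced to their Cα trace.

**Distance fluctuations.** For residues a, b the fluctuation
f_ab = √(⟨d_ab²⟩ − ⟨d_ab⟩²) is the population standard deviation (divisor
M, not M−1: the definition is a second central moment over the observed
set, not an estimator of a larger population) of the Cα–Cα distance over
the M members. Pairwise distances are invariant under global rigid-body
motion, so no superposition step is needed and none is performed.
Numerically the variance is computed in two-pass form,
mean((d − ⟨d⟩)²), which is algebraically identical to the moment form but
avoids the catastrophic cancellation that limits ⟨d²⟩ − ⟨d⟩² to ~1e−7 Å
at typical coordinate magnitudes.

**Coupling network.** σ_ab = exp(−f_ab²/2f̄²) for pairs with mean distance
strictly below the cutoff (default 12 Å — the scale of second-shell Cα
contacts), zero otherwise and on the diagonal. The sensitivity f̄ is the
mean of f_ab over unordered within-cutoff pairs, bonded pairs included:
the natural graph reading of "all local pairs", and the inclusion of
bonded pairs only shifts f̄ slightly since they are a small minority.
A numerically rigid ensemble (f̄ < 1e−9 Å, i.e. pure coordinate round-off)
takes the continuous f → 0 limit, σ = 1 within the cutoff.

**Bridging score.** The symmetric normalized Laplacian
L = I − D^{−1/2} σ D^{−1/2} has eigenvalues in [0, 2] with one zero per
connected component. Softness Ω = Σ 1/λᵢ over non-zero eigenvalues; the
score Δ_k = Ω_k − Ω₀ where Ω_k is the softness after zeroing all
*non-bonded* couplings of node k. The node and its chain bonds stay in the
matrix, so every Ω_k is a sum over the same number of modes and the
differences are comparable. Because L is invariant under uniform rescaling
of σ (the degree normalization cancels the scale), so is every Δ_k — a
property asserted in the tests to 1e−10.

Residues whose only couplings are chain bonds have Δ_k = 0 exactly and are
skipped without an eigendecomposition.

## Numerical choices

- Eigendecompositions are full and dense (`scipy.linalg.eigvalsh`);
  at the intended problem sizes (N ≲ 500) a profile costs N + 1
  decompositions, i.e. seconds.
- An eigenvalue counts as zero iff λ < 1e−9 · max(λ_max, 1). Tests check
  that the resulting zero count equals the number of connected components
  obtained by graph traversal. Eigenvalues in (−tol, 0) are clipped to 0;
  anything below −tol raises.
- Isolated (degree-0) nodes get a zero diagonal entry in L, making them
  exact single-node components rather than spurious λ = 1 modes.
- A deletion that disconnects the network is scored with all zero modes
  omitted (the same tilde rule as Ω₀) and flagged; `mask_disconnecting`
  replaces flagged scores with NaN for workflows that exclude
  disconnection-prone positions from the comparable set instead.
- Ranking ties break by residue order (stable sort), for reproducibility.

## Cross-receptor aggregation

Profiles from different receptors are compared through generic "AxBB"
position labels (helix number + index, most conserved position = 50).
Aggregation keeps only positions present in every contributing profile,
optionally restricted to the packaged transmembrane whitelist
(`data/tm_ranges.txt`, note TM7's deliberate gap at 7x44), and averages
with equal receptor weight; the error bar is the population standard
deviation across receptors. Within one receptor, error bars come from
recomputing the profile on every (active, inactive) structure pair and
taking the per-residue population standard deviation across pair profiles.
Partially active structures are excluded from pairing by default (their
assignment is genuinely ambiguous); a flag groups them with the active set.

The static baseline is the coordination number: neighbours within the same
12 Å mean-distance cutoff, self excluded, bonded included — one consistent
geometric criterion for both the network and the baseline. ROC curves
against a key-site list use the rank-average tie convention, so the AUC
equals the Mann–Whitney U estimate; the curve always carries (0,0) and
(1,1) endpoints.

## Domain decomposition

`partition_domains` embeds residues in the k lowest eigenvectors of the
normalized Laplacian (rows renormalized to unit length) and clusters with
seeded k-medoids (Voronoi iteration, best of `restarts` initialisations by
within-cluster cost; no installed package provides k-medoids, so it is
implemented here). Medoids keep representative residues interpretable.
Quality is the mean silhouette in the embedding. This is a deliberately
simple spectral decomposition in the spirit of quasi-rigid domain servers,
not a reimplementation of any specific one (which typically add
nearest-neighbour sparsification and bespoke quality scores); conclusions
drawn from it are qualitative — which domains exist, which residues they
claim. `membership_fraction` quantifies, across partitions at k = 2…k_max,
how often a query residue shares a domain with the majority of an anchor
set — the signature of an interface residue is a fraction strictly between
0 and 1.

## Synthetic generator

The generator emulates the geometry the method targets: quasi-rigid bodies
articulating through hinge residues, observed with positional noise.

- **Chains** are self-avoiding walks with the canonical 3.8 Å virtual
  Cα–Cα bond. Each body is grown as a compact globule around its own
  target center (radius from a ~110 Å³ per-residue packing volume, centers
  of consecutive bodies at tangency), because compactness — many internal
  contacts — is what makes a body mechanically rigid as a network; an
  extended walk would make every mid-chain residue a bridge. Candidates
  are grown with a 3.5 Å minimum non-bonded separation so that hinge
  rotations and noise rarely push pairs below the 3.0 Å clash limit;
  clashing conformers are rejection-sampled with bounded retries.
- **Hinges** are directional joints: each joint has one fixed rotation
  axis through its pivot Cα, drawn perpendicular to the body-separation
  direction (a door-like hinge, not a swivel about the connecting line)
  and re-drawn until the largest planned deflection is clash-free. Members
  rotate each downstream body by an independent angle (uniform within
  ±max_angle, default 25°) about that axis, then add isotropic Gaussian
  noise (default 0.2 Å) and a random global rigid transform. A fixed axis
  matters twice: it is what "hinge" means mechanically, and it keeps the
  deformation one-dimensional so pair profiles are mutually consistent.
- **Two-state ensembles** sample hinge angles around 0 (inactive) and
  around a state offset (active, default test value 30°) with a small
  within-state spread (5°): structures of one functional state cluster
  tightly compared with the activation motion itself.
- Within a body, the distance fluctuation from isotropic noise of sd s is
  ≈ √2·s (each endpoint contributes s² of variance along the line of
  sight), giving an analytic sanity band used in the tests.

What the generator does **not** emulate: secondary structure, realistic
backbone dihedrals, side chains, membrane context, anisotropic B-factor
structure, or correlated noise. Passing tests therefore demonstrate that
the pipeline recovers planted rigid-body/hinge organisation under
isotropic noise — not that any particular real receptor's hotspots are
correct; those claims require the corresponding structural datasets.

## Problem sizes

The test suite and the acceptance script run on 60-residue two-body
fixtures (20 members), 20 seeds for recovery rates, 10 for pair
consistency, and 200 random networks (N ≤ 50) for the oracle-equivalence
check — sizes at which the full pipeline including N + 1 dense
eigendecompositions per profile completes in seconds while leaving the
planted signal clearly above noise.

## Known limitations

- Residue correspondence within a receptor trusts author numbering plus
  residue identity; no sequence alignment is attempted. Cross-receptor
  correspondence requires a generic-numbering map — none is inferred.
- The two-structure limit (one active–inactive pair) makes f a two-point
  standard deviation; profiles remain well correlated with many-member
  ones but individual magnitudes are noisy, which is exactly what the
  pair-based error bars measure.
- Scores of disconnection-flagged residues mix component contributions and
  should be read with the flag in hand.
- The coordination baseline's contact definition (mean Cα–Cα < 12 Å) is
  one of several reasonable conventions; absolute count ranges depend
  on it.
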