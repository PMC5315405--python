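# mechbridge

Locating the residues that hold a protein's large-scale mechanics together,
from an ensemble of conformers.

Proteins such as G protein-coupled receptors (GPCRs) switch between active
and inactive conformations through concerted motions of quasi-rigid domains.
The residues that *bridge* those domains — hinges and interfaces — control
how structural perturbations propagate, yet they are hard to spot from any
single static structure. `mechbridge` implements an ensemble-based,
dynamics-aware profiling of such sites:

1. **Distance fluctuations.** For every residue pair (a, b), the
   fluctuation f_ab is the (population) standard deviation of the Cα–Cα
   distance d_ab over the conformers. Rigidly coupled pairs fluctuate
   little.
2. **Mechanical coupling network.** Couplings are the Gaussian weights
   σ_ab = exp(−f_ab² / 2f̄²), restricted to pairs whose mean distance is
   below 12 Å; the sensitivity f̄ is the mean fluctuation over those local
   pairs.
3. **Mechanical bridging score.** With the symmetric normalized Laplacian
   L = I − D^{−1/2} σ D^{−1/2} (D the degree matrix) and its eigenvalues
   0 = λ₀ ≤ … ≤ λ_{N−1}, the network softness is Ω = Σ̃ 1/λᵢ (zero
   eigenvalues omitted). The score of residue k is

   Δ_k = Ω_k − Ω₀,

   where Ω_k is recomputed after deleting all *non-bonded* couplings of
   node k. A large Δ_k means the residue's contacts are load-bearing for
   the network's overall mechanical connectedness.

Per-receptor profiles can be mapped onto generic (GPCRdb-style "AxBB")
position labels, averaged across homologous receptors, given error bars
from active–inactive structure pairs, benchmarked against a static
coordination-number baseline via ROC curves, and complemented by a
spectral quasi-rigid domain decomposition of the same network. A synthetic
generator plants hinged rigid-body ensembles with known ground truth, so
the whole pipeline is testable without external data.

## Worked example

Score a synthetic two-body ensemble with one planted hinge (60 residues,
20 conformers, ±25° hinge motion, 0.2 Å noise):

```python
import numpy as np
from mechbridge import (make_hinge_ensemble, distance_stats, build_network,
                        bridging_profile, partition_domains)

ens, truth = make_hinge_ensemble([30, 30], max_angle=25.0, noise_sd=0.2,
                                 n_members=20, seed=1)
net = build_network(distance_stats(ens))
print(f"sensitivity f_bar = {net.sensitivity:.3f} A")

prof = bridging_profile(net)
print(f"baseline softness Omega_0 = {prof.omega0:.2f}")
for i in np.argsort(prof.scores)[::-1][:5]:
    print(f"residue {prof.residues[i]}  Delta = {prof.scores[i]:.2f}")
print("planted hinge:", sorted(truth.hinge_residues))

part = partition_domains(net, k=2, seed=0)
print(f"k=2 quality (silhouette) = {part.quality:.3f}")
```

prints

```
sensitivity f_bar = 0.295 A
baseline softness Omega_0 = 74.79
residue A:ALA31  Delta = 7.75
residue A:ALA30  Delta = 3.67
residue A:ALA55  Delta = 2.91
residue A:ALA6  Delta = 2.87
residue A:ALA7  Delta = 2.84
planted hinge: [30]
k=2 quality (silhouette) = 0.934
```

The hinge (0-based index 30, i.e. residue 31 — the first residue of the
second rigid body) tops the profile: deleting its couplings softens the
network by Δ = 7.75, twice the runner-up. Its chain neighbour ranks second,
as expected for an interface. The k = 2 domain decomposition splits the
chain at the same point with a near-perfect silhouette.

For real data, point the CLI at a dataset manifest (TSV of receptor, PDB
path, activation state) and a generic-numbering map:

```sh
mechbridge run --manifest data.tsv --numbering map.tsv --chain A --out out/
mechbridge domains --manifest data.tsv --k 2..10 --out out/
mechbridge simulate hinge --bodies 30,30 --members 20 --seed 1 --out sim/
```

`run` writes per-receptor profile TSVs, the cross-receptor aggregated
profile, the coordination baseline, a ROC table against a key-site list
(a curated list of known class A GPCR functional sites ships as editable
package data), and a JSONL run manifest.

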