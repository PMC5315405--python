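"""Distance-fluctuation statistics and the Gaussian mechanical coupling network.

The pairwise distance fluctuation f_ab is the population standard deviation
of the Cα–Cα distance d_ab across the ensemble members; its Gaussian
transform sigma_ab = exp(-f_ab^2 / 2 f̄^2), restricted to residue pairs whose
mean distance lies below a 12 Å cutoff, defines the local mechanical
coupling network. The sensitivity f̄ is the mean fluctuation over the
within-cutoff pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ensemble_io import Ensemble, ResidueKey

DEFAULT_CUTOFF = 12.0  # Å

#: an f̄ below this (Å) means a numerically rigid ensemble: far below any
#: physical fluctuation, it only carries coordinate round-off
RIGID_SENSITIVITY_TOL = 1e-9


@dataclass
class FluctuationStats:
    """Pairwise mean distances and distance fluctuations over an ensemble."""

    mean_distance: np.ndarray  # (N, N) Å
    fluctuation: np.ndarray  # (N, N) Å, population std of d_ab
    n_members: int
    residues: list[ResidueKey]

    def __post_init__(self):
        for name in ("mean_distance", "fluctuation"):
            m = getattr(self, name)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if np.any(self.fluctuation < 0):
            raise ValueError("fluctuations must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.mean_distance.shape[0]


@dataclass
class MechanicalNetwork:
    """Symmetric coupling matrix with cutoff, sensitivity and bonded mask."""

    coupling: np.ndarray  # (N, N) sigma in [0, 1]
    cutoff: float  # Å
    sensitivity: float  # Å, f̄
    bonded_mask: np.ndarray  # (N, N) bool
    residues: list[ResidueKey]

    def __post_init__(self):
        s = self.coupling
        if not np.allclose(s, s.T):
            raise ValueError("coupling must be symmetric")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("couplings must lie in [0, 1]")
        if np.any(np.diag(s) != 0):
            raise ValueError("coupling diagonal must be zero")

    @property
    def n_residues(self) -> int:
        return self.coupling.shape[0]

    def with_coupling(self, coupling: np.ndarray) -> "MechanicalNetwork":
        return replace(self, coupling=coupling)


def distance_stats(ensemble: Ensemble) -> FluctuationStats:
    """Compute mean Cα–Cα distances and their fluctuations over an ensemble.

    The mean is the equal-weight average over members; the fluctuation is
    the population standard deviation (second-moment form, divisor M),
    invariant under global rigid-body motion of any member.
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble must have >= 2 members for fluctuations")
    dists = np.stack(
        [squareform(pdist(m.coordinates)) for m in ensemble.members]
    )
    mean = dists.mean(axis=0)
    # two-pass population variance: same moment-form quantity, but immune to
    # the catastrophic cancellation of <d^2> - <d>^2
    var = ((dists - mean) ** 2).mean(axis=0)
    return FluctuationStats(mean, np.sqrt(var), len(ensemble), list(ensemble.residues))


def bonded_mask(residues: Sequence[ResidueKey]) -> np.ndarray:
    """Boolean matrix marking chain-bonded (peptide-neighbour) residue pairs.

    Two residues are bonded iff they sit on the same chain with consecutive
    author numbers (|Δseq| = 1, no insertion codes). A numbering gap — e.g.
    a residue dropped from the common set — breaks the bond.
    """
    n = len(residues)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        a, b = residues[i], residues[i + 1]
        if (
            a.chain_id == b.chain_id
            and a.insertion_code == ""
            and b.insertion_code == ""
            and b.seq_number - a.seq_number == 1
        ):
            mask[i, i + 1] = mask[i + 1, i] = True
    return mask


def build_network(
    stats: FluctuationStats,
    bonded: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> MechanicalNetwork:
    """Build the Gaussian coupling network from fluctuation statistics.

    f̄ is the mean of f_ab over unordered non-self pairs with mean distance
    strictly below the cutoff (bonded pairs included). sigma_ab =
    exp(-f_ab^2 / 2 f̄^2) within the cutoff, zero outside and on the
    diagonal. A rigid ensemble (f̄ below round-off scale) takes the
    continuous f -> 0 limit: sigma = 1 for every within-cutoff pair.
    """
    n = stats.n_residues
    if bonded is None:
        bonded = bonded_mask(stats.residues)
    within = (stats.mean_distance < cutoff) & ~np.eye(n, dtype=bool)
    if not within.any():
        raise ValueError(f"no residue pair within the {cutoff} Å cutoff")
    iu = np.triu_indices(n, k=1)
    sel = within[iu]
    fbar = float(stats.fluctuation[iu][sel].mean())
    if fbar > RIGID_SENSITIVITY_TOL:
        sigma = np.exp(-(stats.fluctuation**2) / (2.0 * fbar**2))
    else:
        fbar = 0.0
        sigma = np.ones((n, n))
    sigma = np.where(within, sigma, 0.0)
    np.fill_diagonal(sigma, 0.0)
    return MechanicalNetwork(sigma, cutoff, fbar, np.asarray(bonded, bool),
                             list(stats.residues))
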