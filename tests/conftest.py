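"""Shared fixtures: toy networks, random-network factory, brute-force oracle."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from mechbridge.ensemble_io import ResidueKey
from mechbridge.mech_network import MechanicalNetwork, bonded_mask


def chain_residues(n: int, chain: str = "A", start: int = 1) -> list[ResidueKey]:
    return [ResidueKey(chain, start + i, "", "ALA") for i in range(n)]


def make_network(
    sigma: np.ndarray,
    bonded: np.ndarray | None = None,
    cutoff: float = 12.0,
    sensitivity: float = 1.0,
) -> MechanicalNetwork:
    """Wrap a coupling matrix in a network with a chain bonded mask."""
    n = sigma.shape[0]
    res = chain_residues(n)
    if bonded is None:
        bonded = bonded_mask(res)
    return MechanicalNetwork(np.asarray(sigma, float), cutoff, sensitivity,
                             np.asarray(bonded, bool), res)


def random_connected_network(rng: np.random.Generator) -> MechanicalNetwork:
    """Random coupling network on a bonded chain backbone (hence connected)."""
    n = int(rng.integers(5, 51))
    sigma = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(0.0, 1.0, size=len(iu[0]))
    keep = rng.uniform(size=len(iu[0])) < 0.2
    sigma[iu] = np.where(keep, vals, 0.0)
    sigma = sigma + sigma.T
    # chain couplings ensure connectivity and a non-trivial bonded mask
    idx = np.arange(n - 1)
    chain_vals = rng.uniform(0.1, 1.0, size=n - 1)
    sigma[idx, idx + 1] = chain_vals
    sigma[idx + 1, idx] = chain_vals
    return make_network(sigma)


# ---------------------------------------------------------------------------
# independent oracle: rebuild, dense eigendecomposition, component count by
# graph traversal (networkx), softness by summing inverse non-zero eigenvalues


def oracle_softness(sigma: np.ndarray) -> float:
    n = sigma.shape[0]
    graph = nx.from_numpy_array((sigma > 0).astype(int))
    n_components = nx.number_connected_components(graph)
    degree = sigma.sum(axis=1)
    dinv = np.zeros(n)
    nz = degree > 0
    dinv[nz] = 1.0 / np.sqrt(degree[nz])
    lap = np.eye(n) - dinv[:, None] * sigma * dinv[None, :]
    lap[~nz, ~nz] = 0.0
    vals = np.sort(np.linalg.eigvalsh(lap))
    return float(np.sum(1.0 / vals[n_components:]))


def oracle_bridging(network: MechanicalNetwork) -> np.ndarray:
    """Naive per-residue rebuild-and-decompose bridging scores."""
    sigma = network.coupling
    omega0 = oracle_softness(sigma)
    out = np.zeros(sigma.shape[0])
    for k in range(sigma.shape[0]):
        pruned = sigma.copy()
        nonbonded = ~network.bonded_mask[k]
        pruned[k, nonbonded] = 0.0
        pruned[nonbonded, k] = 0.0
        out[k] = oracle_softness(pruned) - omega0
    return out


@pytest.fixture
def two_clique_network() -> MechanicalNetwork:
    """Two 10-cliques joined by one weak link: ideal two-block structure."""
    n = 20
    sigma = np.zeros((n, n))
    sigma[:10, :10] = 0.9
    sigma[10:, 10:] = 0.9
    np.fill_diagonal(sigma, 0.0)
    sigma[9, 10] = sigma[10, 9] = 0.05
    return make_network(sigma)
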