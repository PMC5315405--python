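"""Mechanical bridging score via normalized-Laplacian spectral perturbation.

The network softness Omega = sum of inverse non-zero eigenvalues of the
symmetric normalized Laplacian L = I - D^{-1/2} sigma D^{-1/2}. The
bridging score of residue k, Delta_k, is the softening Omega_k - Omega_0
caused by deleting all non-bonded couplings of node k while keeping the
node (and its chain bonds) in place, so the matrix size is constant and
softness differences are comparable.

Zero eigenvalues — one per connected component of the coupling graph —
are omitted from every softness sum. A deletion that disconnects the
network produces extra zeros; by default the residue is still scored
under the same omission rule and flagged, optionally it can be masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, eigvalsh

from .mech_network import MechanicalNetwork

logger = logging.getLogger("mechbridge")

#: eigenvalue lambda is treated as zero iff lambda < tol * max(lambda_max, 1)
DEFAULT_ZERO_TOL = 1e-9


@dataclass
class LaplacianSpectrum:
    matrix: np.ndarray
    eigenvalues: np.ndarray  # ascending, clipped at 0
    zero_tolerance: float
    n_zero: int
    eigenvectors: np.ndarray | None = None


@dataclass
class BridgingProfile:
    receptor_id: str
    residues: list
    omega0: float
    scores: np.ndarray  # Delta_k per residue; NaN where masked
    disconnection_flags: np.ndarray  # bool per residue

    def as_dict(self) -> dict:
        return {str(r): float(s) for r, s in zip(self.residues, self.scores)}


def _laplacian_matrix(coupling: np.ndarray) -> np.ndarray:
    degree = coupling.sum(axis=1)
    isolated = degree <= 0
    with np.errstate(divide="ignore"):
        dinv = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, degree)))
    lap = np.eye(len(degree)) - (dinv[:, None] * coupling * dinv[None, :])
    # an isolated node is its own component: exact zero eigenvalue
    lap[isolated, isolated] = 0.0
    return lap


def _spectrum(
    coupling: np.ndarray, zero_tolerance: float, want_vectors: bool = False
) -> LaplacianSpectrum:
    if not np.any(coupling > 0):
        raise ValueError("all-zero coupling network has no spectrum of interest")
    lap = _laplacian_matrix(coupling)
    if want_vectors:
        vals, vecs = eigh(lap)
    else:
        vals, vecs = eigvalsh(lap), None
    tol = zero_tolerance * max(float(vals[-1]), 1.0)
    if vals[0] < -tol:
        raise np.linalg.LinAlgError(
            f"normalized Laplacian has eigenvalue {vals[0]} below -tolerance"
        )
    vals = np.clip(vals, 0.0, None)
    n_zero = int(np.count_nonzero(vals < tol))
    return LaplacianSpectrum(lap, vals, zero_tolerance, n_zero, vecs)


def normalized_laplacian(
    network: MechanicalNetwork,
    zero_tolerance: float = DEFAULT_ZERO_TOL,
    want_vectors: bool = False,
) -> LaplacianSpectrum:
    """Symmetric normalized Laplacian spectrum of the coupling network.

    Eigenvalues within -tolerance of zero are clipped to 0; the zero count
    equals the number of connected components of the sigma > 0 graph.
    Isolated (degree-0) nodes get a 0 diagonal entry so they contribute an
    exact zero eigenvalue.
    """
    return _spectrum(network.coupling, zero_tolerance, want_vectors)


def softness(spectrum: LaplacianSpectrum) -> float:
    """Network softness: sum of inverse eigenvalues, zeros omitted."""
    nz = spectrum.eigenvalues[spectrum.n_zero:]
    if nz.size == 0:
        raise ValueError("all eigenvalues are zero; softness undefined")
    return float(np.sum(1.0 / nz))


def delete_node_couplings(network: MechanicalNetwork, k: int) -> MechanicalNetwork:
    """Zero all non-bonded couplings of node k (symmetric); bonds retained."""
    if not 0 <= k < network.n_residues:
        raise IndexError(f"node index {k} out of range")
    sigma = network.coupling.copy()
    keep = network.bonded_mask[k]
    sigma[k, ~keep] = 0.0
    sigma[~keep, k] = 0.0
    return network.with_coupling(sigma)


def bridging_profile(
    network: MechanicalNetwork,
    zero_tolerance: float = DEFAULT_ZERO_TOL,
    mask_disconnecting: bool = False,
    receptor_id: str = "",
) -> BridgingProfile:
    """Per-residue mechanical bridging scores Delta_k = Omega_k - Omega_0.

    Residues whose every coupling is a chain bond have Delta_k = 0 exactly
    (deletion is a no-op). When a deletion splits the network the residue is
    flagged; with ``mask_disconnecting`` its score becomes NaN instead,
    mirroring exclusion of disconnection-prone positions from the common set.
    """
    base = _spectrum(network.coupling, zero_tolerance)
    if base.n_zero > 1:
        logger.warning(
            "coupling network has %d connected components; scores computed "
            "with all zero modes omitted", base.n_zero,
        )
    omega0 = softness(base)
    n = network.n_residues
    scores = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    nonbonded = network.coupling * ~network.bonded_mask
    for k in range(n):
        if not np.any(nonbonded[k] > 0):
            continue  # nothing to delete: Delta_k = 0
        try:
            spec = _spectrum(
                delete_node_couplings(network, k).coupling, zero_tolerance
            )
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"eigendecomposition failed deleting residue {network.residues[k]}"
            ) from exc
        flags[k] = spec.n_zero > base.n_zero
        scores[k] = softness(spec) - omega0
    if mask_disconnecting:
        scores = np.where(flags, np.nan, scores)
    return BridgingProfile(receptor_id, list(network.residues), omega0, scores, flags)
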