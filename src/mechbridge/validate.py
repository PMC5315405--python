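"""Static coordination baseline and ROC validation against key-site lists.

The coordination number of a residue is its count of spatial neighbours —
mean Cα–Cα distance below the (12 Å by default) network cutoff, self
excluded, chain bonds included. It is a purely static centrality that
serves as the reference ranking the dynamical bridging score is compared
against.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics

from .aggregate import generic_sort_key, load_position_list
from .mech_network import DEFAULT_CUTOFF, FluctuationStats


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending score values
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def default_key_sites() -> list[str]:
    """Packaged list of known key functional positions (editable data file)."""
    ref = resources.files("mechbridge.data") / "key_sites.txt"
    with resources.as_file(ref) as p:
        return load_position_list(p)


def coordination_counts(
    stats: FluctuationStats, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Per-residue neighbour counts under the mean-distance contact criterion."""
    n = stats.n_residues
    within = (stats.mean_distance < cutoff) & ~np.eye(n, dtype=bool)
    return within.sum(axis=1).astype(float)


def coordination_profile(
    per_receptor: Mapping[str, pd.Series],
) -> pd.Series:
    """Average per-position coordination over receptors (shared positions only).

    Each value of ``per_receptor`` maps generic numbers to counts for one
    receptor (build with :func:`mechbridge.aggregate.profile_by_position`
    applied to coordination scores, or directly).
    """
    table = pd.DataFrame(per_receptor).dropna(axis=0, how="any")
    out = table.mean(axis=1)
    return out.sort_index(key=lambda ix: [generic_sort_key(p) for p in ix])


def roc_curve(
    scores: Mapping[str, float] | pd.Series,
    positives: Iterable[str],
) -> ROCResult:
    """ROC of a per-position score against a key-site list.

    Positions are ranked by descending score; ties follow the rank-average
    (Mann–Whitney) convention, so the AUC equals the U-statistic estimate.
    """
    series = pd.Series(scores, dtype=float)
    positives = set(positives)
    unknown = positives - set(series.index)
    if unknown:
        raise ValueError(f"positives not among scored positions: {sorted(unknown)}")
    y = series.index.isin(positives).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both positive and negative positions for a ROC")
    fpr, tpr, thr = metrics.roc_curve(y, series.to_numpy(), drop_intermediate=False)
    auc = float(metrics.auc(fpr, tpr))
    return ROCResult(thr, fpr, tpr, auc)


def top_k(scores: Mapping[str, float] | pd.Series, k: int) -> list[str]:
    """Top-k positions by descending score, stable tie-break by position order."""
    series = pd.Series(scores, dtype=float)
    if k > len(series):
        raise ValueError(f"k={k} exceeds {len(series)} positions")
    order = series.sort_values(ascending=False, kind="stable")
    return list(order.index[:k])
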