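"""Cross-receptor aggregation of bridging profiles over generic numbers.

Per-receptor profiles live on author-numbered residues; comparison across
receptors goes through the generic AxBB position labels. Aggregation keeps
only positions present in every contributing profile (optionally further
restricted to a transmembrane whitelist) and averages with equal receptor
weight; spread across contributors is the population standard deviation.

Error bars within one receptor come instead from profiles recomputed on
every (active, inactive) structure pair of its ensemble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .bridging import BridgingProfile, bridging_profile
from .ensemble_io import Ensemble
from .mech_network import DEFAULT_CUTOFF, build_network, distance_stats


@dataclass
class AggregatedProfile:
    positions: list[str]  # generic numbers, helix-major order
    mean_score: np.ndarray
    error: np.ndarray  # population std across contributors
    n_contributors: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generic_number": self.positions,
                "mean_score": self.mean_score,
                "error": self.error,
                "n_contributors": self.n_contributors,
            }
        )


def generic_sort_key(position: str) -> tuple[int, int]:
    helix, idx = position.split("x")
    return int(helix), int(idx)


def expand_range(spec: str) -> list[str]:
    """Expand "3x24-3x54" (or a single "3x50") into explicit positions."""
    spec = spec.replace("–", "-").strip()
    if "-" not in spec:
        return [spec]
    lo, hi = spec.split("-")
    h1, i1 = generic_sort_key(lo)
    h2, i2 = generic_sort_key(hi)
    if h1 != h2 or i2 < i1:
        raise ValueError(f"bad generic-number range {spec!r}")
    return [f"{h1}x{i:02d}" for i in range(i1, i2 + 1)]


def load_position_list(path: str | Path) -> list[str]:
    """Read generic numbers or ranges, one per line, '#' comments."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            out.extend(expand_range(line))
    return out


def default_whitelist() -> list[str]:
    """Packaged transmembrane position ranges used for cross-receptor work."""
    ref = resources.files("mechbridge.data") / "tm_ranges.txt"
    with resources.as_file(ref) as p:
        return load_position_list(p)


def profile_by_position(
    profile: BridgingProfile,
    numbering: Optional[Mapping[tuple[str, str, int], str]] = None,
) -> pd.Series:
    """Scores keyed by generic number; unmapped residues are dropped.

    Numbering comes from the residues' own ``generic_number`` annotations or,
    if a map is given, from (receptor, chain, seq) lookup. A generic number
    claimed by two residues of one receptor is an error.
    """
    pos: dict[str, float] = {}
    for r, s in zip(profile.residues, profile.scores):
        gn = r.generic_number
        if gn is None and numbering is not None:
            gn = numbering.get((profile.receptor_id, r.chain_id, r.seq_number))
        if gn is None:
            continue
        if gn in pos:
            raise ValueError(
                f"{profile.receptor_id}: generic number {gn} maps to two residues"
            )
        pos[gn] = float(s)
    return pd.Series(pos, dtype=float)


def align_profiles(
    profiles: Sequence[BridgingProfile],
    numbering: Optional[Mapping[tuple[str, str, int], str]] = None,
    position_whitelist: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Position x receptor score table over shared generic numbers.

    Rows are the generic numbers present in every profile, intersected with
    the whitelist when one is given, in helix-major order.
    """
    if not profiles:
        raise ValueError("no profiles to align")
    cols = {p.receptor_id or f"receptor{i}": profile_by_position(p, numbering)
            for i, p in enumerate(profiles)}
    table = pd.DataFrame(cols).dropna(axis=0, how="any")
    if position_whitelist is not None:
        table = table.loc[table.index.intersection(set(position_whitelist))]
    return table.sort_index(key=lambda ix: [generic_sort_key(p) for p in ix])


def average_profile(table: pd.DataFrame) -> AggregatedProfile:
    """Equal-weight mean across receptors per position; population std error."""
    if table.empty:
        raise ValueError("empty position table")
    return AggregatedProfile(
        positions=list(table.index),
        mean_score=table.mean(axis=1).to_numpy(),
        error=table.std(axis=1, ddof=0).to_numpy(),
        n_contributors=np.full(len(table), table.shape[1], dtype=int),
    )


def pair_error_profile(
    ensemble: Ensemble,
    cutoff: float = DEFAULT_CUTOFF,
    include_partially_active: bool = False,
    zero_tolerance: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and per-residue error of profiles over active-inactive pairs.

    Each (active, inactive) member pair yields a bridging profile from that
    two-structure ensemble; the error per residue is the population standard
    deviation across the pair profiles. Partially active structures are
    excluded from pairing unless ``include_partially_active`` groups them
    with the active set. Returns (mean_profile, error, n_pairs).
    """
    active = ensemble.members_by_state("active")
    if include_partially_active:
        active = active + ensemble.members_by_state("partially_active")
    inactive = ensemble.members_by_state("inactive")
    if not active or not inactive:
        raise ValueError(
            f"{ensemble.receptor_id}: need at least one active and one "
            "inactive member for pairing"
        )
    profiles = []
    for a, i in itertools.product(active, inactive):
        pair = Ensemble(ensemble.receptor_id, [a, i], list(ensemble.residues))
        net = build_network(distance_stats(pair), cutoff=cutoff)
        profiles.append(
            bridging_profile(net, zero_tolerance, receptor_id=ensemble.receptor_id).scores
        )
    arr = np.stack(profiles)
    return arr.mean(axis=0), arr.std(axis=0, ddof=0), arr.shape[0]


def pearson_correlation(p: np.ndarray, q: np.ndarray) -> float:
    """Product-moment correlation between two score vectors."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape or p.size < 3:
        raise ValueError("inputs must be equal-length vectors of size >= 3")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(sstats.pearsonr(p, q).statistic)
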