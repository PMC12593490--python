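"""Pairwise genetic similarity (GS) and strain clustering.

GS(%) = n / N x 100, where n is the number of MNP markers at which two
strains carry identical genotypes (exact haplotype-set equality) and N is,
by default, the total marker count of the database (``mode="total"``; a
MISSING call in either strain is a non-match). ``mode="shared"`` restricts
N to markers called in both strains, which is more forgiving on real data
with dropout. GS is rounded half-away-from-zero to two decimals.

Varieties with GS >= 99% are classified identical (the registration rule
for predominantly asexually propagated crops); everything below is a
distinct variety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ContractError
from .mnp_genotyping import MarkerDatabase, MnpProfile

IDENTITY_THRESHOLD = 99.0


def round_percent(x: float) -> float:
    """Two-decimal rounding, half away from zero (matches printed GS values)."""
    return math.copysign(math.floor(abs(x) * 100 + 0.5) / 100.0, x)


@dataclass(frozen=True)
class GsResult:
    strain_a: str
    strain_b: str
    n: int           # matching markers
    N: int           # compared markers
    gs: float        # percent, 2-decimal

    def swapped(self) -> "GsResult":
        return GsResult(self.strain_b, self.strain_a, self.n, self.N, self.gs)


def compute_gs(a: MnpProfile, b: MnpProfile, mode: str = "total") -> GsResult:
    """GS between two profiles from the same marker database."""
    if set(a.calls) != set(b.calls):
        raise ContractError(
            f"profiles {a.strain!r} and {b.strain!r} cover different marker sets")
    if mode not in ("total", "shared"):
        raise ContractError(f"unknown GS mode {mode!r}")
    n = 0
    n_shared = 0
    for mid, ga in a.calls.items():
        gb = b.calls[mid]
        if ga.haplotypes is None or gb.haplotypes is None:
            continue
        n_shared += 1
        if ga.haplotypes == gb.haplotypes:
            n += 1
    N = len(a.calls) if mode == "total" else n_shared
    if N == 0:
        raise ContractError(
            f"no comparable markers between {a.strain!r} and {b.strain!r}")
    return GsResult(a.strain, b.strain, n, N, round_percent(100.0 * n / N))


@dataclass
class GsMatrix:
    strains: list[str]
    values: dict[tuple[str, str], GsResult]

    def get(self, a: str, b: str) -> GsResult:
        if a == b:
            return GsResult(a, a, 0, 0, 100.0)
        r = self.values.get((a, b))
        return r if r is not None else self.values[(b, a)].swapped()

    def to_frame(self) -> pd.DataFrame:
        k = len(self.strains)
        arr = np.full((k, k), 100.0)
        for i, a in enumerate(self.strains):
            for j in range(i + 1, k):
                arr[i, j] = arr[j, i] = self.get(a, self.strains[j]).gs
        return pd.DataFrame(arr, index=self.strains, columns=self.strains)


def gs_matrix(db: MarkerDatabase, mode: str = "total") -> GsMatrix:
    """All C(k,2) pairwise GS values; diagonal is 100.00 by definition."""
    strains = list(db.profiles)
    if len(strains) < 2:
        raise ContractError("pairwise comparison needs at least 2 strains")
    values = {}
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            values[(a, b)] = compute_gs(db.profiles[a], db.profiles[b], mode)
    return GsMatrix(strains=strains, values=values)


def classify_pair(gs: float, identity_threshold: float = IDENTITY_THRESHOLD) -> str:
    """'identical' iff gs >= threshold (inclusive), else 'distinct'."""
    if not 0.0 <= gs <= 100.0:
        raise ContractError(f"GS {gs} outside [0, 100]")
    return "identical" if gs >= identity_threshold else "distinct"


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Agglomerative tree over strains: scipy linkage matrix + labels."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        # ultrametric convention: a merge at distance d sits at height d/2
        Z = self.linkage_matrix
        k = len(self.labels)

        def node(i: int) -> tuple[str, float]:
            if i < k:
                return self.labels[i], 0.0
            left, right = int(Z[i - k, 0]), int(Z[i - k, 1])
            height = Z[i - k, 2] / 2.0
            parts = []
            for c in (left, right):
                text, h = node(c)
                parts.append(f"{text}:{max(height - h, 0.0):.6g}")
            return "(" + ",".join(parts) + ")", height

        text, _ = node(2 * k - 2)
        return text + ";"


def cluster_from_distances(dist: np.ndarray, labels: Sequence[str],
                           method: str = "average") -> ClusterTree:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(labels), len(labels)):
        raise ContractError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ContractError("distance matrix is not symmetric")
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    return ClusterTree(labels=list(labels), linkage_matrix=Z, method=method)


def cluster_gs(m: GsMatrix, method: str = "average") -> ClusterTree:
    """Cluster strains on d = 1 - GS/100 (UPGMA by default)."""
    frame = m.to_frame()
    dist = 1.0 - frame.to_numpy() / 100.0
    np.fill_diagonal(dist, 0.0)
    return cluster_from_distances(dist, frame.index.tolist(), method=method)


# ---------------------------------------------------------------------------
# group range summaries
# ---------------------------------------------------------------------------

def summarize_ranges(m: GsMatrix, groups: Mapping[str, str]) -> pd.DataFrame:
    """Min/max/mean off-diagonal GS within and between labelled groups.

    Returns one row per group pair (within-group rows have group_a ==
    group_b); groups with no pairs are absent.
    """
    unknown = set(m.strains) - set(groups)
    if unknown:
        raise ContractError(f"strains without a group label: {sorted(unknown)}")
    labels = sorted(set(groups.values()))
    rows = []
    for ia, la in enumerate(labels):
        for lb in labels[ia:]:
            vals = []
            for i, a in enumerate(m.strains):
                for b in m.strains[i + 1:]:
                    pair = {groups[a], groups[b]} if groups[a] != groups[b] \
                        else {groups[a]}
                    if pair == ({la} if la == lb else {la, lb}):
                        vals.append(m.get(a, b).gs)
            if vals:
                rows.append((la, lb, len(vals), min(vals), max(vals),
                             round_percent(sum(vals) / len(vals))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_pairs",
                                       "min", "max", "mean"])
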