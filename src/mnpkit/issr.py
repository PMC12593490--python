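"""ISSR band-matrix comparator.

Inter-simple-sequence-repeat fingerprinting scores each strain for the
presence (1) or absence (0) of every clear electrophoresis band. The
comparator pipeline converts the 0/1 matrix to pairwise Jaccard distances
and builds an agglomerative tree, the classical alternative against which
MNP fingerprinting is judged.

Band identity across gels is taken as given; bands present in almost all or
almost no strains carry little information and are flagged with a warning,
not removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError
from .similarity import ClusterTree, cluster_from_distances

logger = logging.getLogger(__name__)


@dataclass
class BandMatrix:
    """strains x bands binary presence/absence matrix."""

    strains: list[str]
    bands: list[str]
    values: np.ndarray  # (n_strains, n_bands) of {0,1}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.strains)) != len(self.strains):
            raise ContractError("duplicate strain ids in band matrix")
        if self.values.shape != (len(self.strains), len(self.bands)):
            raise ContractError(
                f"band matrix shape {self.values.shape} != "
                f"{(len(self.strains), len(self.bands))}")
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("band matrix entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.bands)

    def validate_informative(self, lo: float = 0.05, hi: float = 0.95) -> list[str]:
        """Warn about bands present in > ``hi`` or < ``lo`` of strains."""
        freq = self.values.mean(axis=0)
        flagged = [b for b, f in zip(self.bands, freq) if f > hi or f < lo]
        if flagged:
            logger.warning("%d uninformative bands (freq <%.0f%% or >%.0f%%): %s",
                           len(flagged), lo * 100, hi * 100, flagged[:10])
        return flagged


def read_band_matrix(path) -> BandMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BandMatrix(strains=[str(s) for s in df.index],
                      bands=[str(b) for b in df.columns],
                      values=df.to_numpy())


def jaccard_distance(a, b) -> float:
    """1 - |a AND b| / |a OR b| on binary vectors; 0 if both are all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError(f"band vectors differ in length ({a.shape} vs {b.shape})")
    union = int(np.sum(a | b))
    if union == 0:
        logger.warning("both band vectors all-zero; Jaccard distance set to 0")
        return 0.0
    return 1.0 - int(np.sum(a & b)) / union


def jaccard_matrix(m: BandMatrix) -> np.ndarray:
    k = len(m.strains)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = jaccard_distance(m.values[i], m.values[j])
    return dist


def issr_tree(m: BandMatrix, method: str = "average") -> ClusterTree:
    """Agglomerative tree over strains from pairwise Jaccard distances."""
    if len(m.strains) < 2:
        raise ContractError("clustering needs at least 2 strains")
    return cluster_from_distances(jaccard_matrix(m), m.strains, method=method)


def band_summary(m: BandMatrix, primer_of_band: Mapping[str, str]) -> pd.DataFrame:
    """Polymorphic band count per primer, plus a 'total' row with the mean.

    A band counts as polymorphic when it is neither absent from all strains
    nor present in all of them.
    """
    unmapped = [b for b in m.bands if b not in primer_of_band]
    if unmapped:
        raise ContractError(f"bands without a primer mapping: {unmapped[:10]}")
    freq = m.values.mean(axis=0)
    polymorphic = (freq > 0.0) & (freq < 1.0)
    counts: dict[str, int] = {p: 0 for p in dict.fromkeys(primer_of_band.values())}
    for band, poly in zip(m.bands, polymorphic):
        if poly:
            counts[primer_of_band[band]] += 1
    total = sum(counts.values())
    rows = [(p, c) for p, c in counts.items()]
    df = pd.DataFrame(rows, columns=["primer", "n_polymorphic_bands"])
    df.attrs["total_bands"] = total
    df.attrs["mean_bands_per_primer"] = total / len(counts) if counts else 0.0
    return df
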