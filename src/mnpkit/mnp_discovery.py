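"""MNP marker discovery.

Scans a polymorphic-SNP callset with 100-bp windows anchored at each SNP,
scores every candidate window by the polymorphism information content (PIC)
of its multi-SNP genotype "words" across samples, and greedily selects
markers with PIC >= 0.5 spaced more than 50 kb apart.

Window genotype words are unphased: per SNP a sample contributes 'R'
(homozygous reference), the allele digit (homozygous alternate) or the
sorted allele pair (heterozygous), joined with '|'. Dikaryotic heterozygotes
make phase unknowable from a VCF, so PIC operates on these unphased words
rather than on haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError
from .formats_io import SnpTable

#: Defaults mirroring the published marker-screen parameters.
WINDOW_BP = 100
MIN_SNPS = 2
MAX_SNPS = 10
PIC_MIN = 0.5
SPACING_BP = 50_000


@dataclass(frozen=True)
class WindowCandidate:
    """A 100-bp window with 2-10 SNPs, before spacing selection."""

    chrom: str
    start: int
    end: int
    snp_positions: tuple[int, ...]
    pic: float
    word_freqs: dict[str, float] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class MnpMarker:
    """A selected MNP marker window.

    ``allele_words`` maps each observed window genotype word to its sample
    frequency; frequencies sum to 1.
    """

    marker_id: str
    chrom: str
    start: int
    end: int
    snp_positions: tuple[int, ...]
    pic: float
    allele_words: dict[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ps = self.snp_positions
        if list(ps) != sorted(set(ps)):
            raise ContractError(f"{self.marker_id}: SNP positions not sorted/unique")
        if ps and not (self.start <= ps[0] and ps[-1] <= self.end):
            raise ContractError(f"{self.marker_id}: SNPs outside [{self.start},{self.end}]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


# ---------------------------------------------------------------------------
# genotype words
# ---------------------------------------------------------------------------

def _pair_token(a: int, b: int) -> str:
    lo, hi = (a, b) if a <= b else (b, a)
    if lo == hi:
        return "R" if lo == 0 else str(lo)
    return f"{lo}{hi}"


def genotype_word(site_genotypes: Sequence[tuple[int, int] | None]) -> str:
    """Canonical unphased word for one sample over a window's SNPs.

    Heterozygous calls are order-normalised, so (1,0) and (0,1) encode
    identically. Missing calls violate the upstream polymorphic screen.
    """
    tokens = []
    for g in site_genotypes:
        if g is None:
            raise ContractError("MISSING genotype in window (screen violated)")
        tokens.append(_pair_token(g[0], g[1]))
    return "|".join(tokens)


def compute_pic(word_frequencies: Mapping[str, float], mode: str = "nei") -> float:
    """Polymorphism information content of a window.

    ``nei`` (default): gene diversity ``1 - sum(p_i^2)``. ``botstein``:
    ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``, the locus-informativeness
    variant used for pedigree markers.
    """
    freqs = np.asarray(list(word_frequencies.values()), dtype=float)
    if (freqs < 0).any():
        raise ContractError("negative word frequency")
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ContractError(f"word frequencies sum to {freqs.sum()}, not 1")
    p2 = float(np.sum(freqs ** 2))
    if mode == "nei":
        return 1.0 - p2
    if mode == "botstein":
        p4 = float(np.sum(freqs ** 4))
        return 1.0 - p2 - (p2 * p2 - p4)
    raise ContractError(f"unknown PIC mode {mode!r}")


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def _genotype_codes(table: SnpTable) -> np.ndarray:
    """(n_sites, n_samples) uint8 codes of unphased genotype pairs."""
    lo = np.minimum(table.geno[:, :, 0], table.geno[:, :, 1])
    hi = np.maximum(table.geno[:, :, 0], table.geno[:, :, 1])
    if (lo < 0).any():
        raise ContractError("table contains MISSING genotypes; run the "
                            "polymorphic screen first")
    if (hi >= 15).any():
        raise ContractError("more than 15 alternate alleles unsupported")
    return (lo * 16 + hi).astype(np.uint8)


def _decode_word(raw: bytes) -> str:
    return "|".join(_pair_token(c // 16, c % 16) for c in raw)


def _chrom_blocks(table: SnpTable):
    start = 0
    for i in range(1, len(table) + 1):
        if i == len(table) or table.chroms[i] != table.chroms[start]:
            yield table.chroms[start], start, i
            start = i


def scan_windows(table: SnpTable, window: int = WINDOW_BP,
                 min_snps: int = MIN_SNPS, max_snps: int = MAX_SNPS,
                 pic_mode: str = "nei") -> list[WindowCandidate]:
    """Enumerate candidate marker windows.

    One window ``[p, p + window - 1]`` is anchored at every SNP position
    ``p``; windows whose SNP count falls outside ``[min_snps, max_snps]``
    are dropped. Anchoring at SNP starts needs no step parameter and covers
    every maximal SNP cluster; distinct anchors yield distinct SNP sets, so
    no dedup pass is required.
    """
    if len(table) == 0:
        return []
    codes = _genotype_codes(table)
    n_samples = table.n_samples
    decode_cache: dict[bytes, str] = {}
    out: list[WindowCandidate] = []
    for chrom, c0, c1 in _chrom_blocks(table):
        pos = table.pos[c0:c1]
        ends = np.searchsorted(pos, pos + window - 1, side="right")
        for i in range(len(pos)):
            k = int(ends[i]) - i
            if k < min_snps or k > max_snps:
                continue
            sub = np.ascontiguousarray(codes[c0 + i:c0 + ends[i]].T)  # (s, k)
            counts: dict[bytes, int] = {}
            for s in range(n_samples):
                w = sub[s].tobytes()
                counts[w] = counts.get(w, 0) + 1
            freqs = {}
            for raw, c in counts.items():
                word = decode_cache.get(raw)
                if word is None:
                    word = decode_cache[raw] = _decode_word(raw)
                freqs[word] = c / n_samples
            pic = compute_pic(freqs, mode=pic_mode)
            start = int(pos[i])
            out.append(WindowCandidate(
                chrom=chrom, start=start, end=start + window - 1,
                snp_positions=tuple(int(p) for p in pos[i:ends[i]]),
                pic=pic, word_freqs=freqs))
    return out


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def select_markers(candidates: Sequence[WindowCandidate],
                   pic_min: float = PIC_MIN, spacing_bp: int = SPACING_BP,
                   rank_by_pic: bool = False) -> list[MnpMarker]:
    """Select markers: PIC >= ``pic_min``, then spacing > ``spacing_bp``.

    Default strategy is greedy left-to-right per chromosome: a candidate is
    accepted iff its start exceeds the last accepted start by more than
    ``spacing_bp`` (the first candidate on a chromosome is always accepted).
    With ``rank_by_pic`` candidates are instead considered in decreasing-PIC
    order and accepted when no already-accepted marker on the chromosome
    lies within ``spacing_bp``. Marker ids ``mnp_0001`` ... are assigned in
    (chrom, start) order either way.
    """
    eligible = [c for c in candidates if c.pic >= pic_min]
    accepted: list[WindowCandidate] = []
    if rank_by_pic:
        for c in sorted(eligible, key=lambda c: (-c.pic, c.chrom, c.start)):
            if all(a.chrom != c.chrom or abs(a.start - c.start) > spacing_bp
                   for a in accepted):
                accepted.append(c)
    else:
        last: dict[str, int] = {}
        for c in sorted(eligible, key=lambda c: (c.chrom, c.start)):
            if c.chrom not in last or c.start - last[c.chrom] > spacing_bp:
                accepted.append(c)
                last[c.chrom] = c.start
    accepted.sort(key=lambda c: (c.chrom, c.start))
    width = max(4, len(str(len(accepted))))
    return [
        MnpMarker(marker_id=f"mnp_{i + 1:0{width}d}", chrom=c.chrom,
                  start=c.start, end=c.end, snp_positions=c.snp_positions,
                  pic=c.pic, allele_words=dict(c.word_freqs))
        for i, c in enumerate(accepted)
    ]


def discover(table: SnpTable, window: int = WINDOW_BP, min_snps: int = MIN_SNPS,
             max_snps: int = MAX_SNPS, pic_min: float = PIC_MIN,
             spacing_bp: int = SPACING_BP, pic_mode: str = "nei",
             rank_by_pic: bool = False) -> list[MnpMarker]:
    """Full discovery: window scan followed by marker selection."""
    return select_markers(
        scan_windows(table, window, min_snps, max_snps, pic_mode),
        pic_min=pic_min, spacing_bp=spacing_bp, rank_by_pic=rank_by_pic)
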