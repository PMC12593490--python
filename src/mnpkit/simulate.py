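"""Synthetic strain populations with known truth.

Emulates the study population structure — two colour subpopulations (18
white + 14 gray strains), an F1 hybrid trio from two gray parents, optional
clonal duplicates — as biallelic SNPs Poisson-placed along chromosomes with
group-structured allele frequencies (Balding–Nichols model, divergence
``fst``). Each dikaryotic strain carries two haploid nuclei per site; with
probability ``het_rate`` the second nucleus is drawn independently of the
first, otherwise it copies it (homokaryotic state).

Downstream truth: after marker discovery on the simulated callset, each
strain's marker genotype is the unordered pair of window haplotype strings
read off its two nuclei. Pairs listed in ``marker_sharing_targets`` get
their genotypes copied at exactly ``round(f * M)`` markers and are forced to
differ elsewhere, so the genetic similarity of an engineered pair is known
exactly. Read counts are Poisson in total depth, split 50/50 between the
two haplotypes of a heterozygote, with independent per-base sequencing
errors diverting reads to off-target haplotype words.

The generator does not emulate alignment artefacts, mapping bias, indels,
linked selection or quality scores; recovery results on it bound what the
pipeline can do on ideal data, not on real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError
from .formats_io import CountTable, SnpTable
from .issr import BandMatrix
from .mnp_discovery import MnpMarker

#: Published chromosome lengths (bp) of the 42-Mb reference genome.
REFERENCE_CHROM_LENGTHS: dict[str, int] = {
    "chromosome01": 5_516_215,
    "chromosome02": 4_999_619,
    "chromosome03": 4_517_060,
    "chromosome04": 4_177_578,
    "chromosome05": 4_102_088,
    "chromosome06": 3_364_172,
    "chromosome07": 3_318_489,
    "chromosome08": 2_643_500,
    "chromosome09": 2_421_378,
    "chromosome10": 2_260_060,
    "chromosome11": 2_188_314,
    "chromosome12": 2_080_224,
}

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults mirror the study: 12 chromosomes with the published lengths,
    32 strains (18 white + 14 gray), ~1 SNP per 100 bp (≈420 k sites
    genome-wide), one F1 hybrid trio among the gray strains, 60x read
    depth and a 0.1% per-base error rate.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(REFERENCE_CHROM_LENGTHS))
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"white": 18, "gray": 14})
    snp_density: float = 0.01          # SNPs per bp
    het_rate: float = 0.5              # P(second nucleus drawn independently)
    fst: float = 0.25                  # between-group divergence
    n_hybrid_trios: int = 1            # F1 trios within the last group
    clone_pairs: tuple[tuple[str, str], ...] = ()
    marker_sharing_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    depth: float = 60.0                # fold coverage for read counts
    error_rate: float = 0.001          # per-base
    seed: int = 0

    def __post_init__(self):
        for name, rate in (("snp_density", self.snp_density),
                           ("het_rate", self.het_rate), ("fst", self.fst),
                           ("error_rate", self.error_rate)):
            if not 0 <= rate <= 1:
                raise ContractError(f"{name} {rate} outside [0, 1]")
        for f in self.marker_sharing_targets.values():
            if not 0 <= f <= 1:
                raise ContractError(f"sharing fraction {f} outside [0, 1]")

    @property
    def n_strains(self) -> int:
        return sum(self.group_sizes.values())

    def strain_names(self) -> list[str]:
        return [f"{g}_{i + 1:02d}" for g, n in self.group_sizes.items()
                for i in range(n)]


@dataclass
class SimTruth:
    """Ground truth: nuclei, pedigree, clones and engineered sharing."""

    strains: list[str]
    groups: dict[str, str]
    chroms: list[str]
    pos: np.ndarray
    ref: list[str]
    alts: list[str]
    nuclei: np.ndarray                      # (n_sites, n_strains, 2) of 0/1
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    clones: dict[str, str] = field(default_factory=dict)
    sharing: dict[tuple[str, str], float] = field(default_factory=dict)
    #: strain -> marker_id -> (hap1, hap2); filled by assign_marker_truth
    marker_haplotypes: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise ContractError(f"unknown strain {strain!r}") from None


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(cfg: SimConfig) -> tuple[SimTruth, SnpTable]:
    """Simulate the SNP callset and per-strain nuclei.

    Deterministic under ``cfg.seed``. Raises if the density is too low to
    place any 2-SNP window.
    """
    rng = np.random.default_rng(cfg.seed)
    strains = cfg.strain_names()
    groups = {s: g for g, n in cfg.group_sizes.items()
              for s in strains if s.startswith(f"{g}_")}

    chrom_list: list[str] = []
    pos_parts: list[np.ndarray] = []
    for chrom, length in cfg.chrom_lengths.items():
        n = rng.poisson(length * cfg.snp_density)
        n = min(n, length)
        p = np.sort(rng.choice(length, size=n, replace=False)) + 1
        chrom_list.extend([chrom] * n)
        pos_parts.append(p.astype(np.int64))
    pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
    n_sites = len(pos)
    if n_sites and not _any_two_snp_window(chrom_list, pos):
        raise ContractError("snp_density too low: no 100-bp window holds 2 SNPs")
    if n_sites == 0:
        raise ContractError("no SNPs placed; increase snp_density or lengths")

    # group-structured allele frequencies (Balding-Nichols around a shared
    # ancestral frequency)
    p0 = rng.uniform(0.1, 0.9, size=n_sites)
    nuclei = np.empty((n_sites, cfg.n_strains, 2), dtype=np.int8)
    col = 0
    for g, size in cfg.group_sizes.items():
        if cfg.fst > 0:
            a = p0 * (1 - cfg.fst) / cfg.fst
            b = (1 - p0) * (1 - cfg.fst) / cfg.fst
            pg = rng.beta(a, b)
        else:
            pg = p0
        first = rng.random((n_sites, size)) < pg[:, None]
        indep = rng.random((n_sites, size)) < pg[:, None]
        het = rng.random((n_sites, size)) < cfg.het_rate
        second = np.where(het, indep, first)
        nuclei[:, col:col + size, 0] = first
        nuclei[:, col:col + size, 1] = second
        col += size

    truth = SimTruth(strains=strains, groups=groups, chroms=chrom_list,
                     pos=pos,
                     ref=[_BASES[i] for i in rng.integers(0, 4, n_sites)],
                     alts=[], nuclei=nuclei)
    truth.alts = [_BASES[(b + int(o)) % 4] for b, o in
                  zip((_BASES.index(r) for r in truth.ref),
                      rng.integers(1, 4, n_sites))]

    _install_hybrids(cfg, truth, rng)
    for src, dst in cfg.clone_pairs:
        truth.nuclei[:, truth.strain_index(dst)] = \
            truth.nuclei[:, truth.strain_index(src)]
        truth.clones[dst] = src
        truth.sharing[(src, dst)] = 1.0
    for (a, b), f in cfg.marker_sharing_targets.items():
        truth.strain_index(a), truth.strain_index(b)
        truth.sharing[(a, b)] = f
    return truth, _to_snp_table(cfg, truth, rng)


def _any_two_snp_window(chroms: Sequence[str], pos: np.ndarray,
                        window: int = 100) -> bool:
    for i in range(1, len(pos)):
        if chroms[i] == chroms[i - 1] and pos[i] - pos[i - 1] <= window - 1:
            return True
    return False


def _install_hybrids(cfg: SimConfig, truth: SimTruth, rng: np.random.Generator):
    """Replace the tail strains of the last group by F1s of its first two.

    One whole nucleus is inherited per 100-bp block, so window haplotypes
    segregate as units (Mendelian sampling at the marker scale).
    """
    if cfg.n_hybrid_trios == 0:
        return
    last_group = list(cfg.group_sizes)[-1]
    members = [s for s in truth.strains if truth.groups[s] == last_group]
    need = 2 + 3 * cfg.n_hybrid_trios
    if len(members) < need:
        raise ContractError(
            f"group {last_group!r} has {len(members)} strains; "
            f"{need} needed for {cfg.n_hybrid_trios} hybrid trio(s)")
    pa, pb = members[0], members[1]
    ia, ib = truth.strain_index(pa), truth.strain_index(pb)
    block = np.zeros(len(truth.pos), dtype=np.int64)
    bid, prev = 0, None
    for i, (c, p) in enumerate(zip(truth.chroms, truth.pos)):
        key = (c, p // 100)
        if key != prev:
            bid += 1
            prev = key
        block[i] = bid
    n_blocks = bid + 1
    children = members[-3 * cfg.n_hybrid_trios:]
    for child in children:
        ic = truth.strain_index(child)
        pick_a = rng.integers(0, 2, n_blocks)[block]
        pick_b = rng.integers(0, 2, n_blocks)[block]
        rows = np.arange(len(truth.pos))
        truth.nuclei[:, ic, 0] = truth.nuclei[rows, ia, pick_a]
        truth.nuclei[:, ic, 1] = truth.nuclei[rows, ib, pick_b]
        truth.pedigree[child] = (pa, pb)


def _to_snp_table(cfg: SimConfig, truth: SimTruth,
                  rng: np.random.Generator) -> SnpTable:
    n = len(truth.pos)
    depth = rng.poisson(cfg.depth, size=(n, cfg.n_strains)).astype(np.int32)
    info = {
        "QD": rng.uniform(15, 35, n),
        "FS": rng.uniform(0, 5, n),
        "MQ": np.full(n, 60.0),
        "SOR": rng.uniform(0.5, 1.5, n),
        "MQRankSum": rng.normal(0, 1, n),
    }
    return SnpTable(samples=truth.strains, chroms=truth.chroms, pos=truth.pos,
                    ref=truth.ref, alts=[(a,) for a in truth.alts],
                    geno=truth.nuclei.astype(np.int16), depth=depth, info=info,
                    validate=False)


# ---------------------------------------------------------------------------
# marker-level truth
# ---------------------------------------------------------------------------

def assign_marker_truth(truth: SimTruth, markers: Sequence[MnpMarker],
                        seed: int = 0) -> None:
    """Fill ``truth.marker_haplotypes`` from nuclei at the markers' SNPs,
    then engineer the configured sharing fractions (exact to rounding)."""
    index = {(c, int(p)): i for i, (c, p) in enumerate(zip(truth.chroms, truth.pos))}
    site_rows = {
        m.marker_id: [index[(m.chrom, p)] for p in m.snp_positions]
        for m in markers
    }
    for s_idx, strain in enumerate(truth.strains):
        haps: dict[str, tuple[str, str]] = {}
        for m in markers:
            rows = site_rows[m.marker_id]
            pair = []
            for nucleus in (0, 1):
                pair.append("".join(
                    truth.alts[r] if truth.nuclei[r, s_idx, nucleus] else truth.ref[r]
                    for r in rows))
            haps[m.marker_id] = (pair[0], pair[1])
        truth.marker_haplotypes[strain] = haps
    _apply_sharing(truth, [m.marker_id for m in markers], seed)


def _apply_sharing(truth: SimTruth, marker_ids: list[str], seed: int) -> None:
    rng = np.random.default_rng(seed)
    M = len(marker_ids)
    for (a, b), f in truth.sharing.items():
        src, dst = truth.marker_haplotypes[a], truth.marker_haplotypes[b]
        m_shared = int(round(f * M))
        shared = set(rng.choice(M, size=m_shared, replace=False).tolist())
        for k, mid in enumerate(marker_ids):
            if k in shared:
                dst[mid] = src[mid]
            elif frozenset(dst[mid]) == frozenset(src[mid]):
                dst[mid] = _perturb(dst[mid], frozenset(src[mid]))


def _perturb(pair: tuple[str, str], avoid: frozenset[str]) -> tuple[str, str]:
    """Minimally mutate a haplotype pair until its set differs from ``avoid``."""
    h1, h2 = pair
    for base in _BASES:
        cand = (base + h1[1:], h2)
        if frozenset(cand) != avoid:
            return cand
    raise AssertionError("unreachable: 4 bases cannot all collide")


def simulate_hybrid(parent_a: Mapping[str, tuple[str, str]],
                    parent_b: Mapping[str, tuple[str, str]],
                    seed: int) -> dict[str, tuple[str, str]]:
    """F1 marker genotypes: one haplotype from each parent per marker,
    sampled independently across markers."""
    if set(parent_a) != set(parent_b):
        raise ContractError("parents cover different marker sets")
    rng = np.random.default_rng(seed)
    child = {}
    for mid in parent_a:
        ha = parent_a[mid][int(rng.integers(0, 2))]
        hb = parent_b[mid][int(rng.integers(0, 2))]
        child[mid] = (ha, hb)
    return child


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def simulate_strain_counts(haplotypes: Mapping[str, tuple[str, str]],
                           depth: float, error_rate: float,
                           rng: np.random.Generator, strain: str = "sim") -> CountTable:
    """Poisson read totals, 50/50 haplotype split for heterozygotes, and
    per-base errors that divert whole reads to off-target words."""
    ct = CountTable(strain=strain)
    for mid, (h1, h2) in haplotypes.items():
        total = int(rng.poisson(depth))
        counts: dict[str, int] = {}
        if h1 == h2:
            alloc = {h1: total}
        else:
            n1 = int(rng.binomial(total, 0.5))
            alloc = {h1: n1, h2: total - n1}
        k = len(h1)
        p_off = 1.0 - (1.0 - error_rate) ** k
        for hap, n in alloc.items():
            n_off = int(rng.binomial(n, p_off)) if error_rate > 0 else 0
            if n - n_off:
                counts[hap] = counts.get(hap, 0) + n - n_off
            for _ in range(n_off):
                i = int(rng.integers(0, k))
                wrong = _BASES[(_BASES.index(hap[i]) + int(rng.integers(1, 4))) % 4]
                bad = hap[:i] + wrong + hap[i + 1:]
                counts[bad] = counts.get(bad, 0) + 1
        ct.entries[mid] = counts
    return ct


def simulate_counts(truth: SimTruth, markers: Sequence[MnpMarker],
                    depth: float, error_rate: float,
                    seed: int) -> dict[str, CountTable]:
    """Count tables for every strain (marker truth must be assigned)."""
    if not truth.marker_haplotypes:
        raise ContractError("call assign_marker_truth before simulate_counts")
    rng = np.random.default_rng(seed)
    return {
        strain: simulate_strain_counts(truth.marker_haplotypes[strain], depth,
                                       error_rate, rng, strain=strain)
        for strain in truth.strains
    }


# ---------------------------------------------------------------------------
# ISSR bands
# ---------------------------------------------------------------------------

def simulate_bands(groups: Mapping[str, str], n_bands: int = 62,
                   n_primers: int = 10, flip_rate: float = 0.05,
                   pedigree: Mapping[str, tuple[str, str]] | None = None,
                   dropout: float = 0.1, seed: int = 0,
                   ) -> tuple[BandMatrix, dict[str, str]]:
    """Block-structured binary band matrix plus band -> primer mapping.

    Each group label gets a characteristic band profile; strains copy their
    group profile with per-band flip noise. F1 strains in ``pedigree``
    inherit the union of their parents' bands, each band then dropped with
    probability ``dropout``.
    """
    rng = np.random.default_rng(seed)
    strains = list(groups)
    labels = sorted(set(groups.values()))
    prototypes = {lab: rng.random(n_bands) < 0.5 for lab in labels}
    values = np.zeros((len(strains), n_bands), dtype=np.int8)
    for i, s in enumerate(strains):
        proto = prototypes[groups[s]]
        flip = rng.random(n_bands) < flip_rate
        values[i] = np.where(flip, ~proto, proto)
    if pedigree:
        idx = {s: i for i, s in enumerate(strains)}
        for child, (pa, pb) in pedigree.items():
            if child not in idx:
                continue
            union = values[idx[pa]].astype(bool) | values[idx[pb]].astype(bool)
            keep = rng.random(n_bands) >= dropout
            values[idx[child]] = union & keep
    primers = [f"P{p + 1:02d}" for p in range(n_primers)]
    bands = [f"{primers[j % n_primers]}_b{j // n_primers + 1}" for j in range(n_bands)]
    matrix = BandMatrix(strains=strains, bands=bands, values=values)
    return matrix, {b: b.split("_")[0] for b in bands}
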