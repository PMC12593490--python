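"""Sequencing-depth titration of MNP genotype concordance.

Downsamples a deep strain's window read counts to target coverages by
binomial thinning (each read kept independently with probability
``target / full``), re-genotypes, and counts markers whose call differs
from the full-depth reference profile. Markers that become MISSING at low
depth are tallied separately from discordant (differential) markers: only
loci called in both profiles can disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError
from .formats_io import CountTable
from .mnp_discovery import MnpMarker
from .mnp_genotyping import HET_THRESHOLD, MIN_READS, MnpProfile, genotype_strain


@dataclass(frozen=True)
class TitrationResult:
    depth: float
    replicate: int
    n_discordant: int
    n_missing: int


def downsample_counts(counts: CountTable, target_depth: float,
                      full_depth: float, seed: int | np.random.Generator) -> CountTable:
    """Binomially thin every haplotype count by ``target_depth / full_depth``."""
    if target_depth > full_depth:
        raise ContractError(
            f"target depth {target_depth} exceeds full depth {full_depth}")
    if full_depth <= 0:
        raise ContractError("full depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = target_depth / full_depth
    thinned = CountTable(strain=counts.strain)
    for mid, haps in counts.entries.items():
        thinned.entries[mid] = {
            h: int(rng.binomial(c, p)) if p < 1.0 else int(c)
            for h, c in haps.items()
        }
    return thinned


def count_discordant(reference: MnpProfile, test: MnpProfile) -> tuple[int, int]:
    """(discordant, newly missing) marker counts of ``test`` vs ``reference``.

    Discordant: both called, haplotype sets differ. Newly missing: called in
    the reference but MISSING in the test profile.
    """
    if set(reference.calls) != set(test.calls):
        raise ContractError("profiles cover different marker universes")
    discordant = missing = 0
    for mid, ref in reference.calls.items():
        t = test.calls[mid]
        if ref.haplotypes is None:
            continue
        if t.haplotypes is None:
            missing += 1
        elif t.haplotypes != ref.haplotypes:
            discordant += 1
    return discordant, missing


def titration_curve(counts_full: CountTable, markers: Sequence[MnpMarker],
                    full_depth: float, depths: Sequence[float], reps: int = 20,
                    seed: int = 0, het_threshold: float = HET_THRESHOLD,
                    min_reads: int = MIN_READS) -> list[TitrationResult]:
    """Thin to each target depth ``reps`` times and score against full depth."""
    if list(depths) != sorted(depths):
        raise ContractError("depths must be sorted ascending")
    reference = genotype_strain(counts_full, markers, het_threshold, min_reads)
    rng = np.random.default_rng(seed)
    out = []
    for depth in depths:
        for rep in range(reps):
            thinned = downsample_counts(counts_full, depth, full_depth, rng)
            profile = genotype_strain(thinned, markers, het_threshold, min_reads)
            d, m = count_discordant(reference, profile)
            out.append(TitrationResult(depth=depth, replicate=rep,
                                       n_discordant=d, n_missing=m))
    return out
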