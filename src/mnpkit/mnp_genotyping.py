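"""MNP genotype calling from window read counts.

A strain's genotype at a marker is the set of window haplotypes (1 for a
homokaryotic state, 2 for a dikaryotic heterozygote) whose read fraction
reaches the heterozygote threshold of 0.1 (inclusive). Markers with fewer
than ``min_reads`` spanning reads are MISSING. At most two haplotypes are
kept — dikaryon biology allows no more; additional passing haplotypes
indicate contamination or error and are dropped deterministically (top-2 by
count, lexicographic tie-break) with a log message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ContractError
from .formats_io import CountTable
from .mnp_discovery import MnpMarker

logger = logging.getLogger(__name__)

HET_THRESHOLD = 0.1
MIN_READS = 10


@dataclass(frozen=True)
class MnpGenotype:
    """Called genotype at one marker; ``haplotypes is None`` means MISSING."""

    marker_id: str
    haplotypes: frozenset[str] | None
    support: dict[str, int] = field(default_factory=dict, compare=False)
    total_reads: int = 0

    @property
    def is_missing(self) -> bool:
        return self.haplotypes is None

    @property
    def is_het(self) -> bool:
        return self.haplotypes is not None and len(self.haplotypes) == 2


@dataclass
class MnpProfile:
    """All marker calls for one strain; keys match the database marker list."""

    strain: str
    calls: dict[str, MnpGenotype] = field(default_factory=dict)


def call_genotype(counts: Mapping[str, int], het_threshold: float = HET_THRESHOLD,
                  min_reads: int = MIN_READS, marker_id: str = "") -> MnpGenotype:
    """Call one marker from ``haplotype -> read count``.

    Haplotypes with ``count / total >= het_threshold`` are retained
    (inclusive bound); totals below ``min_reads`` give MISSING.
    """
    if any(c < 0 for c in counts.values()):
        raise ContractError(f"negative read count at {marker_id or 'marker'}")
    total = sum(counts.values())
    if not counts:
        logger.warning("empty count map at %s -> MISSING", marker_id or "marker")
    if total < min_reads:
        return MnpGenotype(marker_id, None, dict(counts), total)
    passing = sorted(
        (h for h, c in counts.items() if c / total >= het_threshold),
        key=lambda h: (-counts[h], h))
    if not passing:  # unreachable for <=10 haplotypes at threshold 0.1; guarded
        return MnpGenotype(marker_id, None, dict(counts), total)
    if len(passing) > 2:
        logger.warning("%s: %d haplotypes pass the %.2f threshold; keeping "
                       "top 2 by count", marker_id or "marker", len(passing),
                       het_threshold)
        passing = passing[:2]
    return MnpGenotype(marker_id, frozenset(passing), dict(counts), total)


def genotype_strain(counts: CountTable, markers: Sequence[MnpMarker],
                    het_threshold: float = HET_THRESHOLD,
                    min_reads: int = MIN_READS, strict: bool = False) -> MnpProfile:
    """Call every marker for one strain; markers without counts are MISSING."""
    known = {m.marker_id for m in markers}
    unknown = set(counts.entries) - known
    if unknown:
        msg = f"{counts.strain}: counts reference unknown markers {sorted(unknown)[:5]}"
        if strict:
            raise ContractError(msg)
        logger.warning("%s (ignored)", msg)
    calls = {}
    for m in markers:
        haps = counts.entries.get(m.marker_id)
        if haps is None:
            calls[m.marker_id] = MnpGenotype(m.marker_id, None, {}, 0)
        else:
            bad = [h for h in haps if len(h) != m.n_snps]
            if bad:
                raise ContractError(
                    f"{counts.strain}/{m.marker_id}: haplotype length != "
                    f"{m.n_snps} SNPs (e.g. {bad[0]!r})")
            calls[m.marker_id] = call_genotype(haps, het_threshold, min_reads,
                                               marker_id=m.marker_id)
    return MnpProfile(strain=counts.strain, calls=calls)


@dataclass
class MarkerDatabase:
    """Marker definitions plus per-strain genotype profiles.

    Supports incremental addition of strains: a new profile can be added
    without touching existing entries, which is how a reference library grows
    as new varieties are registered.
    """

    markers: list[MnpMarker] = field(default_factory=list)
    profiles: dict[str, MnpProfile] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def add_profile(self, profile: MnpProfile) -> None:
        if profile.strain in self.profiles:
            raise ContractError(f"duplicate strain id {profile.strain!r}")
        want = set(self.marker_ids)
        got = set(profile.calls)
        if got != want:
            raise ContractError(
                f"profile {profile.strain!r} keys do not match the marker "
                f"list (missing {len(want - got)}, extra {len(got - want)})")
        self.profiles[profile.strain] = profile

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerDatabase):
            return NotImplemented
        if self.meta != other.meta or self.markers != other.markers:
            return False
        if set(self.profiles) != set(other.profiles):
            return False
        for s, p in self.profiles.items():
            q = other.profiles[s]
            if p.strain != q.strain or p.calls != q.calls:
                return False
        return True


def build_database(markers: Sequence[MnpMarker],
                   profiles: Sequence[MnpProfile],
                   meta: Mapping | None = None) -> MarkerDatabase:
    """Assemble a database; strain ids must be unique."""
    db = MarkerDatabase(markers=list(markers), meta=dict(meta or {}))
    for p in profiles:
        db.add_profile(p)
    return db
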