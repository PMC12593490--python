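"""On-disk artifact I/O: VCF callsets, haplotype read-count tables, marker
tables, the genotype database, distance matrices and Newick trees.

Coordinates are 1-based and intervals inclusive throughout (VCF convention);
a 100-bp marker window is ``[start, start + 99]``.

``SnpTable`` is stored columnar (numpy arrays for genotypes, depths and INFO
metrics) so that population-scale callsets (hundreds of thousands of sites x
tens of strains) stay cheap; the per-record view used in examples and tests
is materialised on demand via :meth:`SnpTable.records`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ContractError, DatabaseVersionError, FormatError

#: INFO metrics consumed by the hard filters.
DEFAULT_INFO_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum")

#: Schema tag embedded in every saved marker database.
DB_SCHEMA = "mnpkit.db/1"

#: Genotype sentinel for a missing diploid call ("./." in VCF).
MISSING = None


# ---------------------------------------------------------------------------
# SnpTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One VCF site: alleles, INFO metrics and per-sample calls."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alts: tuple[str, ...]
    info: dict[str, float]        # absent keys are absent, never 0
    genotypes: tuple[tuple[int, int] | None, ...]
    depths: tuple[int, ...]


class SnpTable:
    """Multi-sample SNP/InDel callset with per-sample GT and DP.

    Parameters
    ----------
    samples
        Ordered strain identifiers.
    chroms, pos, ref, alts
        Per-site metadata; positions must be strictly increasing within each
        chromosome.
    geno
        ``(n_sites, n_samples, 2)`` int16 allele indices, ``-1`` for missing.
    depth
        ``(n_sites, n_samples)`` int32 read depths.
    info
        Map INFO key -> float array, ``NaN`` meaning absent at that site.
    """

    def __init__(
        self,
        samples: Sequence[str],
        chroms: Sequence[str],
        pos: np.ndarray,
        ref: Sequence[str],
        alts: Sequence[tuple[str, ...]],
        geno: np.ndarray,
        depth: np.ndarray,
        info: Mapping[str, np.ndarray] | None = None,
        validate: bool = True,
    ):
        self.samples = list(samples)
        self.chroms = list(chroms)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alts = [tuple(a) for a in alts]
        self.geno = np.asarray(geno, dtype=np.int16)
        self.depth = np.asarray(depth, dtype=np.int32)
        self.info = {k: np.asarray(v, dtype=np.float64) for k, v in (info or {}).items()}
        if validate:
            self._validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _validate(self) -> None:
        n = len(self.pos)
        for name, got in (("chroms", len(self.chroms)), ("ref", len(self.ref)),
                          ("alts", len(self.alts))):
            if got != n:
                raise ContractError(f"{name} has length {got}, expected {n}")
        if self.geno.shape != (n, self.n_samples, 2):
            raise ContractError(
                f"geno shape {self.geno.shape} != {(n, self.n_samples, 2)}")
        if self.depth.shape != (n, self.n_samples):
            raise ContractError(
                f"depth shape {self.depth.shape} != {(n, self.n_samples)}")
        for k, v in self.info.items():
            if len(v) != n:
                raise ContractError(f"INFO {k} has length {len(v)}, expected {n}")
        # positions strictly increasing within each chromosome block
        seen: dict[str, int] = {}
        prev_chrom: str | None = None
        for i in range(n):
            c = self.chroms[i]
            if c != prev_chrom:
                if c in seen:
                    raise FormatError(
                        f"chromosome {c} appears in non-contiguous blocks")
                seen[c] = i
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise FormatError(
                    f"positions not strictly increasing on {c}: "
                    f"{self.pos[i - 1]} then {self.pos[i]} (record {i})")
        # allele indices in range
        for i in range(n):
            g = self.geno[i]
            hi = int(g.max(initial=-1))
            if hi > len(self.alts[i]):
                raise FormatError(
                    f"allele index {hi} out of range at {self.chroms[i]}:"
                    f"{self.pos[i]} ({1 + len(self.alts[i])} alleles)")

    # -- views --------------------------------------------------------------

    def record(self, i: int) -> SnpRecord:
        gt = []
        for s in range(self.n_samples):
            a, b = int(self.geno[i, s, 0]), int(self.geno[i, s, 1])
            gt.append(None if a < 0 or b < 0 else (a, b))
        info = {k: float(v[i]) for k, v in self.info.items() if not math.isnan(v[i])}
        return SnpRecord(self.chroms[i], int(self.pos[i]), self.ref[i],
                         self.alts[i], info, tuple(gt),
                         tuple(int(d) for d in self.depth[i]))

    def records(self) -> Iterator[SnpRecord]:
        return (self.record(i) for i in range(len(self)))

    def subset(self, mask: np.ndarray) -> "SnpTable":
        """New table keeping sites where ``mask`` is True; order preserved."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.nonzero(mask)[0]
        return SnpTable(
            self.samples,
            [self.chroms[i] for i in idx],
            self.pos[idx],
            [self.ref[i] for i in idx],
            [self.alts[i] for i in idx],
            self.geno[idx],
            self.depth[idx],
            {k: v[idx] for k, v in self.info.items()},
            validate=False,
        )

    @classmethod
    def from_records(cls, records: Iterable[SnpRecord],
                     samples: Sequence[str]) -> "SnpTable":
        records = list(records)
        n, s = len(records), len(samples)
        geno = np.full((n, s, 2), -1, dtype=np.int16)
        depth = np.zeros((n, s), dtype=np.int32)
        info_keys = sorted({k for r in records for k in r.info})
        info = {k: np.full(n, np.nan) for k in info_keys}
        for i, r in enumerate(records):
            if len(r.genotypes) != s:
                raise ContractError(
                    f"record {i} has {len(r.genotypes)} genotypes for {s} samples")
            for j, g in enumerate(r.genotypes):
                if g is not None:
                    geno[i, j] = g
            depth[i] = r.depths
            for k, v in r.info.items():
                info[k][i] = v
        return cls(samples, [r.chrom for r in records],
                   np.array([r.pos for r in records], dtype=np.int64),
                   [r.ref for r in records], [r.alts for r in records],
                   geno, depth, info)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpTable):
            return NotImplemented
        if (self.samples != other.samples or self.chroms != other.chroms
                or self.ref != other.ref or self.alts != other.alts
                or not np.array_equal(self.pos, other.pos)
                or not np.array_equal(self.geno, other.geno)
                or not np.array_equal(self.depth, other.depth)
                or set(self.info) != set(other.info)):
            return False
        # INFO floats survive a float32 round-trip through htslib; compare
        # to that precision rather than bit-exactly.
        return all(
            np.allclose(self.info[k], other.info[k], rtol=1e-6, equal_nan=True)
            for k in self.info
        )


# ---------------------------------------------------------------------------
# VCF read/write
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path,
             required_fields: Sequence[str] = DEFAULT_INFO_KEYS) -> SnpTable:
    """Read a multi-sample VCF v4.2 into a :class:`SnpTable`.

    Record order is preserved; multi-allelic records are kept unsplit; INFO
    keys absent at a site are stored as absent (NaN), never as zero.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise ContractError("VCF FORMAT field 'GT' is required but absent")
        samples = list(vf.header.samples)
        records: list[SnpRecord] = []
        for rec in vf:
            info = {}
            for k in required_fields:
                if k in rec.info:
                    v = rec.info[k]
                    info[k] = float(v[0] if isinstance(v, tuple) else v)
            gts, dps = [], []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    gts.append(None)
                else:
                    gts.append((int(gt[0]), int(gt[1])))
                dp = call.get("DP")
                dps.append(int(dp) if dp is not None else 0)
            records.append(SnpRecord(rec.chrom, rec.pos, rec.ref,
                                     tuple(rec.alts or ()), info,
                                     tuple(gts), tuple(dps)))
    return SnpTable.from_records(records, samples)


def write_vcf(table: SnpTable, path: str | Path) -> None:
    """Write a :class:`SnpTable` as uncompressed VCF v4.2 text."""
    info_keys = [k for k in DEFAULT_INFO_KEYS if k in table.info]
    info_keys += [k for k in table.info if k not in info_keys]
    lines = ["##fileformat=VCFv4.2"]
    for c in dict.fromkeys(table.chroms):
        lines.append(f"##contig=<ID={c}>")
    for k in info_keys:
        lines.append(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples))
    for i in range(len(table)):
        info_parts = []
        for k in info_keys:
            v = table.info[k][i]
            if not math.isnan(v):
                info_parts.append(f"{k}={v:.9g}")
        alt = ",".join(table.alts[i]) or "."
        fields = [table.chroms[i], str(int(table.pos[i])), ".", table.ref[i],
                  alt, ".", "PASS", ";".join(info_parts) or ".", "GT:DP"]
        for s in range(table.n_samples):
            a, b = int(table.geno[i, s, 0]), int(table.geno[i, s, 1])
            gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
            fields.append(f"{gt}:{int(table.depth[i, s])}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Haplotype read-count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Per-strain read counts of window haplotypes.

    ``entries[marker_id][haplotype] -> count``; haplotype strings within one
    marker all share the length equal to the marker's SNP count.
    """

    strain: str
    entries: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        for mid, haps in self.entries.items():
            lengths = {len(h) for h in haps}
            if len(lengths) > 1:
                raise FormatError(
                    f"marker {mid}: inconsistent haplotype lengths {sorted(lengths)}")
            for h, c in haps.items():
                if c < 0 or int(c) != c:
                    raise FormatError(f"marker {mid}: count {c!r} for {h} "
                                      "is not a non-negative integer")


_COUNT_COLS = ["strain", "marker_id", "haplotype", "count"]


def read_count_tables(path: str | Path) -> dict[str, CountTable]:
    """Read a TSV of (strain, marker_id, haplotype, count) rows.

    Duplicate (strain, marker, haplotype) rows are summed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "marker_id": str,
                                            "haplotype": str})
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"count table {path} lacks columns {missing}")
    out: dict[str, CountTable] = {}
    grouped = df.groupby(["strain", "marker_id", "haplotype"], sort=False)["count"].sum()
    for (strain, mid, hap), count in grouped.items():
        ct = out.setdefault(strain, CountTable(strain))
        ct.entries.setdefault(mid, {})[hap] = int(count)
    for ct in out.values():
        ct.validate()
    return out


def read_count_table(path: str | Path) -> CountTable:
    """Read a single-strain count table (errors if several strains present)."""
    tables = read_count_tables(path)
    if len(tables) != 1:
        raise FormatError(
            f"expected one strain in {path}, found {sorted(tables)}")
    return next(iter(tables.values()))


def write_count_table(counts: CountTable | Iterable[CountTable],
                      path: str | Path) -> None:
    tables = [counts] if isinstance(counts, CountTable) else list(counts)
    rows = [(t.strain, mid, hap, c)
            for t in tables
            for mid, haps in sorted(t.entries.items())
            for hap, c in sorted(haps.items())]
    pd.DataFrame(rows, columns=_COUNT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

def write_marker_table(markers, path: str | Path) -> None:
    """TSV with columns marker_id, chrom, start, end, n_snps, snp_positions, pic."""
    rows = []
    for m in markers:
        rows.append((m.marker_id, m.chrom, m.start, m.end, len(m.snp_positions),
                     ",".join(str(p) for p in m.snp_positions), f"{m.pic:.6g}"))
    pd.DataFrame(rows, columns=["marker_id", "chrom", "start", "end", "n_snps",
                                "snp_positions", "pic"]).to_csv(
        path, sep="\t", index=False)


def read_marker_table(path: str | Path):
    from .mnp_discovery import MnpMarker

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_positions": str})
    markers = []
    for row in df.itertuples(index=False):
        positions = tuple(int(p) for p in str(row.snp_positions).split(","))
        markers.append(MnpMarker(marker_id=str(row.marker_id), chrom=row.chrom,
                                 start=int(row.start), end=int(row.end),
                                 snp_positions=positions, pic=float(row.pic),
                                 allele_words={}))
    return markers


# ---------------------------------------------------------------------------
# Genotype profiles (TSV; read-count support is carried in the database,
# not in this exchange format)
# ---------------------------------------------------------------------------

def write_profile(profile, path: str | Path) -> None:
    rows = []
    for mid, g in profile.calls.items():
        haps = "MISSING" if g.haplotypes is None else ",".join(sorted(g.haplotypes))
        rows.append((profile.strain, mid, haps, g.total_reads))
    pd.DataFrame(rows, columns=["strain", "marker_id", "haplotypes",
                                "total_reads"]).to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path):
    from .mnp_genotyping import MnpGenotype, MnpProfile

    df = pd.read_csv(path, sep="\t", dtype=str)
    strains = df["strain"].unique()
    if len(strains) != 1:
        raise FormatError(f"profile {path} must hold one strain, found {list(strains)}")
    calls = {}
    for row in df.itertuples(index=False):
        haps = None if row.haplotypes == "MISSING" \
            else frozenset(row.haplotypes.split(","))
        calls[row.marker_id] = MnpGenotype(marker_id=row.marker_id,
                                           haplotypes=haps, support={},
                                           total_reads=int(row.total_reads))
    return MnpProfile(strain=str(strains[0]), calls=calls)


# ---------------------------------------------------------------------------
# Marker database (versioned JSON container)
# ---------------------------------------------------------------------------

def save_database(db, path: str | Path) -> None:
    """Serialise a :class:`~mnpkit.mnp_genotyping.MarkerDatabase`.

    The container is schema-tagged JSON: portable across platforms and
    versionable, unlike a language-native binary dump.
    """
    doc = {
        "schema": DB_SCHEMA,
        "meta": dict(db.meta),
        "markers": [
            {"marker_id": m.marker_id, "chrom": m.chrom, "start": m.start,
             "end": m.end, "snp_positions": list(m.snp_positions),
             "pic": m.pic, "allele_words": dict(m.allele_words)}
            for m in db.markers
        ],
        "profiles": {
            strain: {
                mid: {
                    "haplotypes": (sorted(g.haplotypes)
                                   if g.haplotypes is not None else None),
                    "support": dict(g.support),
                    "total_reads": g.total_reads,
                }
                for mid, g in profile.calls.items()
            }
            for strain, profile in db.profiles.items()
        },
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_database(path: str | Path):
    from .mnp_discovery import MnpMarker
    from .mnp_genotyping import MarkerDatabase, MnpGenotype, MnpProfile

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path} is not a valid database file: {exc}") from exc
    if not isinstance(doc, dict) or "schema" not in doc:
        raise FormatError(f"{path} carries no database schema tag")
    if doc["schema"] != DB_SCHEMA:
        raise DatabaseVersionError(
            f"{path}: schema {doc['schema']!r} unsupported (expected {DB_SCHEMA!r})")
    markers = [
        MnpMarker(marker_id=m["marker_id"], chrom=m["chrom"], start=m["start"],
                  end=m["end"], snp_positions=tuple(m["snp_positions"]),
                  pic=m["pic"], allele_words=dict(m["allele_words"]))
        for m in doc["markers"]
    ]
    profiles = {}
    for strain, calls in doc["profiles"].items():
        parsed = {}
        for mid, g in calls.items():
            haps = frozenset(g["haplotypes"]) if g["haplotypes"] is not None else None
            parsed[mid] = MnpGenotype(marker_id=mid, haplotypes=haps,
                                      support={k: int(v) for k, v in g["support"].items()},
                                      total_reads=int(g["total_reads"]))
        profiles[strain] = MnpProfile(strain=strain, calls=parsed)
    return MarkerDatabase(markers=markers, profiles=profiles,
                          meta=dict(doc["meta"]))


# ---------------------------------------------------------------------------
# Trees and matrices
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a clustering tree (or a ready Newick string) to ``path``."""
    text = tree if isinstance(tree, str) else tree.to_newick()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def write_matrix(matrix, path: str | Path) -> None:
    """Write a labelled square matrix (GsMatrix, BandMatrix or DataFrame) as TSV."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    elif hasattr(matrix, "to_frame"):
        df = matrix.to_frame()
    else:
        raise ContractError(f"cannot serialise {type(matrix).__name__} as a matrix")
    df.to_csv(path, sep="\t", index=True, index_label="strain")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
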