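"""SNP/InDel quality control.

Implements the GATK-style hard-filter expressions, the population-level
MAF / missing-rate / site-depth cascade, the per-sample polymorphic-SNP
screen that precedes marker discovery, and the per-chromosome variant
density summary (bases per variant).

All comparators are strict exactly as printed in the filter expressions:
a site sitting exactly on a bound (e.g. QD == 2.0) is retained by the hard
filters, and site depth must satisfy 10 < depth < 2000 with both bounds
exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .formats_io import SnpTable


@dataclass(frozen=True)
class QcThresholds:
    """Filtering thresholds; defaults are the published values."""

    snp_qd_min: float = 2.0
    snp_fs_max: float = 60.0
    snp_mq_min: float = 40.0
    snp_sor_max: float = 3.0
    snp_mqranksum_min: float = -12.5
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_sor_max: float = 10.0
    maf_min: float = 0.05
    missing_max: float = 0.20
    site_depth_low: int = 10        # exclusive
    site_depth_high: int = 2000     # exclusive
    per_sample_depth_min: int = 10  # exclusive (polymorphic screen)
    identical_genotype_max_frac: float = 0.95

    def __post_init__(self):
        if not 0 < self.maf_min < 0.5:
            raise ContractError(f"maf_min {self.maf_min} outside (0, 0.5)")
        if not 0 < self.missing_max < 1:
            raise ContractError(f"missing_max {self.missing_max} outside (0, 1)")


DEFAULT_THRESHOLDS = QcThresholds()

# (info key, threshold attribute, fail direction) per variant kind; a record
# fails when metric < min or metric > max, i.e. bounds themselves pass.
_HARD_FILTERS = {
    "snp": (("QD", "snp_qd_min", "lt"), ("FS", "snp_fs_max", "gt"),
            ("MQ", "snp_mq_min", "lt"), ("SOR", "snp_sor_max", "gt"),
            ("MQRankSum", "snp_mqranksum_min", "lt")),
    "indel": (("QD", "indel_qd_min", "lt"), ("FS", "indel_fs_max", "gt"),
              ("SOR", "indel_sor_max", "gt")),
}


def apply_hard_filters(table: SnpTable, kind: str = "snp",
                       thresholds: QcThresholds = DEFAULT_THRESHOLDS) -> SnpTable:
    """Remove records failing any hard-filter inequality for ``kind``.

    Absent metrics never trigger removal; output order is preserved.
    """
    kind = kind.lower()
    if kind not in _HARD_FILTERS:
        raise ContractError(f"unknown variant kind {kind!r} (use 'snp' or 'indel')")
    fail = np.zeros(len(table), dtype=bool)
    for key, attr, direction in _HARD_FILTERS[kind]:
        if key not in table.info:
            continue
        vals = table.info[key]
        bound = getattr(thresholds, attr)
        with np.errstate(invalid="ignore"):
            # NaN (absent metric) compares False, so it never triggers removal
            bad = (vals < bound) if direction == "lt" else (vals > bound)
        fail |= bad
    return table.subset(~fail)


def _allele_stats(table: SnpTable):
    """Per-site (missing fraction, minor allele frequency over non-missing calls)."""
    n = len(table)
    called = table.geno[:, :, 0] >= 0                     # (n, s)
    n_called = called.sum(axis=1)
    missing_rate = 1.0 - n_called / table.n_samples
    if n == 0:
        return missing_rate, np.zeros(0)
    # per-site allele counts via one flat bincount (rows offset by allele range)
    flat = table.geno.reshape(n, -1).astype(np.int64)
    mask = flat >= 0
    n_alleles = int(flat.max(initial=0)) + 1
    rows = np.nonzero(mask)
    keys = rows[0] * n_alleles + flat[mask]
    counts = np.bincount(keys, minlength=n * n_alleles).reshape(n, n_alleles)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, 1.0 - counts.max(axis=1) / np.maximum(total, 1), 0.0)
    return missing_rate, maf


def filter_maf_missing(table: SnpTable,
                       thresholds: QcThresholds = DEFAULT_THRESHOLDS) -> SnpTable:
    """Remove sites with MAF < ``maf_min`` or missing rate > ``missing_max``.

    MAF is computed from non-missing diploid calls only (allele count over
    2 x non-missing samples). A site where every call is missing falls under
    the missing-rate rule.
    """
    missing_rate, maf = _allele_stats(table)
    keep = (maf >= thresholds.maf_min) & (missing_rate <= thresholds.missing_max)
    return table.subset(keep)


def filter_maf(table: SnpTable,
               thresholds: QcThresholds = DEFAULT_THRESHOLDS) -> SnpTable:
    missing_rate, maf = _allele_stats(table)
    # an all-missing site has no defined MAF; leave it to the missing-rate rule
    return table.subset((maf >= thresholds.maf_min) | (missing_rate >= 1.0))


def filter_missing(table: SnpTable,
                   thresholds: QcThresholds = DEFAULT_THRESHOLDS) -> SnpTable:
    missing_rate, _ = _allele_stats(table)
    return table.subset(missing_rate <= thresholds.missing_max)


def filter_site_depth(table: SnpTable,
                      thresholds: QcThresholds = DEFAULT_THRESHOLDS) -> SnpTable:
    """Retain sites with summed per-sample DP strictly inside (low, high)."""
    site_depth = table.depth.sum(axis=1)
    keep = (site_depth > thresholds.site_depth_low) & \
           (site_depth < thresholds.site_depth_high)
    return table.subset(keep)


def polymorphic_screen(table: SnpTable,
                       thresholds: QcThresholds = DEFAULT_THRESHOLDS) -> SnpTable:
    """Screen for polymorphic SNPs usable as marker components.

    A site is retained iff (1) every sample's depth exceeds
    ``per_sample_depth_min`` (strict), (2) no genotype is missing, and
    (3) the most frequent genotype is carried by at most
    ``identical_genotype_max_frac`` of the samples.
    """
    if table.n_samples < 2:
        raise ContractError("polymorphic screen needs at least 2 samples")
    depth_ok = (table.depth > thresholds.per_sample_depth_min).all(axis=1)
    called = (table.geno[:, :, 0] >= 0).all(axis=1)
    keep = depth_ok & called
    if keep.any():
        # modal genotype fraction, treating (a,b)/(b,a) as the same unphased
        # call; vectorised as the longest run in row-sorted genotype codes
        s = table.n_samples
        lo = np.minimum(table.geno[:, :, 0], table.geno[:, :, 1]).astype(np.int64)
        hi = np.maximum(table.geno[:, :, 0], table.geno[:, :, 1]).astype(np.int64)
        code = np.sort(lo * 1024 + hi, axis=1)
        starts = np.concatenate(
            [np.ones((len(code), 1), bool), code[:, 1:] != code[:, :-1]], axis=1)
        run_id = np.cumsum(starts, axis=1) - 1               # 0..s-1 per row
        keys = (np.arange(len(code))[:, None] * s + run_id).ravel()
        run_len = np.bincount(keys, minlength=len(code) * s).reshape(len(code), s)
        modal_frac = run_len.max(axis=1) / s
        keep &= modal_frac <= thresholds.identical_genotype_max_frac
    return table.subset(keep)


def cascade(table: SnpTable, kind: str = "snp",
            thresholds: QcThresholds = DEFAULT_THRESHOLDS,
            order: tuple[str, ...] = ("hard", "maf", "missing", "site_depth"),
            ) -> tuple[SnpTable, list[tuple[str, int]]]:
    """Run the QC cascade and return (filtered table, per-step report).

    The report lists (step name, surviving record count) beginning with the
    input count, mirroring a published filter-cascade table. Default order:
    hard filters, MAF, missing rate, site depth.
    """
    steps = {
        "hard": lambda t: apply_hard_filters(t, kind, thresholds),
        "maf": lambda t: filter_maf(t, thresholds),
        "missing": lambda t: filter_missing(t, thresholds),
        "maf_missing": lambda t: filter_maf_missing(t, thresholds),
        "site_depth": lambda t: filter_site_depth(t, thresholds),
        "polymorphic": lambda t: polymorphic_screen(t, thresholds),
    }
    report = [("input", len(table))]
    for name in order:
        if name not in steps:
            raise ContractError(f"unknown cascade step {name!r}")
        table = steps[name](table)
        report.append((name, len(table)))
    return table, report


def variant_density(chrom_length: int, n_variants: int) -> int:
    """Bases per variant: ``floor(chrom_length / n_variants)``."""
    if n_variants <= 0:
        raise ContractError("variant density undefined for n_variants == 0")
    if chrom_length <= 0:
        raise ContractError("chromosome length must be positive")
    return chrom_length // n_variants
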