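import numpy as np
import pytest

from mnpkit import MnpGenotype, MnpProfile, SimConfig, SnpRecord, SnpTable


def make_snp_table(genotypes, positions=None, chrom="chr1", samples=None,
                   depths=None, info=None):
    """Build a SnpTable from a list of per-site genotype lists.

    ``genotypes[i][j]`` is sample j's (a, b) pair or None at site i.
    """
    n = len(genotypes)
    s = len(genotypes[0])
    positions = positions or [100 * (i + 1) for i in range(n)]
    samples = samples or [f"s{j + 1}" for j in range(s)]
    records = []
    for i in range(n):
        rec_info = info[i] if info else {}
        dp = depths[i] if depths else [50] * s
        records.append(SnpRecord(chrom=chrom, pos=positions[i], ref="A",
                                 alts=("C",), info=rec_info,
                                 genotypes=tuple(genotypes[i]),
                                 depths=tuple(dp)))
    return SnpTable.from_records(records, samples)


def make_profile(strain, calls):
    """Profile from {marker_id: iterable-of-haplotypes or None}."""
    parsed = {}
    for mid, haps in calls.items():
        hs = None if haps is None else frozenset(haps)
        parsed[mid] = MnpGenotype(marker_id=mid, haplotypes=hs,
                                  total_reads=0 if haps is None else 50)
    return MnpProfile(strain=strain, calls=parsed)


def make_matched_profiles(n_match, n_total, name_a="a", name_b="b"):
    """Two profiles over n_total markers agreeing at exactly n_match."""
    ids = [f"m{i:04d}" for i in range(n_total)]
    a = {mid: ["ACG"] for mid in ids}
    b = {mid: (["ACG"] if i < n_match else ["TCG"]) for i, mid in enumerate(ids)}
    return make_profile(name_a, a), make_profile(name_b, b)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated population reused across read-only tests."""
    from mnpkit import simulate_population

    cfg = SimConfig(chrom_lengths={"c1": 250_000, "c2": 250_000},
                    group_sizes={"white": 5, "gray": 7}, snp_density=0.02,
                    n_hybrid_trios=1, seed=42)
    truth, table = simulate_population(cfg)
    return cfg, truth, table


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=QD,Number=1,Type=Float,Description="qd">
##INFO=<ID=FS,Number=1,Type=Float,Description="fs">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t100\t.\tA\tC\t.\tPASS\tQD=20;FS=1.5\tGT:DP\t0/1:33
chr1\t250\t.\tG\tT,A\t.\tPASS\tQD=3.5\tGT:DP\t1/2:28
chr1\t400\t.\tT\tG\t.\tPASS\tFS=0.5\tGT:DP\t./.:0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path
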