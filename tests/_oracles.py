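"""Naive reference implementations used as independent oracles.

Everything here is deliberately brute force: windows are found by scanning
the full position list for every anchor, genotype words are built through
the public string encoding one record at a time, PIC comes from a Counter,
and spacing selection is a plain loop. No bisect, no numpy code paths
shared with the package implementation.

Enumerating every base-anchored window reduces to enumerating windows that
start on a SNP: a window whose leftmost SNP is p has a SNP set contained in
the set of [p, p+99], and under dedup-keep-leftmost with starts
canonicalised to the first SNP only those survive.
"""

from collections import Counter

from mnpkit import genotype_word


def oracle_discover(table, window=100, min_snps=2, max_snps=10,
                    pic_min=0.5, spacing_bp=50_000):
    """Return [(chrom, start, snp_positions, pic)] of selected markers."""
    by_chrom = {}
    for i in range(len(table)):
        by_chrom.setdefault(table.chroms[i], []).append(i)

    candidates = []
    for chrom, idx in by_chrom.items():
        positions = [int(table.pos[i]) for i in idx]
        for anchor in positions:
            members = [i for i, p in zip(idx, positions)
                       if anchor <= p <= anchor + window - 1]
            if not (min_snps <= len(members) <= max_snps):
                continue
            words = []
            for s in range(table.n_samples):
                gts = [table.record(i).genotypes[s] for i in members]
                words.append(genotype_word(gts))
            freqs = Counter(words)
            pic = 1.0 - sum((c / table.n_samples) ** 2 for c in freqs.values())
            candidates.append((chrom, anchor,
                               tuple(int(table.pos[i]) for i in members), pic))

    selected = []
    last_start = {}
    for chrom, start, snps, pic in sorted(candidates, key=lambda c: (c[0], c[1])):
        if pic < pic_min:
            continue
        if chrom in last_start and start - last_start[chrom] <= spacing_bp:
            continue
        last_start[chrom] = start
        selected.append((chrom, start, snps, pic))
    return selected
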