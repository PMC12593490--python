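# Methods

## The identification problem

Commercial strains of dikaryotic fungi are propagated asexually, mutate
slowly, and are frequently renamed. Deciding whether two isolates are the
same variety therefore reduces to measuring genotype identity at a panel of
highly informative loci. `mnpkit` builds that panel (MNP markers: 100-bp
windows holding 2–10 SNPs), genotypes strains at it from read counts, and
scores pairs with a similarity percentage. Every stage is exercised against
a simulator with known ground truth.

## Quality control

A site enters marker discovery only after three layers of filtering, with
every comparator strict exactly as written:

| layer | rule | default |
|---|---|---|
| hard filters (SNP) | remove iff QD < 2.0 ∨ FS > 60.0 ∨ MQ < 40.0 ∨ SOR > 3.0 ∨ MQRankSum < −12.5 | boundary values retained |
| hard filters (InDel) | remove iff QD < 2.0 ∨ FS > 200.0 ∨ SOR > 10.0 | |
| population cascade | MAF ≥ 0.05 over non-missing calls; missing rate ≤ 0.2; 10 < Σ DP < 2000 | |
| polymorphic screen | every sample DP > 10; no missing call; modal genotype ≤ 95 % of samples | |

Interpretation choices the filters' source text leaves open: *site depth* is
the sum of per-sample DP (the only reading under which a 10–2000 range is
plausible for tens of samples); MAF uses non-missing calls only; an absent
INFO metric never triggers removal; "samples with identical genotypes not
exceeding 95 %" is read as the modal-genotype frequency. All of these are
documented in the code and boundary-tested. The cascade order is
configurable; the default applies hard filters, then MAF, missing rate and
site depth, and each step is idempotent and non-increasing in record count.

`variant_density` is floor division (bases per variant); rounding instead
of flooring fails on known chromosome summaries, which the tests pin down.

## Window scan and PIC

The scan anchors one window [p, p + 99] at every SNP position p. A window
anchored anywhere else is redundant: its SNP set is contained in the set of
the window anchored at its own leftmost SNP, so SNP-anchoring enumerates
every maximal SNP cluster with no step-size parameter. A brute-force oracle
(naive O(n²) scans, string genotype words, Counter-based PIC, independent
greedy loop) is kept in the test suite and the selection is asserted equal
to it over 100 random instances.

Genotype words are unphased: per SNP a sample contributes `R`, the
homozygous alternate digit, or the sorted heterozygous pair, joined with
`|`. Dikaryon heterozygosity makes phase unknowable from a VCF, so PIC is
computed on word frequencies across samples. The default statistic is gene
diversity, PIC = 1 − Σᵢ pᵢ²; the Botstein variant
(1 − Σpᵢ² − Σᵢ Σⱼ>ᵢ 2pᵢ²pⱼ²) is available as `pic_mode="botstein"`.

Selection keeps windows with PIC ≥ 0.5 (inclusive) and then walks each
chromosome left to right, accepting a window iff its start exceeds the last
accepted start by more than 50,000 bp. Spacing is measured start-to-start;
a PIC-ranked alternative (`rank_by_pic=True`) exists but is off by default
because position-greedy selection is order-stable and reproducible.

## Genotype calling

With counts c(h) of window haplotypes and T = Σ c(h): if T < 10 the marker
is MISSING; otherwise haplotypes with c(h)/T ≥ 0.1 are retained (the bound
is inclusive and tested at exactly 0.1). More than two passing haplotypes
contradicts dikaryon biology and indicates error or contamination: the top
two by count survive (lexicographic tie-break) and the event is logged. The
fraction is per-haplotype, not a minor/major ratio — the configurable
`het_threshold` makes the alternative reading available.

The floor of 10 reads per window mirrors the per-sample depth screen; below
it a call would rest on fewer observations than the site filters themselves
require.

## Genetic similarity and classification

GS(%) = n/N × 100, rounded half-away-from-zero to two decimals. Matching is
exact haplotype-set equality; a het/hom pair sharing one haplotype is a
non-match. By default N is the full database marker count and a MISSING
call in either strain counts as a non-match (`mode="total"`); with real
dropout `mode="shared"` restricts N to markers called in both strains. The
rounding convention is regression-tested by inverting all reference GS
values to integer match counts at N = 369.

Pairs with GS ≥ 99 % are classified as the same (or highly similar)
variety; the threshold is inclusive and deliberately strict because
asexually propagated crops accumulate almost no variation. Clustering uses
d = 1 − GS/100 with average linkage (UPGMA) by default; the linkage method
is a flag, so dendrogram topology is a qualitative, not bit-exact, output.
Newick export places a merge at distance d at height d/2 (ultrametric
convention).

## Depth titration

Downsampling is binomial thinning: each read survives with probability
target/full, independently per haplotype count. Against the full-depth
profile, a marker is *discordant* if both calls exist and differ, and
*newly missing* if it drops below the read floor. Below ~15× the missing
category dominates and masks discordance (a marker that is MISSING cannot
disagree), so monotonicity in depth holds for the total deviation
(discordant + newly missing) across all depths and for discordance alone
once dropout is negligible (≥ 25× of a 60× library). At ≥ 40×, error-free
thinning leaves zero discordant loci in ≥ 99 % of replicates — the
criterion by which 40× is judged a sufficient sequencing depth.

## ISSR comparator

The band matrix is taken as scored (band identity across gels is a wet-lab
problem, out of algorithmic scope; bands present in > 95 % or < 5 % of
strains are flagged as uninformative). Jaccard distance
d = 1 − |a∧b|/|a∨b| treats double absence as no information; two all-zero
vectors get d = 0 by logged convention. The per-primer summary counts
polymorphic bands (present in some but not all strains) and their mean per
primer. The implementation is cross-checked against
`scipy.spatial.distance.pdist(..., "jaccard")` in the tests.

## Simulator

What it emulates: two subpopulations with Balding–Nichols allele-frequency
divergence (`fst`, default 0.25) around ancestral frequencies uniform on
[0.1, 0.9]; Poisson-placed biallelic SNPs (`snp_density`, default 1/100 bp
on the 12 published chromosome lengths, ≈ 420 k sites); dikaryotic strains
as two haploid nuclei (second nucleus independent with probability
`het_rate` = 0.5, else copied); one F1 trio whose children inherit one
whole nucleus per 100-bp block, so window haplotypes segregate as units;
clonal duplicates; read counts Poisson in depth (default 60×), split 50/50
for heterozygotes, with per-base errors (default 0.1 %) diverting whole
reads to off-target words at rate 1 − (1 − e)^k.

Engineered sharing: a pair listed in `marker_sharing_targets` with fraction
f has genotypes copied at exactly round(f·M) of the M discovered markers;
at the remainder a chance collision is minimally mutated away, so the
pair's GS is exactly round(100·round(f·M)/M, 2) and recovery tests have a
closed-form expectation.

What it does not emulate: alignment and mapping bias, indels, base-quality
structure, linked selection, recombination maps, contamination. Passing
recovery tests bound behaviour on ideal data; they do not certify
performance on real libraries.

Problem sizes: unit tests run on 0.1–0.5 Mb genomes; the end-to-end
recovery check uses 18 × 3.5 Mb chromosomes at 1 SNP/70 bp, which yields
≥ 1000 markers — a genome larger than the 42 Mb reference because > 50 kb
spacing caps the marker yield at roughly genome-length/50 kb. The
depth-titration checks use 1000 synthetic three-SNP markers at 60× full
depth.

## Numerical and degenerate-input choices

- GS rounding is half-away-from-zero (`floor(100x + 0.5)/100`), matching
  the printed two-decimal convention under inversion.
- A zero-read or empty count map is MISSING, never an error; a negative
  count is a contract violation.
- An all-missing site has undefined MAF and is removed by the missing-rate
  rule, not the MAF rule.
- Marker ids are `mnp_0001…` in (chromosome, start) order; identical input
  always yields identical ids and order.
- The database is schema-tagged JSON (`mnpkit.db/1`); loading any other
  version raises a versioned error rather than guessing.
- VCF INFO floats survive the float32 round-trip of htslib; table equality
  compares them at that precision and everything else exactly.

## Known limitations

- Haplotype counts must come from reads spanning all of a window's SNPs;
  extracting them from BAMs (with MAPQ/BAQ handling) is an adapter contract
  outside this package.
- Heterozygote matching is all-or-nothing; a partial-overlap mode is not
  scored by default.
- Reference marker counts and filter-cascade totals from the original
  79-strain dataset are not reproducible without that data; the test suite
  substitutes property-based checks with simulated truth.
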