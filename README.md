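# mnpkit

Multiple-nucleotide-polymorphism (MNP) marker discovery, genotyping and
genetic-similarity fingerprinting for fungal variety identification.

Edible fungi such as *Hypsizygus marmoreus* are propagated clonally, and the
same commercial strain often circulates under several names. `mnpkit`
implements an identification pipeline that resolves this from resequencing
data: it screens a multi-strain SNP callset, finds short genomic windows
dense in polymorphism, genotypes each strain at those windows from read
counts, and quantifies how similar any two strains are.

## Method

1. **SNP quality control** (`snp_qc`). GATK-style hard filters (SNPs:
   QD < 2.0, FS > 60.0, MQ < 40.0, SOR > 3.0, MQRankSum < −12.5; InDels:
   QD < 2.0, FS > 200.0, SOR > 10.0; sites on a bound are kept), then a
   population cascade: MAF ≥ 0.05, missing rate ≤ 0.2, summed site depth
   strictly inside (10, 2000). A polymorphic screen keeps sites where every
   sample has depth > 10, no call is missing, and the modal genotype covers
   ≤ 95 % of samples. `variant_density(L, n) = ⌊L / n⌋` summarises variants
   per chromosome as bases-per-variant.
2. **Marker discovery** (`mnp_discovery`). 100-bp windows anchored at each
   SNP; windows with 2–10 SNPs are scored by the polymorphism information
   content of their multi-SNP genotype words across strains
   (PIC = 1 − Σᵢ pᵢ²); markers require PIC ≥ 0.5 and > 50 kb spacing
   (greedy, left-to-right).
3. **Genotyping** (`mnp_genotyping`). A strain's genotype at a marker is the
   set of window haplotypes with read fraction ≥ 0.1 (at most two — the
   dikaryotic mycelium carries two nuclei); markers with < 10 spanning reads
   are MISSING. Profiles live in a versioned, portable database.
4. **Similarity** (`similarity`). GS(%) = n/N × 100 with n the markers where
   two strains carry identical haplotype sets and N the database marker
   count; GS ≥ 99 % ⇒ same variety, GS < 99 % ⇒ distinct. UPGMA clustering
   of d = 1 − GS/100 gives the strain dendrogram.
5. **Depth titration** (`depth_titration`). Binomial thinning of read counts
   to target coverages quantifies when genotype calls stabilise (≈ 40×).
6. **ISSR comparator** (`issr`). The classical fingerprint: a binary band
   matrix → Jaccard distances → agglomerative tree.
7. **Simulation** (`simulate`). Synthetic populations with known truth —
   subpopulations, F1 hybrid trios, clones, engineered pairwise sharing
   fractions — drive every test without external data.

## Worked example

```python
import mnpkit as mk

cfg = mk.SimConfig(
    chrom_lengths={"c1": 400_000, "c2": 400_000},
    group_sizes={"white": 5, "gray": 7},
    snp_density=0.02, n_hybrid_trios=1,
    clone_pairs=(("white_01", "white_02"),),
    seed=7,
)
truth, callset = mk.simulate_population(cfg)
screened = mk.polymorphic_screen(callset)
markers = mk.discover(screened)
print(f"{len(callset)} SNPs -> {len(screened)} polymorphic -> {len(markers)} MNP markers")
print(f"PIC range {min(m.pic for m in markers):.2f}-{max(m.pic for m in markers):.2f}")

mk.assign_marker_truth(truth, markers, seed=cfg.seed)
counts = mk.simulate_counts(truth, markers, depth=60, error_rate=0.001, seed=cfg.seed)
profiles = [mk.genotype_strain(counts[s], markers) for s in truth.strains]
db = mk.build_database(markers, profiles, meta={"tool": "mnpkit 0.1.0"})

matrix = mk.gs_matrix(db)
clone = matrix.get("white_01", "white_02")
sibs = matrix.get("gray_05", "gray_06")   # F1 siblings of gray_01 x gray_02
print(f"clone pair GS = {clone.gs:.2f}% ({clone.n}/{clone.N}) -> {mk.classify_pair(clone.gs)}")
print(f"F1 sibling GS = {sibs.gs:.2f}% ({sibs.n}/{sibs.N}) -> {mk.classify_pair(sibs.gs)}")
```

prints

```
16144 SNPs -> 13838 polymorphic -> 16 MNP markers
PIC range 0.58-0.89
clone pair GS = 100.00% (16/16) -> identical
F1 sibling GS = 56.25% (9/16) -> distinct
```

The clonal duplicate matches at every marker and classifies as the same
variety; the F1 siblings, despite sharing both parents, agree at only 9 of
16 markers and are correctly called distinct. At the reference scale
(~42 Mb genome, hundreds of markers) the same quantities are resolved to
two decimals.

The same pipeline is scriptable from a shell:

```sh
mnpkit simulate --config sim.yaml --outdir sim/
mnpkit run-all --vcf sim/sim.vcf --counts-dir sim/counts --outdir out/
mnpkit cluster --matrix out/gs_matrix.tsv --newick out/tree.nwk
```

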