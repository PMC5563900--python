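# Methods

## Coordinate conventions

All intervals are 1-based and closed. Transcript space (spliced mRNA,
position 1 at the 5′ end) is the primary analysis space; genomic
alignments are projected through exon blocks (`TranscriptModel.
genomic_to_transcript` / `transcript_to_genomic`). On the minus strand
the 5′-most exon is the genomically rightmost one; the projection is
strand-symmetric, and a property test asserts that reflecting a gene's
genomic coordinates and flipping its strand leaves the transcript-space
regions unchanged.

A transcript partitions into 5′UTR / CDS / 3′UTR; the CDS interval
includes the stop codon as annotated, with no trimming. A CDS length
that is not a multiple of 3 is flagged (`cds_frame_ok`) but not treated
as an error, since real annotations contain ragged CDS ends.

## Canonical isoforms

Translation-level metrics are computed on one canonical isoform per
gene: the transcript with the longest CDS. Ties break to the longest
transcript and then the lexicographically smallest transcript id, making
the choice deterministic and order-independent. Genes with no annotated
CDS on any isoform are dropped from footprint analyses (the 5′ loading
ratio and TE are CDS-defined) but still appear in mRNA-level counting.

## Counting and normalisation

A read is assigned to the region containing its **5′-end base**, so
boundary-spanning reads are attributed unambiguously and the rule is
consistent with footprint conventions (the biological signal of an RPF
is anchored at its 5′ end). Reads whose span leaves the transcript are
rejected and tallied. Reads mapping to transcripts of more than one gene
(possible with genomic SAM input) are discarded as ambiguous and logged.

The per-library normalisation factor is the total of reads assigned to
genes in that sample and assay. RPKM = count / (length/1000) /
(mapped/10⁶); region density = count / region length / library size ×
10⁹, which puts densities on the RPKM scale. Zero-length regions are
excluded rather than given a density. Replicate correlations are Pearson
r on log2(RPKM + 0.01); the pseudocount keeps zero-count genes finite
without dominating the dynamic range of typical RPKM values (~0.1–1000).

## A-site assignment and 5′ loading ratios

Offsets by footprint length: 25–28 nt → +14, 29–30 → +15, 31–33 → +16,
34–35 → +17; other lengths are excluded. The offset is interpreted as a
0-based displacement added to the 1-based 5′-end position (a 28-nt read
starting at p has its A-site at p + 14). A-sites falling outside the CDS
are dropped and tallied, so profile mass plus drops equals the number of
length-retained reads (a conservation property test).

The 5′ loading ratio uses the numerator window CDS bases 16–195
(codons 6–65, 180 nt): 5′LR = (n_w/180) / (n_d/(cds_len − 195)).
Eligibility guards (configurable, `LoadingRatioConfig`): CDS ≥ 300 nt,
≥ 10 A-site counts in the windowed CDS, ≥ 1 downstream count. The
guards exist because the ratio is unstable when the denominator count is
near zero; 300 nt guarantees a meaningful downstream stretch (≥ 105 nt).

Replicates are **pooled** (counts summed) per condition before the ratio
is formed. This matches the density-based definition of the ratio and
avoids zero cells in sparse genes; the alternative (per-replicate ratios
then averaging) weights low-coverage replicates equally and is noisier.

r5′LR = 5′LR(stress) / 5′LR(control), defined only when both conditions
pass the guards.

## Translation efficiency and differential calling

TE = RPF RPKM / mRNA RPKM per condition on replicate-averaged RPKMs; TE
is undefined (gene excluded) when the mRNA RPKM is 0. Fold changes use a
pseudocount of 0.01 RPKM before log2. Because RPF and mRNA fold changes
are computed from the same RPKMs, log2FC(TE) = log2FC(RPF) −
log2FC(mRNA) holds to numerical precision, and a test asserts the
identity at 1e-9 across a 2000-gene synthetic run.

DEG (mRNA level) and DTG (RPF level): |log2FC| ≥ 1 **and** mean
log2(RPKM) of the two conditions ≥ 3.3, both inclusive. DTE: fold change
strictly > 2 and mean RPKM strictly > 5 on the linear scale. The
different scales and strictness of the two abundance guards are kept as
stated; both are configurable (`Thresholds`). Calls are deterministic
threshold functions, so no multiple-testing correction applies.

## Stratified statistics

The Wilcoxon rank-sum test is implemented directly. For pooled
n ≤ 14 the p-value enumerates the permutation null exactly via a
dynamic program over the doubled-midrank multiset — doubling makes
midranks integral, so ties are handled without approximation. The
two-sided exact p is P(|W − E W| ≥ |w_obs − E W|) under the null
("as extreme as observed" counting). For larger samples the normal
approximation with tie-corrected variance and a 0.5 continuity
correction is used; two identical constant samples give p = 1. The test
suite checks the exact path against naive `itertools` enumeration
(ties included) and the asymptotic path against an independent
implementation.

Element comparisons split genes into with/without groups on a
per-element basis; the default alternative is two-sided, with
directional claims read off the group medians. Profile clustering is
k-means (k = 5 by default, seed required) on per-gene z-scored log2FC
profiles; genes with flat profiles z-score to the zero vector. Cluster
enrichment is the upper-tail hypergeometric test P(X ≥ k); the universe
defaults to the genes that entered clustering (i.e., genes passing
abundance filters), not all annotated genes.

## Synthetic data generator

The generator emulates a two-assay stress time course: conditions 0h
(control), 1h, 2h, 4h with 2 replicates each. Defaults (chosen once as
the study conditions the package targets):

| parameter | default | meaning |
|---|---|---|
| n_genes | 500 | genes, each with one coding transcript |
| utr5 / cds / utr3 | U(100,300) / U(300,3000)·3∤ / U(200,800) nt | region lengths |
| p_uorf / p_ires / p_5top | 0.35 / 0.10 / 0.05 | element prevalence, approximating human 5′UTR annotation |
| abundance | LogNormal(0, 1) | relative expression weight |
| baseline TE | LogNormal(0, 0.35) | per-gene translation efficiency |
| te_fc_uorf | 2.0 | TE multiplier for uORF genes at 1h/2h |
| ramp_rho | 1.2 | A-site density multiplier on CDS bases 16–195 at 1h/2h |
| dispersion | 20 | NB size; Fano ≈ 1 + mean/20 |
| library sizes | 10⁶ reads/library | per assay |
| RPF lengths | 25–35 nt, mode 29 | 85% of reads in 28–32 nt |
| mRNA reads | 50 nt, uniform 5′ ends | |

Gene totals are NB(mean = library share, size = dispersion); RPF reads
are placed by drawing an A-site position (density ρ on bases 16–195 for
affected genes under affected conditions, uniform otherwise) and backing
out the 5′ end through the length-dependent offset, so the simulator and
the analysis share no code path for A-site arithmetic beyond the offset
table itself.

All randomness flows from one seed through CRC32-keyed named substreams
per stage, so any stage is reproducible in isolation and end-to-end runs
are byte-identical given the same seed.

**What the generator does not model:** nucleotide sequence, rRNA/tRNA
contamination, positional biases beyond the single 5′ ramp, uORF
translation itself (the uORF mechanism is phenomenological — TE and ramp
multipliers, not scanning/reinitiation), multi-isoform genes, and
genomic multi-mapping. Passing recovery tests therefore demonstrate that
the estimators are unbiased under the generative model, not that they
are robust to every artefact of real libraries.

**Composition effects are real and intentional.** Because RPKM divides
by total mapped reads, planting a TE increase in 20% of the library
deflates every other gene's apparent RPF abundance. The planted 2× TE
effect is therefore recovered as the *difference* between group medians
of log2FC(TE) (≈ 1.0), while each group's median carries an offset of
−log2(1 + φ) where φ is the affected genes' share of footprint mass.
The acceptance script reports both.

## Problem sizes

Desk-scale runs use 60–500 genes and 4×10⁴–10⁶ reads per library; the
parameter-recovery experiments use 500 genes at ~2000 pooled footprints
per gene per condition, which puts the per-gene r5′LR sampling error
near 8–10% and the group-median error near 1–2%. The demo subcommand
defaults to 200 genes at 1.5×10⁵ reads per library.

## Known limitations

- The 5′LR denominator treats the downstream CDS as homogeneous; genes
  with strong internal pause sites will show r5′LR variance the
  generator does not reproduce.
- DEG/DTG/DTE calling is threshold-based by design; it has no error-rate
  control and should not be read as hypothesis testing.
- The exact rank-sum path is quadratic in the pooled rank sum and is
  limited to pooled n ≤ 14 by default; beyond that the asymptotic
  approximation is used even when an exact answer would be feasible.
- BED12 input carries gene ids through the name field
  (`gene|transcript`); GTF input is the richer and preferred dialect.
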