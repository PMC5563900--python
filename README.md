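# riboload

Translational-regulation analysis of paired ribosome profiling (Ribo-seq)
and RNA-seq data, built for hypoxia-style stress time courses: per-region
read densities, A-site-resolved footprint profiles, 5′ loading ratios,
translation efficiency, threshold-based differential calling, and 5′UTR
element-stratified statistics — plus a synthetic-data generator with known
ground truth so every stage of the pipeline is testable end to end.

## Who this is for

Groups analysing matched RPF (ribosome-protected fragment) and mRNA
libraries who want the standard translational readouts as a tested,
scriptable library rather than a one-off notebook: which genes change at
the mRNA level vs the footprint level, whether ribosomes pile up behind
the start codon under stress, and whether 5′UTR elements (uORFs, IRES,
5′TOP) stratify those responses.

## The quantities computed

**A-site assignment.** Footprint reads are attributed to the ribosomal
A-site by a length-dependent offset from the read 5′ end: +14 for
25–28 nt reads, +15 for 29–30 nt, +16 for 31–33 nt, +17 for 34–35 nt;
reads outside 25–35 nt are excluded. Offsets are 0-based displacements
(a 28-nt read starting at position *p* has its A-site at *p* + 14).

**5′ loading ratio.** For a gene with canonical CDS of length *L* (the
isoform with the longest CDS), with *n*<sub>w</sub> A-site counts on CDS
bases 16–195 (codons 6–65) and *n*<sub>d</sub> counts downstream,

    5′LR = (n_w / 180) / (n_d / (L − 195))

and the relative loading ratio r5′LR = 5′LR(stress) / 5′LR(control).
r5′LR > 1 means ribosomes accumulate in the early-elongation window
under stress.

**Translation efficiency.** TE = RPF RPKM / mRNA RPKM per condition, so
log2FC(TE) = log2FC(RPF) − log2FC(mRNA) exactly.

**Differential calling.** DEG/DTG: |log2FC| ≥ 1 and mean log2(RPKM) ≥ 3.3
(inclusive); DTE: fold change > 2 and mean RPKM > 5 (strict). Calls are
threshold-based; no test statistics or multiple-testing correction are
involved.

**Stratified statistics.** Genes are split by element presence and
compared by the Wilcoxon rank-sum test (exact tie-aware permutation null
for pooled n ≤ 14, tie-corrected normal approximation otherwise);
fold-change dynamics are clustered with k-means on z-scored profiles and
annotated against user gene sets with an upper-tail hypergeometric test.

## Worked example

Simulate a two-condition experiment in which uORF-bearing genes get a
1.2× A-site density ramp on CDS bases 16–195 under hypoxia, then recover
the effect:

```python
import numpy as np
from riboload import (SimulationConfig, simulate_annotation, simulate_truth,
                      simulate_reads, canonical_transcripts, wilcoxon_rank_sum)
from riboload.asite import build_profiles, loading_ratio_table
from riboload.simulate import condition_of_sample

cfg = SimulationConfig(
    n_genes=300, seed=42,
    conditions=("0h", "1h"), effect_conditions=("1h",),
    p_uorf=0.25, ramp_rho=1.2, te_fc_uorf=2.0,
    library_size_rpf=300_000, library_size_mrna=100_000,
)
models, elements = simulate_annotation(cfg)
truth = simulate_truth(cfg, models, elements)
reads = simulate_reads(cfg, models, truth)

canon = canonical_transcripts(models)
profiles = build_profiles(reads, canon, condition_of_sample(cfg))
lr = loading_ratio_table(profiles, [("1h", "0h")])

r5 = lr["r5lr_1h_vs_0h"].dropna()
uorf = r5.index.isin(truth.index[truth["has_uORF"]])
u, p = wilcoxon_rank_sum(r5[uorf], r5[~uorf])
print(f"median r5'LR, uORF genes:  {np.median(r5[uorf]):.3f}")
print(f"median r5'LR, other genes: {np.median(r5[~uorf]):.3f}")
print(f"rank-sum p (two-sided):    {p:.2e}")
```

Output:

```
median r5'LR, uORF genes:  1.176
median r5'LR, other genes: 1.007
rank-sum p (two-sided):    4.15e-17
```

The uORF group's median r5′LR recovers the planted 1.2× ramp (1.176,
within sampling error at ~1000 pooled footprints per gene), the
unaffected genes sit at 1.0, and the rank-sum test separates the groups
decisively.

The same analysis runs from the shell:

```sh
riboload demo --outdir out --seed 42        # simulate + full analysis
riboload simulate --outdir sim --seed 1     # data generation only
riboload run --annotation sim/annotation.gtf --reads sim/reads.tsv \
    --elements sim/elements.tsv --outdir analysis
```

`riboload run` writes TSV artifacts (counts, RPKM, densities, loading
ratios, gene metrics, Venn overlaps, element comparisons, ECDFs,
clusters) plus a `manifest.json`; runs are byte-identical given the same
inputs and seed.

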