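# methwave

Whole-genome bisulfite sequencing (WGBS) methylome analysis for two-sample
comparisons: per-CpG track construction, sliding-window calling of
differentially methylated regions (DMRs), gene-body methylation
classification, GREAT-style regulatory-domain and genomic-feature
annotation, input-normalized ChIP enrichment, and methylation–expression
integration — plus a synthetic methylome simulator with planted ground
truth so the whole pipeline is testable without any sequencing data.

It is aimed at epigenomics analysts comparing pooled high-coverage CpG
methylation tracks between two conditions or developmental stages (e.g.
stem cells versus differentiated cells, newborn versus adult tissue,
healthy versus diseased), where differential methylation is defined by
explicit thresholds rather than a statistical model.

## The method

**Preprocessing.** Strand calls of each palindromic CpG are combined by
summing methylated/total read counts (a minus-strand call at position *p*
belongs to the plus-strand site *p* − 1). Sites in a SNP/blacklist mask are
removed, and only CpGs with combined coverage ≥ 4 are kept. The two
samples are intersected to their common CpGs and each is smoothed with a
running average over 3 consecutive CpGs; the per-CpG difference is
Δᵢ = ā₁(i) − ā₂(i).

**DMR calling.** A window of 5 consecutive CpGs seeds a DMR when all
deltas share one sign, each |Δᵢ| ≥ 0.10, the window mean |Δ̄| ≥ 0.40
(0.20 in the relaxed "disease" mode), and adjacent CpGs are ≤ 1,000 bp
apart. Seeds are extended until the criteria fail: each reported DMR is
the maximal run of consecutive CpGs that still satisfies every criterion
and contains a seed window. Reported DMRs are disjoint, coordinate-sorted,
and labelled hyper-/hypomethylated by the sign of Δ̄. The caller is
validated against an exhaustive brute-force enumeration (`methwave.reference`)
on thousands of random tracks.

**Gene bodies and annotation.** A gene qualifies as differentially
body-methylated when DMRs cover > 25 % of its TSS–TES span (counting only
DMRs ≥ 1 kb) or, in the postnatal mode, > 5 % with no length floor; genes
< 500 bp are excluded. DMR midpoints are assigned one feature label with
precedence promoter (−1 kb/+100 bp) > TTS (−100 bp/+1 kb) > 5′UTR > 3′UTR
> exon > intron > intergenic, with CpG-island/shore context as a second
label. Regulatory domains follow the basal-plus-extension rule: basal
−5 kb/+1 kb around the TSS, extended both ways up to 50 kb to the nearest
other gene's basal domain.

**Chromatin and expression.** ChIP and input reads are counted per
fixed-width genome bin by their 5′ ends, normalized to RPKM, and compared
as log2((ChIP + c)/(input + c)) with pseudocount c = 0.25. Metaprofiles
average any signal over anchored windows or gene bodies rescaled
TSS→TES. Expression integration bins genes by FPKM (< 1 "very low",
\> 250 "high") and averages per-feature methylation differences, and an
OLS regression relates per-gene methylation change to expression change.

## Worked example

```python
from methwave import SimConfig, simulate_methylome_pair, call_dmrs, evaluate_recovery

cfg = SimConfig(seed=1, chrom_len_bp=500_000, n_planted_dmrs=5, n_null_regions=5)
a, b, truth = simulate_methylome_pair(cfg)
print(f"{len(a)} / {len(b)} CpGs in samples A / B")
dmrs = call_dmrs(a, b)
print(f"{len(dmrs)} DMRs called")
for d in dmrs[:3]:
    print(f"  {d.chrom}:{d.start}-{d.end}  n_cpgs={d.n_cpgs}  "
          f"{d.direction}  mean_delta={d.mean_delta:+.3f}")
m = evaluate_recovery(dmrs, truth)
print(f"sensitivity={m['sensitivity']:.2f}  precision={m['precision']:.2f}")
```

prints

```
4397 / 4402 CpGs in samples A / B
5 DMRs called
  chr1:128293-130028  n_cpgs=15  hypo  mean_delta=-0.424
  chr1:195967-196729  n_cpgs=12  hypo  mean_delta=-0.532
  chr1:299119-299830  n_cpgs=11  hypo  mean_delta=-0.468
sensitivity=1.00  precision=1.00
```

i.e. on a 500 kb toy genome with five planted DMRs (Δ = 0.5, 30× coverage)
the caller recovers every planted region — each reported with its member
CpG count and mean smoothed delta — and calls nothing in the matched null
regions.

The same pipeline is available from the shell:

```bash
methwave --seed 1 simulate --outdir sim/
methwave preprocess --cov sim/sample_a.cov -o a.track.tsv
methwave preprocess --cov sim/sample_b.cov -o b.track.tsv
methwave call-dmrs --track-a a.track.tsv --track-b b.track.tsv -o dmrs.bed
methwave genebody --genes sim/genes.bed12 --dmrs dmrs.bed --mode postnatal -o genebody.tsv
```

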