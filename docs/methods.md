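# Methods

## Scope and data model

methwave compares exactly two pooled methylomes. Replicate pooling is a
count-summing utility (`preprocess.pool_tracks`); the pipeline itself never
models replicate variance. Internally all coordinates are 0-based
half-open; Bismark coverage input is converted from its 1-based convention
at the boundary, and writers restore each format's native convention. A
CpG site is keyed by its plus-strand C position; minus-strand calls at
position *p* are folded into site *p* − 1 when strands are combined.
Methylation levels are fractions in [0, 1]; thresholds quoted in percent
are converted exactly once at configuration load. Chromosome names are
matched as exact strings; an explicit "chr"/plain remapping helper is the
only aliasing performed, because silent chromosome-name mismatches are the
most common interval-analysis bug.

## Preprocessing

Order: combine strands → mask → coverage filter (per sample) → intersect →
smooth. Masking and coverage filtering commute (property-tested).
Smoothing is a centred running mean over a window of CpGs (default 3,
odd), defined in CpG index space, never crossing chromosome boundaries;
edge windows truncate to the available CpGs rather than dropping sites, so
track length is stable for downstream intersection. By default smoothing
runs on the *intersected* common-CpG grid so that the per-CpG delta is a
difference of like-for-like local averages; smoothing each full track
before intersection is available via `PreprocessParams.smooth_order`
because the alternative order is equally defensible and the choice is
otherwise invisible to the user.

Coverage filtering keeps CpGs with ≥ `min_coverage` (default 4) combined
reads. bedGraph tracks carry no depth and are read with coverage 0; they
should not be coverage-filtered.

## DMR calling semantics

Parameters (`DmrParams`): region mean |Δ| ≥ 0.40 (0.20 in disease mode),
seed window of 5 CpGs, per-CpG |Δ| ≥ 0.10, adjacent-CpG gap ≤ 1,000 bp.
All thresholds apply to the smoothed deltas, and the reported region mean
is computed on the same smoothed values, for internal consistency. The
sliding window steps one CpG at a time over common-CpG index space.

Three of the criteria (single sign, per-CpG minimum, gap limit) are
hereditary: they hold for a run iff they hold for every sub-run. The
region-mean criterion is not — extending a region can push the mean below
threshold and further extension can raise it again. "Extended stepwise
until the criteria fail" is therefore implemented as **maximal qualifying
runs**: a region is reported iff it satisfies all criteria, contains at
least one qualifying seed window, and no strictly larger qualifying run
contains it. A one-CpG-at-a-time greedy grower would stall in the mean dip
and is not what the validation oracle specifies; the two definitions agree
everywhere except on such dips, and the maximal-run reading is the one we
adopt (see `tests/test_dmr.py::TestOracleEquivalence::test_adversarial_mean_dip`).

The production caller partitions each chromosome into hereditary blocks,
then finds per-start maximal runs with prefix sums (O(B²) per block, with
blocks short in practice because per-CpG noise rarely sustains |Δ| ≥ 0.10).
Overlapping maximal runs of one block merge iff their union still
qualifies; otherwise the run with more CpGs wins, ties to the smaller
start. This makes output disjoint, deterministic and order-independent.
`methwave.reference.brute_force_dmrs` recomputes the same definition by
exhaustive enumeration of all O(n²) runs with no shared code path; caller
and oracle agree exactly (spans, CpG counts, means to 1e-9) on thousands
of random tracks.

Numerical note: mean-threshold comparisons use a 1e-9 tolerance so that
the qualifying set cannot depend on floating-point summation order
(prefix-sum versus direct mean).

Reported spans run from the first member C to the end of the last member
dinucleotide (last C + 2), a fixed testable convention. Direction is the
sign of the mean delta (sample A minus sample B): hyper = A higher.

## Gene bodies, features, domains

Gene-body coverage uses the genomic TSS–TES span (not exonic bp): the
quantity of interest is how far differential methylation extends across
the gene, and the span reading keeps the fraction monotone under DMR
growth. Cutoffs are strict inequalities (> 25 % with a 1 kb DMR length
floor in `es_vs_adult` mode; > 5 % with no floor in `postnatal` mode), and
genes < 500 bp are excluded everywhere and reported. Genes covered by
both hyper- and hypomethylated DMRs are labelled "mixed" and reported
separately from the two directional tallies.

Feature annotation assigns the DMR midpoint to one category with
precedence promoter > TTS > 5′UTR > 3′UTR > exon > intron > intergenic.
The promoter window is −1,000/+100 bp around the TSS (Homer's default
promoter definition), the TTS window −100/+1,000 bp around the TES, both
strand-aware. UTR calls require CDS (thick) information in the gene
models; without it UTRs are indistinguishable from exons and collapse into
the exon category. CpG-island overlap or shore (±2 kb) context is an
independent second label, since island context is not exclusive with any
gene feature.

Regulatory domains: basal window −5 kb/+1 kb around the TSS
(strand-adjusted), extended on each side by up to 50 kb but clipped at the
nearest other gene's basal window and at chromosome bounds; a domain never
shrinks below its own basal window even when basal windows overlap. The
computation is per-gene against the set of all basal windows, hence
independent of gene order (property-tested). Curated-domain exceptions of
the original GREAT tool are out of scope; only the basal-plus-extension
rule is implemented. A DMR is assigned to every gene whose domain it
overlaps by ≥ 1 bp.

## ChIP enrichment and profiles

Bin width defaults to 1,000 bp (configurable; the appropriate value is
analysis-dependent). Reads are assigned to bins by their 5′ end with no
fragment extension — the simplest deterministic rule. RPKM divides the
bin count by bin kilobases times million mapped reads; the trailing
partial bin of a chromosome is normalized by its actual width. Log2
enrichment adds a 0.25-RPKM pseudocount to numerator and denominator,
which bounds the ratio and defines it at empty bins; chip-versus-itself is
identically zero. Note that because RPKM normalizes by the *total* read
count, a library whose reads concentrate in enriched regions shows a small
negative log-ratio in background bins (≈ −0.1 under the simulator's
default enrichment load) — the same property real input-normalized tracks
have.

Metaprofile bins with no data (no CpGs in a methylome bin, or outside the
chromosome) are NaN-masked, not zero-filled, so CpG deserts do not bias
column means. Gene-scaled profiles use fixed-bp flank bins and percent
bins over TSS→TES; minus-strand rows are flipped before averaging.

Expression groups default to the edges (1, 250) FPKM, giving "very low"
(< 1), intermediate, and "high" (> 250) strata. The
methylation–expression matrix averages per-CpG differences within each
feature (promoter, exon_k/intron_k in transcription order, ordinals past 3
pooled), then across the genes of each stratum. The Δmethylation–
Δexpression relation is an ordinary least-squares fit
(`scipy.stats.linregress`) reported with Pearson r and the two-sided
slope p-value; it requires ≥ 3 finite gene pairs and non-degenerate x.

## Synthetic data

The simulator emulates the statistical features the pipeline is sensitive
to, with one 5 Mb chromosome at the defaults:

- **CpG spacing**: a two-state island/desert process (mean gaps 20 bp and
  120 bp, switching probabilities 0.01/0.05 per CpG) produces clustered
  spacing with occasional gaps near the 1 kb rule, ~1 CpG/110 bp overall
  (≈ 45,000 CpGs per 5 Mb genome).
- **Coverage**: negative-binomial with mean 30 and size 5 — overdispersed
  like WGBS depth, so the coverage-4 filter removes a realistic tail.
- **Methylation**: both samples share an 80 % methylated baseline; inside
  a planted hypo DMR sample A's true level drops by Δ = 0.5 (hyper: B
  drops), and observed counts are Binomial(coverage, level). 5 % of sites
  drop out per sample independently, exercising the intersection step.
- **Planting**: 50 DMRs spanning 8–15 CpGs plus 50 matched null regions,
  placed on CpG runs whose internal gaps stay under 1 kb (a run broken by
  a longer gap is, by the region definition itself, not one contiguous
  region) and separated by ≥ 25 CpGs so regions cannot merge.
- **Genes**: non-overlapping stranded genes with 1–6 exons; genes laid
  over planted DMRs have covered fractions fixed by construction (cycling
  0.3, 0.1), so gene-body truth is exact.
- **ChIP**: input reads uniform; ChIP adds (fold − 1)-weighted extra reads
  inside planted regions so in-region density is exactly fold × baseline.
- **Expression**: baseline FPKM log-normal (μ = 1, σ = 1.5 in log space);
  log2 fold change = −4 × (gene-body methylation delta) + N(0, 0.5), an
  inverse coupling whose slope the regression recovers.

Recovery is scored by overlap: a planted DMR counts as found iff a called
DMR covers ≥ 50 % of its span, and the same rule defines called true
positives. At the defaults the caller reaches ≈ 0.98 sensitivity and
≈ 0.99 precision over five seeded genomes.

All randomness flows through `numpy.random.default_rng` seeded from the
config, with independent named streams per generator, so outputs are
bit-reproducible for a given seed.

**What passing does not show.** The simulator has no sequence, no
bisulfite-conversion failure, no mapping bias, no copy-number or SNP
artefacts, no spatially correlated noise, and planted DMRs have sharp
edges and a single effect size. Passing recovery tests therefore
demonstrates the *caller's* correctness and calibration under the stated
noise model, not performance on real libraries, where boundary precision
and the coverage filter interact with artefacts the simulator omits.

## Problem sizes in tests

The validation suite uses 1,000 random ≤ 50-CpG tracks for oracle
equivalence, five seeded 5 Mb genomes for recovery, and 1 Mb genomes with
200k-read ChIP libraries for enrichment recovery — sizes at which the
brute-force oracle is exact and the full suite runs in well under a
minute, while still exercising every code path at genome-like CpG
densities.

## Known limitations

- Purely threshold-based calling: no p-values, no multiple-testing
  control, no replicate variance — by design.
- Gene-body direction uses bp coverage dominance only through the
  mixed/hyper/hypo trichotomy; partially opposing DMRs within one gene are
  reported, not resolved.
- The GTF reader requires exon features carrying `gene_id`; transcript
  isoforms are flattened to their exon union.
- `intersect_dmr_sets` counts are asymmetric by construction and reported
  from both sides; the "common" relation is symmetric only at
  `min_overlap_bp = 1`.
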