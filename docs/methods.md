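# Methods

## Coordinate system and event assignment

All computation happens in 0-based, half-open mature-transcript
coordinates, 5′→3′. BED input keeps BED conventions; positions are only
rendered 1-based in human-facing reports. A `TranscriptModel` carries the
exon blocks and the genomic CDS interval; UTR5/CDS/UTR3 lengths are
derived by projecting the thick interval through the blocks, so the three
regions tile `[0, mature_length)` exactly (property-tested over random
exon structures on both strands).

Crosslink events are single-nucleotide RT stops whose BED score is the
stop count; counts, not unique positions, weight every distribution (a
unique-position weighting is available as `weight="unique"`). An event is
assigned to at most one transcript: the strand must match (antisense
events fall to the "other" class); when several annotation classes
overlap, priority is rRNA > mRNA > pseudogene > lncRNA > other (rRNA
loci receive dedicated treatment and dominate any co-annotation;
thereafter decreasing annotation confidence — deterministic
tie-breaking); among coding transcripts of one gene, the longest
("canonical") model wins so per-gene totals are unambiguous.

## Metagene profiles

Density profiles are computed over a composite layout of segments, each
scaled to a fixed number of bins (`floor(pos · n_bins / region_len)`) or
binned at 1 nt/bin for flanks. Per bin, the summed event count is
rescaled to a fixed library size — counts per 10 million (CP10M) for
iCLIP, counts per million (CPM) for footprints — and divided by the
number of transcripts *contributing to that segment*, not to the whole
layout, so transcripts lacking a region (e.g. an annotated zero-length
5′UTR) do not dilute that segment's average. 5′ flanks project genomic
sequence upstream of the TSS as negative transcript coordinates;
transcripts whose flank would run off the chromosome are dropped from
flank bins only. Ribosome footprints are reduced to their midpoint
(`floor((start+end)/2)`) before binning — symmetric and robust to the
28–30-nt length spread; a strand-aware 5′-end reduction is available via
`anchor="5p"`.

Stress/control ratio profiles are `(treated + ε)/(untreated + ε)` per
bin with ε = 0.1 density units by default: large enough to pin empty
bins at a ratio of 1, small relative to typical occupied-bin densities
(tens of units at the default library sizes), and reported on the linear
scale with log2 as an option.

## Translation efficiency and Z grouping

TE per gene is FPKM(RPF)/FPKM(RNA). The effective length for both assays
is the mature transcript length, which cancels in the ratio and makes TE
robust to length annotation. Library sizes come from the sample sidecar's
`library_size` column (total mapped reads) when present, else from the
count-table column sums. The distinction matters: per-library
normalization by gene-count sums makes a *uniform* global repression
mathematically invisible (relative proportions are unchanged), whereas
total-depth normalization preserves it as a drop in the mRNA-mapping
fraction — which is how global repression manifests in real libraries.

Genes are removed when their RPF count is below 36 in *every* RPF sample
(the filter keeps genes measurable in at least one library; the stricter
any-sample and summed readings are available via `mode=`). Genes with
zero RNA FPKM in either condition have undefined TE and are dropped with
a log message.

The stress response is the TE fold change (arsenite/untreated), taken on
the log2 scale — symmetric in up/down and standard for ratio
distributions — and standardized against the reference (Rluc) cell
line's fold-change distribution using the sample SD. Groups: sensitive
(z < −1.5), bulk (−1.5 ≤ z ≤ 1.5, boundaries inclusive), resistant
(z > 1.5). The "median fold reduction" is the median over genes of
untreated/arsenite TE, so 5.3 means TE typically fell to 1/5.3.

Per-gene iCLIP change is log2 of the pseudocounted CP10M-normalized
RT-stop totals (arsenite vs untreated) over the canonical transcript,
ε = 0.1 CP10M as above.

## Binding-site context

Crosslink positions on one transcript merge by single-linkage chaining:
consecutive sorted positions ≤ 100 bp apart join one cluster, represented
by the rounded mean of its constituents (exact halves round down, keeping
centers integral and deterministic). Merging is idempotent and surviving
centers are pairwise > 100 bp apart (property-tested, plus an exhaustive
transitive-closure oracle on small inputs).

Footprints below MAPQ 20 are discarded; the rest are contracted to a
30-bp interval centered on the fragment midpoint (symmetric and
length-robust; a 5′-anchored contraction is available via
`anchor="5p"`). Coverage at offsets −100..+100
around each site center is normalized to CPM; the `ceil(0.001 · n)` sites
with the highest total row coverage are removed before averaging — the
trim is per *site*, not per value, because its purpose is to keep rare
extremely occupied sites from skewing the average — and the profile is
reported as mean ± SEM (sample SD / √n). CDS sites within 200 nt of the
start codon are excluded from the footprint analysis to avoid
initiation-proximal pileups.

GC content at offset o of a site uses a 10-bp window whose 6th base is
the queried position, i.e. `[c+o−5, c+o+5)`; windows running off a
sequence end are excluded at that offset only. Base composition around
stops reports A/C/G/U frequencies (U substituted for T on DNA input).

## Synthetic data generator

The generator emulates the signal structure the estimators assume, at a
desk-scale transcriptome of 2000 single-exon genes (5′UTR 100–300 nt,
CDS 300–1500 nt rounded to codons, 3′UTR 200–800 nt) laid out on one
synthetic chromosome with alternating strands; an optional two-exon mode
exercises spliced-coordinate code paths. Sequences are drawn per region
at 45% GC; a 5% "resistant" gene subset gets +12 GC percentage points in
CDS and 3′UTR only.

**iCLIP.** Each library draws 10⁵ events from a four-component positional
mixture — 5′UTR (weight 0.45), TIS ±3 nt (0.15), CDS (0.30), 3′UTR
(0.10) — over a small per-gene set of discrete binding positions (2/3/1
candidate sites per region), because real crosslink signal concentrates
at discrete contact sites rather than spreading uniformly; this is also
what makes site merging meaningful. Under arsenite, 0.25 of mixture
weight moves from the 5′UTR into the CDS; for the R534H variant the
shift is scaled by 0.4.

**Counts.** Gene expression is gamma-Poisson: a log-normal abundance
(σ_ln = 1) times a gene-level Gamma(k=10, 1/k) factor shared across all
libraries of a clone, then Poisson sampling per library. Marginally
across genes the counts are negative binomial with dispersion k
(variance = μ + μ²/k), but between-condition ratios are shot-noise
limited — the overdispersion is biological and clone-intrinsic, so it
cancels in within-clone comparisons. An explicit per-gene jitter
(σ_ln = 0.10) on the arsenite TE supplies the biological fold-change
noise; it is kept small so that the programmed escape effect is on the
order of ten reference SDs, the ≥4-SD regime the Z-classification rule
is designed for. Library depth is 5×10⁶ reads, the proportional scaling
of typical practice (~25M mapped reads over ~10k expressed genes) to the
2000-gene toy transcriptome. RPF depth is anchored to the untreated
state, so arsenite libraries carry a ~5× lower mRNA-mapping count at
fixed recorded depth.

**Translation.** Baseline TE is log-normal (σ_ln = 0.35); under arsenite
TE is multiplied by a cell-line repression factor — 1/5.34 (Rluc),
1/6.26 (DDX3), 1/4.5 (R534H) — except for resistant genes in the DDX3
and R534H lines, whose TE is preserved. The escape is not programmed in
the Rluc line: the reference distribution stays unimodal, matching the
reference role Rluc plays in the Z computation.

**Footprints.** The footprint file is a positional subsample (10⁵
fragments, lengths 28–30 nt, 10% below the MAPQ threshold) drawn
proportionally to RPF expectation; 30% of fragments sit at a CDS CLIP
site displaced +30 nt 3′ (with a ±20 nt triangular jitter so the
averaged profile has a unique mode), the rest uniform in the CDS.

Every library uses an independent RNG stream derived from (seed,
cell line, condition, assay), so outputs are byte-identical across runs
of one config and libraries are mutually independent.

**What the generator does not emulate** — multi-isoform structure,
sequencing error and adapters, rRNA/contaminant reads, 3-nt codon
periodicity of footprints, replicate structure, and any dependence of
RNA abundance on stress. Passing recovery tests therefore demonstrate
estimator correctness under the assumed signal structure, not robustness
to these real-data complications.

## Numerical and degenerate-input choices

Pseudocounts default to 0.1 density units (ratio profiles, per-gene
iCLIP change); ratios of two empty quantities are exactly 1 (log2 0).
`bin_scaled` uses pure integer arithmetic; conservation of event counts
through binning and the coverage matrix holds exactly in integers before
normalization. ANOVA is classical one-way fixed-effects
(`scipy.stats.f_oneway`) with a brute-force sum-of-squares oracle in the
tests; constant input across all groups is defined as F = 0, p = 1.
Group 95% CIs use the normal approximation (±1.96·sd/√n) by default with
a t-quantile option. Degenerate groupings (<2 groups or <2 values in a
group) raise in `group_compare`; the report builder degrades to
descriptive rows with NaN F/p so a small run still produces a complete
bundle. Merged-site centers round half down; outlier trimming uses a
stable argsort so ties break deterministically.

## Problem sizes

The validation suite runs the full default conditions (2000 genes,
5×10⁶-read libraries) for the count-based analyses, 10⁵ CLIP events for
metagene-ratio recovery, and 500-gene / 3×10⁴-event constructions for
the positional analyses — sizes at which every recovery target (weight
ratios within 10%, median repression within 10%, escape-set sensitivity
≥ 0.8 at FDR ≤ 0.2, footprint peak within ±5 nt, the CDS/3′UTR-specific
GC ANOVA pattern) is comfortably identifiable while the whole suite runs
in well under a minute of compute per analysis.

## Known limitations

Single-sample conditions (replicates are summed, not modelled); no
differential-expression testing of RNA abundance; no isoform-level TE;
no peak calling or motif discovery on the CLIP data; metagene profiles
are unsmoothed; the 36-count filter's exact reading ("across all
samples") is ambiguous in the field's usage and is exposed as a flag.
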