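# Methods

This note documents the models behind each stage, the parameter defaults
and why they were chosen, the numerical decisions, and what the synthetic
studies can and cannot demonstrate about real data.

## Coordinates and cut sites

All intervals are 0-based half-open (BED). A single-end read's cut site
is its 5′ end: the interval `start` on the plus strand and the `end`
coordinate on the minus strand, whose 5′ *base* is `end − 1` under
half-open coordinates. When coverage is materialized each cut site is
extended 5 bp on either side of the cut base: `[cut−5, cut+6)` for plus
sites, `[cut−6, cut+5)` for minus sites. Aggregate profiles and
footprint matrices use the raw cut base (minus-strand sites shifted to
`end − 1`), not the extension. No Tn5 +4/−5 offset correction is applied
by default; at the window sizes used here (±100 bp and up) a 4–5 bp
shift does not change any conclusion, and the correction is easy to
apply upstream by shifting the input intervals.

Interval merging is single-linkage on ≥ 1 bp overlap; abutting half-open
intervals (`[a,b)` + `[b,c)`) do not merge. The fractional-overlap
filter follows `bedtools intersect -f` semantics: a region is kept if a
*single* overlapping partner covers the required fraction of its length;
overlaps are not summed.

## Differential accessibility

Counts per merged region are modeled per region as

  y_ij ~ NB(μ_ij, α_i),  log μ_ij = log s_j + β₀ + β_batch·batch_j + β_c·cond_j

with `s_j` the median-of-ratios size factor (the median over regions,
positive in every sample, of the count over the region's geometric
mean). The GLM is fit by IRLS (statsmodels); significance of β_c is a
Wald test against the normal reference, and p-values are BH-adjusted.

**Dispersion moderation.** The per-region dispersion α_i is estimated by
method of moments within condition×batch cells (so real effects do not
inflate it), then shrunk toward a trend α(μ) = a₀ + a₁/μ fitted across
regions by least squares. The shrinkage is df-weighted,

  α̂_i = (d_i·raw_i + d₀·trend_i) / (d_i + d₀),  d₀ = 10,

where d_i is the residual df behind the raw estimate (≈ 2 at 3 vs 3
samples split over two assays). A fixed 50/50 average was considered and
rejected: at these sample sizes the raw moment estimate is so noisy that
half-weighting it inflates the null type-I error at p < 0.05 to ≈ 0.072,
while df-weighting restores ≈ 0.052 (the Wald test with the true
dispersion measures 0.0525, so the residual miscalibration lives in the
dispersion estimate, not the test). With more replication d_i grows and
the data reclaim weight automatically.

**Near-separated regions.** When |log2FC| > 10 the Wald statistic is
unreliable — the standard error grows faster than the estimate
(Hauck–Donner), so a 0-vs-100 count pattern would be called
non-significant. Such regions are re-tested with a likelihood ratio
against the model without the condition term (χ², 1 df). Under the null
this branch never triggers, so calibration is unaffected.

Not implemented by design: outlier refitting, independent filtering,
fold-change shrinkage, more than one nuisance covariate. The intended
scale is thousands of regions and a handful of samples per group.

## Region dynamics

Two pairwise differential tables (wild type → early, early → late) feed
the classifier. Thresholds use strict inequalities; boundary values fall
to `none`:

| class       | early log2FC | late log2FC        |
|-------------|--------------|--------------------|
| stable      | > 1          | in (−0.2, 0.2)     |
| gradual     | > 0          | > 0.5              |
| global_open | padj < 0.01 and log2FC > 1 in the pooled wild-type-vs-tumor table, when neither of the above applies |

The two p-values of every region are combined with Fisher's omnibus
X = −2·Σ ln pᵢ ~ χ²(2k); the combination is computed for all regions
(not only gradual candidates) and an optional omnibus-p gate on the
gradual class is off by default. Signed-p ranking uses the raw p
(score = sign(log2FC)·(−log₁₀ p)), with ties broken by |log2FC| then
region id; zero p-values are floored at the smallest positive float.

## Motif enrichment

PWMs hold base probabilities; scoring is log₂((p + pc)/bg) with
pseudocount pc = 0.001 per cell (so zero-count JASPAR columns stay
finite) and `N` bases contributing 0 bits. The best hit is the maximum
over both strands and all offsets; ties go to the smallest offset, plus
strand preferred. The scan threshold default is 7.0 bits on the best
single site; no homotypic-cluster scoring is attempted.

A motif's ranking of the region database orders regions by best-hit
score (ties by id, unscorable regions last). For an input region set,
recovery(i) is the fraction of the set at rank ≤ i and
AUC = mean recovery over the top T ranks; NES is the population z-score
of the AUC over the whole motif collection. The defaults T = 10000 and
NES > 2.5 suit a genome-scale database (≈ 7% of a 136K-region
collection); the synthetic studies use T = 100 on their 1000-region
database — the same fraction. Using T equal to the database size is
degenerate (every recovery ends at 1, the AUC spread collapses) and is
rejected.

Candidate targets of a reported motif are the input regions ranked at or
above the leading-edge rank r*, the rank maximizing
recovery(i) − mean-recovery(i) where the mean is over the whole
collection; the construction of the expected-recovery curve is exposed
as configuration since conventions differ. Input sets given as intervals
are mapped onto the database by ≥ 40% reciprocal overlap. When a
motif-to-factor map is supplied only the best-NES motif per factor is
reported.

**Limitation.** With a desk-scale collection of 20 motifs the NES null
is weakly calibrated: AUCs share the input set and the database, so they
are positively correlated, and the maximum NES across the collection
exceeds 2.5 in roughly 5–20% of random input sets depending on the seed.
With thousands of motifs, as in a production collection, the z-scores
stabilize. The planted-motif signal (NES ≈ 4, rank 1 of 20) sits well
clear of this band.

## Footprinting

Around motif-centered, stranded anchors, raw cut-site counts are
collected into a sites × offsets matrix (rows of minus-strand anchors
reversed; rows ordered by total count). The aggregate profile is
corrected by subtracting the profile of the same PWM's best hits in
random regions, scaled to equal total count, which removes sequence
composition bias around the motif. Protection is

  (mean flank − mean motif span) / mean flank

with flanks the 50 bp on either side of the span: 1 = complete
protection, 0 = flat, negative = central enrichment. Background anchors
are drawn by rejection sampling (same width, motif hit required at the
same threshold, anchor windows excluded, 50× oversampling cap, seeded).
For a motif of length L centered at offset L//2, the span in profile
offsets is (−L//2, L − L//2 − 1). Aggregation windows should lie inside
accessible regions — windows crossing into closed flanks deflate the
flank mean and bias protection downward — so planted-truth validation
restricts anchors to motifs with ≥ 60 bp of region on both sides.

## Gene linkage and GSEA

A gene model's TSS is strand-aware (span start on +, span end − 1 on −);
introns are gaps in the exon union; the upstream window excludes the
gene body. In `upstream5kb_intronic` mode a peak links to every gene
whose 5 kb upstream window or any intron it overlaps (one peak may feed
several genes); in `nearest_tss` mode each peak links to exactly one
gene. Per gene the retained peak minimizes padj, ties broken by larger
|log2FC| then leftmost coordinate. Genomic annotation assigns one
category per peak with precedence promoter > exon > intron > distal.

Preranked GSEA: walking the ranked list, the running sum gains
|score|^w (normalized over set members, w ∈ {0, 1}) at members and loses
1/(N − N_h) at non-members; ES is the signed extremum. The null
re-draws member labels uniformly (gene-label permutation — the only
null available for a preranked list); NES = ES divided by the mean |null
ES| of the same sign, and p is the same-sign exceedance fraction with
add-one correction. With w = 0 this is the classical Kolmogorov–Smirnov
statistic, verified by brute force in the tests. Probe-level expression
tables are collapsed to genes by keeping the probe with the smallest
adjusted p.

## The synthetic study

Defaults describe the validation conditions used throughout:
2 conditions × 3 samples, NB dispersion 0.1, planted |log2FC| = 2 in 10%
opening + 10% closing regions, a 2-fold assay batch offset, sample size
multipliers spread over a 2-fold range, lognormal baseline means (median
100 counts), 2000 regions of ≈ 500 bp on 2 chromosomes. Fragment
lengths mix four Gaussian modes at 80/200/400/600 bp (weights
0.45/0.30/0.15/0.10, sds 25/40/55/70) — a sub-nucleosomal mode plus one,
two and three nucleosome multiples. Footprints reduce the cut rate over
planted motifs by 50%. Sequences are i.i.d. at GC 0.5 with one
PWM-sampled motif instance per bearing region. All generators descend
from one integer seed through independent named streams, so outputs are
byte-identical per config and independent of call order.

What this does **not** emulate: mappability and GC bias, duplicate
reads, sequence-dependent Tn5 insertion preference, peak-calling noise,
correlated replicates, and real enhancer/gene architecture. Passing the
planted-truth tests therefore demonstrates the correctness and
calibration of the inference chain under its stated model, not
robustness to artifacts of real libraries.

## Problem sizes and numerics

Validation runs use 2000 regions for differential calibration, a
1000-region/20-motif database for enrichment, 100K fragments over 200
regions for footprinting, 50K fragments for insert-size modes, and 1000
random gene sets × 200 permutations for GSEA calibration — sizes at
which every planted quantity is measurable with comfortable margin.
Insert-size modes are local maxima of a 31 bp moving-average-smoothed
histogram (prominence ≥ 2% of the global maximum, ≥ 80 bp apart —
roughly half the nucleosome repeat), each refined by a quadratic fit to
the log-smoothed histogram, which is exact for a Gaussian mode and
stabilizes minor modes riding on a heavier neighbor's tail. BH
adjustment is the standard step-up running minimum. Size factors fall
back to positive-entry geometric means only on request
(`pseudo_reference=True`), since an all-positive reference region set is
the defined behavior.
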