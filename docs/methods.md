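# Methods

## Model and rationale

hMe-seal pulldown sequencing enriches 5hmC-containing DNA fragments;
coverage in a genomic bin is proportional to the *relative* abundance of
the mark there, conditional on library depth. Standard depth normalization
therefore removes any uniform genome-wide difference between groups. The
central procedure implemented here calibrates the normalized counts with an
orthogonal absolute measurement (UHPLC-MS/MS nucleoside quantification)
before differential testing.

**Global quantification.** A mass-spec record carries molar signals for
5hmdC and dC. The global 5hmC fraction is defined per *total* cytosine,
`f = 5hmdC / (5hmdC + dC)`; at tissue abundances (well under 1% of
cytosines) this is numerically indistinguishable from the per-dC ratio, but
one convention has to be fixed and this one matches the fraction-of-total
phrasing used for brain tissue. 5mdC is not modeled separately: the dC
signal stands in for all non-hydroxymethylated cytosine, a documented
approximation. Relative levels divide `f` by the arithmetic mean of the
reference (normal) group, so the reference group's mean fold is exactly 1;
the calibration factor of a group is the arithmetic mean of its folds
(reported to 4 decimals, the convention behind published factors such as
0.4367 for human tumors and 0.3148 for the mouse model).

**Binning and counting.** Chromosomes are tiled with fixed 2 kb bins
(0-based half-open; the final partial bin is retained so that in-bounds
fragments are conserved). A fragment is assigned to the unique bin
containing its midpoint `floor((start+end)/2)` — one fragment, one count,
the sampling unit an NB count model assumes. Optional deduplication on
(chrom, start, end, strand) emulates PCR-duplicate removal. The read-to-bin
assignment rule is a documented package choice; overlap-weighted or 5'-end
assignment would change counts only at bin boundaries.

**Normalization and calibration.** Size factors use the median-of-ratios
method over bins positive in all samples (total-count ratios as a logged
fallback). Calibration divides each sample's size factor by its calibration
fold (`offset` mode, default), so normalized counts become
`fold x raw / sf` — tumor profiles are compared on their absolute 5hmC
scale while raw counts and the NB variance structure are untouched. A
`scaled-counts` mode instead multiplies raw counts by the fold and rounds;
its size factors are computed on the *unscaled* matrix, because
median-of-ratios on uniformly scaled counts would absorb the adjustment and
silently undo the calibration. With all folds equal to 1 the calibrated and
uncalibrated pipelines are bit-identical.

**Dispersion.** Per-bin method-of-moments on normalized counts,
`alpha = max(0, (s^2 - mu) / mu^2)`, with the variance pooled within groups
and `mu` the grand mean; a mean-dispersion trend `alpha(mu) = a0 + a1/mu`
is fitted by least squares over bins with positive raw estimates, and the
final dispersion is the log-scale geometric interpolation (weight 0.5)
between the raw estimate (floored at 1e-8) and the trend. This is a
deliberately simple stand-in for shrinkage-prior machinery: adequate at
desk scale, not a numerical reproduction of any specific tool.

**Testing and calling.** Each bin gets a two-group NB GLM with log link
fitted by IRLS (vectorized across bins; coefficients clipped to ±30 ln
units; convergence at 1e-10 or 50 iterations), Wald z on the group
coefficient with SE from the observed information, two-sided normal p, and
Benjamini-Hochberg FDR over non-NA bins. All-zero bins report NA and are
excluded from FDR. Bins entirely zero in one group keep the GLM p-value but
report log2FC from group means with a 0.5 pseudo-mean. Calls: gain iff
log2FC > 2 and q < 0.01; loss symmetric (expression analyses use |log2FC| >
1, q < 0.05). No LFC shrinkage, no independent filtering, no outlier
handling — intentionally minimal and stated. The Wald z is asymptotic:
at depth ~100/bin its null p-values are uniform to within a KS statistic of
~0.02 over 5000 bins; the uniformity property test therefore runs at depth
~300/bin where the approximation is clean, while FDR-control checks run at
the study-scale depth.

**Annotation.** One category per region, decided at the region midpoint
with priority promoter-TSS > TTS > 5'UTR > 3'UTR > exon > intron >
intergenic; promoter-TSS is TSS−1 kb..TSS+100 b and TTS is TES−100
b..TES+1 kb, strand-aware (HOMER-style windows; upstream of a minus-strand
TSS is the higher coordinate). Published annotations sometimes distinguish
"promoter" from "TSS" categories with undefined windows; here they are one
merged category, so those two enrichments are not separately reproducible.
Enrichment against the genome-composition background (all grid bins
classified the same way) uses a one-sided binomial tail with BH correction
across categories. Gene assignment follows the GREAT basal-plus-extension
rule: basal = TSS−5 kb..TSS+1 kb strand-aware, assigned regardless of
neighbors; each side extends to the nearer of 1 Mb from the TSS or the
closest neighboring basal edge, never shrinking below the gene's own basal,
clipped to the chromosome; a region maps to every gene whose extended
domain it overlaps by ≥ 1 bp.

**Liftover and cross-species overlap.** UCSC chain files are parsed with
full block-arithmetic validation. A region maps through the highest-scoring
chain of its chromosome; success requires ≥ `min_ratio` (default 0.95,
the liftOver minMatch default) of its bases in aligned blocks of that
single chain, and the output is the [min, max) hull of mapped destination
positions in forward coordinates (minus-strand chains follow the UCSC
reverse-complement convention). Failures carry a reason: `none` (no chain
for the chromosome), `deleted` (no base maps), `split` (only a combination
of chains would suffice; no multi-chain stitching is attempted), `partial`.
Region-set overlap is computed on the bin-grid universe — a region marks
every bin it overlaps by ≥ 1 bp — with a one-sided Fisher exact test on
the resulting 2x2 table; the bin grid is the natural sampling unit since
DhMRs are bins. Ortholog-aware gene overlap classifies each gene as
no-ortholog / ortholog-only / common (one-to-many ortholog entries collapse
to the first pair in file order) and reports
100 x common / (common + ortholog-only).

**Integration funnel.** DhMRs overlapping ≥ 1 bp of *both* ChIP peak sets
(each factor independently, matching sequential intersectBed), restricted
to promoter-TSS, joined with the differential-expression table:
concordant-up = gain with significant up-regulation, concordant-down = loss
with significant down; significant opposite sign = discordant; absent or
non-significant = untested. The expression-significance threshold is a
parameter (default q < 0.05). Genes with both gain and loss promoter DhMRs
appear in both strata with a conflict flag; region counts can exceed unique
gene counts.

**Statistical kernel.** Fisher's exact test (hypergeometric tail via
log-gamma; two-sided = sum of outcomes no more probable than observed, no
continuity corrections), BH step-up with monotonicity enforcement and NA
pass-through, Welch's t with Satterthwaite df, OLS with slope t-test (R^2
defined as 0 for constant y), and the product-limit estimator with the
standard (Mantel-Cox) log-rank chi-square, ties handled by the
simultaneous-risk-set convention; the median is the first time S(t) ≤ 0.5
and is undefined if never reached. scipy/statsmodels/lifelines serve only
as independent cross-checks in the test suite.

## Synthetic data generator

The generator emulates the structure of a two-group 5hmC study so every
stage can be scored against recorded truth. Defaults are the human study
arm: 16 tumors vs 6 normal cerebella, 2 kb bins on a 10 Mb three-chromosome
toy genome, ~100 expected fragments per bin (depth 500k), NB dispersion
0.05, true tumor global level 0.44-fold, mass-spec CV 0.1, a normal-tissue
5hmC fraction of 0.007 of cytosines, and a per-tumor biological level
spread (CV 0.2) so survival has a covariate to act on.

Latent bin intensities are lognormal (sigma 0.5) with a 2% zero-inflated
"unmappable" fraction; planted gain/loss effects (default ±4 log2 units;
chosen so that a planted gain still clears the +2 calling threshold after
the −1.2 log2 genome-wide calibration shift at the default 0.44 global
level) occupy whole bins spaced ≥ 3 bins apart. Expected counts of *every*
sample are renormalized to the same total depth, which is exactly what
makes the global level invisible in counts; it is carried only by the
mass-spec table (truth levels times multiplicative lognormal noise). Half
of the planted bins sit at gene promoters (TSS placed at the bin midpoint);
linked genes receive a concordant ±2 log2 expression effect with
probability `expr_link_prob`. Two ChIP peak-set factors jointly cover
`chip_overlap_frac` of planted bins, plus background peaks kept ≥ 2 bins
away from planted bins so the covered fraction stays controlled. The shadow
genome maps each chromosome with a distinct offset, two unaligned source
gaps and one target insertion; the last chromosome maps to the minus
strand. Survival times are exponential with hazard
`h0 exp(-beta x fold)` (h0 = 0.05/week, beta = 2), censored at 120 weeks,
subjects = the tumor samples grouped high/low at the median fold.

All randomness flows from the single config seed through one
`numpy.random.default_rng`; identical config + seed gives byte-identical
files. `emit_fragments` derives a per-sample stream from the same seed and
emits fragments whose midpoint histogram equals the count matrix exactly.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: read-level sequence and mappability structure, GC and
fragment-length bias, input-control libraries, spatially correlated
enrichment along the genome, copy-number and mutational confounders, and
cohort-scale survival. Recovery results on synthetic data demonstrate
correctness of the computations, not field performance.

## Problem sizes and numerical choices

Tests and the acceptance script run the full genome-scale configuration
(5000 bins, 14-22 samples) in seconds because the IRLS is vectorized across
bins; null-control and calibration-rate checks average over 20 and 5
replicate simulations respectively. Replicate averaging is used wherever
the measured quantity is a rate whose single-run value fluctuates around
its expectation — notably the calibration-efficacy rate, whose per-bin
pass probability under the stated conditions is analytically ~0.954
(|log2 0.2| = 2.32 against the 2.0 cutoff with estimator sd ~0.19).
Degenerate inputs are handled explicitly: empty region sets and empty
groups raise; unknown chromosomes warn and skip (counting) or classify as
intergenic (annotation); unmapped liftover is a value with a reason, not an
error.

## Known limitations

The dispersion model is intentionally simpler than shrinkage-prior
estimators; at very small group sizes its raw estimates are noisy and lean
on the trend. The Wald test inherits the usual finite-count skew (see
above). Group-wise calibration treats the tumor group as one scale class;
per-sample folds are supported but conflate biological level variation with
the regional signal. Liftover does not stitch regions across chains.
Enhancer catalogs and ortholog maps are consumed as user-supplied files,
never bundled.
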