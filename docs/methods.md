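# Methods

This note documents the models and procedures implemented in
`chromcompare`, the parameters that matter, the synthetic data the test
suite runs on, and the design decisions taken where the methodology was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and genomic primitives

All coordinates are 0-based half-open (BED-native); GTF input is converted
on read. A promoter is the strand-symmetric window `[TSS − f, TSS + f)`
with `f = 2000` bp, clipped to the chromosome; strand does not change the
window. "Overlap" with no stated fraction means at least one shared base
pair; fractional thresholds apply only where stated (reciprocal
conservation). DHS annotation is promoter-first: a peak overlapping any
gene's promoter is a promoter DHS even if it also overlaps another gene's
body. Peak sets are extended ±500 bp and merged (book-ended intervals
merge too) before cross-species overlap tests.

Promoter CpG density is CpG sites per 100 bp of promoter. Promoter
methylation is the unweighted mean over covered CpG sites of
methylated/total reads; a promoter with no covered site is *undefined*
(`None`/NaN), not 0 — missing data is not unmethylated.

## Quantification and normalization

Tag density is FPKM: fragments / (window kb × library millions). Both
accessibility and expression are transformed as `log2(FPKM + c)` with
pseudocount `c = 1` (configurable). The data contain exact zeros, so a
pseudocount is unavoidable; `c = 1` keeps zero FPKM at exactly 0 on the
log scale. Quantile normalization maps every stage column onto the row
mean of the column-sorted matrix; tied values within a column receive the
mean of the reference values their ranks span (the common convention).
A single-column matrix is returned unchanged. Genes with FPKM < 1 at a
stage are treated as not expressed there; exactly 1 counts as expressed.

## Dynamic genes

The entropy score is the Shannon entropy (bits) of the stage-proportion
vector of quantile-normalized log2 expression, with negative normalized
values floored at 0 and 0·log 0 = 0. All-zero profiles are undefined and
excluded. The stage-specific thresholds default to 2.55 bits for a
6-stage series and 1.56 for a 3-stage series; both sit just below the
respective maxima log₂6 ≈ 2.585 and log₂3 ≈ 1.585, so they separate
near-uniform genes from everything with concentrated expression. The
exact entropy variant behind these published threshold values is not
fully specified upstream; proportion entropy over stages is the
reconstruction that makes the thresholds sit naturally under the maxima,
and the thresholds are configurable.

Stage-specific genes are min-max scaled to [0, 1]; flat profiles are
excluded from clustering. K-means uses Euclidean distance, 50 restarts
and a fixed seed; `k` defaults to 6 with an automatic elbow mode
(maximum second difference of SSE over k ∈ [2, 10]). K-means cluster
indices are arbitrary labels; cross-species cluster comparisons take an
explicit cluster correspondence from the caller.

Genes driven by two distinct element sets are recognized by profile
shape, not by cluster index (cluster numbering is seed-dependent): a
scaled profile with both flank stages ≥ 0.7 and interior minimum ≤ 0.3
is treated as bimodal and eligible for stage-masked pairing.

## Element–gene pairing

Candidates for a gene are peaks overlapping the promoter or the ±998 kb
distal window around it (≈1 Mb around the TSS). The pairing rule is
Pearson r > 0.8 and two-sided p < 0.05 with p from t = r√(n−2)/√(1−r²)
against the t distribution with n − 2 df (the behavior of the standard
correlation test). Zero-variance vectors are undefined and never pass.
No multiple-testing correction is applied to pair p-values, matching the
original procedure. A peak may pair with many genes and a gene with many
peaks.

With only 3 stages the rule implies r > 0.9969, so the test has power
only for near-exact coupling; this is a property of the published rule,
not of the implementation. The pipeline applies the rule literally in
both species.

Stage-masked pairing for bimodal genes runs the correlation twice: once
with the latest flank stage masked (all candidate signals set to 0 at
that stage; the gene's expression set to the not-expressed floor, 0 on
the normalized scale) to find early-acting elements, and once with the
earliest flank masked for late-acting elements. An element active at
both flanks legitimately appears in both sets.

Hi-C support is overlap of the element with one anchor and the promoter
with the opposite anchor of any interaction record; both anchors in the
same record never support a pair.

## Cross-species conservation

Chains are ordered ungapped blocks (source span, target span,
orientation, chain id); UCSC chain files are parsed into this form, and
a simplified block-map TSV is the native dialect. Lifting projects the
query through each chain independently: a chain qualifies when it maps
≥ 95% of the query bases (the liftOver default `-minMatch`); two or
more qualifying chains → ambiguous ("multiple"), removed from all
downstream conservation analysis; none → unmapped. The unique target is
the span of projected bases, orientation-aware, so inverted blocks
preserve mapped length.

Conserved pairs require (i) the lifted A peak to overlap the pad-extended
B peak with fraction > 0.5 — strictly greater — of the *lifted query*
length (the denominator is a documented choice; the upstream description
names no denominator, and reciprocity makes the call nearly symmetric);
(ii) the same in the B→A direction; (iii) mutual best match (largest
fraction, ties to the smallest target start) so pairs are one-to-one; and
(iv) synteny. Synteny is operationalized as: the nearest
ortholog-bearing gene TSS upstream and downstream of the element must
map to the same ortholog set around the lifted locus (sets, not ordered
tuples, so inversions pass; a single existing flank suffices when the
element sits before the first or after the last gene).

Sequence-conserved peaks that fail reciprocity or synteny fall into the
divergent-state category together with lift-but-no-peak (class 2)
elements; class-2 peaks open in ≥2 of 6 stages (species A) or ≥1 of 3
(species B) are flagged species-specific open. Peaks unmappable in every
outgroup chain are newly emerged; an ambiguous (multiple) lift counts as
mappable. Promoter conservation for an orthologous gene pair is
"A-specific open" when open at *every* A stage and *no* B stage (strict
on both sides), symmetric for B, "conserved open" when open at every
stage in both.

Pair groups: Group I — the element is half of a conserved pair and the
partner pairs with the 1-to-1 ortholog in its species; Group II — the
element is sequence-conserved but the pairing is not mirrored,
subcategorized as species-specific open, inconsistent cross-species
signal dynamics, or simply unmirrored; Group III — genome-specific
element. "Inconsistent dynamics" needed an operational criterion (none
is published): the conserved element's per-stage signals, after folding
the 6-stage frame onto the 3-stage frame by a configurable stage
correspondence (default (0,1)→1, (2,3)→2, (4,5)→3), correlate at
r ≤ 0.8 — reusing the pairing threshold. Element–gene distance is
measured from the element midpoint to the TSS; the anchor point is a
documented choice.

## Variation and GO enrichment

SNP frequency per peak: count/(length/1000), half-open membership
(start ≤ pos < end). The enrichment score of a peak set merges peaks
first so no base or SNP is double-counted:
ES = (SNPs in peaks / total peak length) / (total SNPs / genome length),
enriched iff ES ≥ 1.5. Genome length is the sum of the assembly's
chromosome lengths (not non-N length; configurable by supplying a
different table). The per-stage trend is an OLS fit of ES on stage index
with a 95% confidence band.

SNP-associated genes: expressed genes whose open promoter contains a
catalog SNP, or with at least one paired element open at some stage and
containing a catalog SNP.

GO enrichment: ES = (members in input / input size) / (term size /
genome size); p is the accumulative (upper-tail) hypergeometric
probability of at least the observed member count with the full gene
universe as background; q is Benjamini–Hochberg across terms.

## The synthetic dataset

The generator emulates the *structure* of a two-species developmental
chromatin atlas, not its biology: its purpose is planted-truth recovery,
so every downstream call has a known correct answer.

Genome A is two 10-Mb chromosomes with 150 evenly spaced 10-kb genes
each. Genome B is derived by a fixed per-chromosome layout: a 100-kb
segment deleted in B *and* all outgroups (newly-emerged territory), a
100-kb segment deleted in B only (genome-specific territory), a 500-kb
inversion, a 60-kb segment translocated to the other chromosome, a 20-kb
segmentally duplicated region recorded twice in the chain (ambiguous
lifting), and a 50-kb B-specific insertion. Outgroup chains (default 3,
plus species B itself, mirroring a four-outgroup comparison) are identity
maps minus the newly-emerged territory. All A↔B gene orthology is
1-to-1 except 10 genes with the mapping removed.

Expression archetypes over the 6 A stages are cyclic blocks: high at k
consecutive stages (mod 6) for k = 1, 2, 3, with exactly equal counts per
rotation (36/60/60 genes), plus 60 uniform-high, 48 low-flat
(FPKM < 1) and 36 silent genes. The wrap-around rotation high at the
first and last stage is the bimodal class; its two flanks share one
amplitude draw, since the class is defined by comparable activation at
both ends of the series. High/low FPKM levels are 30 and 0.3 with a
per-gene, per-stage log-normal signature (sd 0.6 on the log2 scale) so
co-archetype genes are not clones; one-stage-family genes have true zero
FPKM off stage. The rotational balance keeps the per-stage value
distributions essentially identical, so quantile normalization is nearly
shape-preserving — without it, normalization visibly distorts
planted profiles and uniform genes would leak below the entropy
threshold.

Species B profiles are exact two-valued patterns — early (h,l,l),
middle (l,h,l), late (l,l,h), bimodal (h,l,h), one-stage with zeros —
assigned from the A archetype so that *every* B stage column of both the
expression and the accessibility matrix carries the identical value
multiset. Quantile normalization is then exactly the identity in the
noise-free regime, which is what makes the literal 3-stage pairing rule
(r > 0.9969) recoverable at all: any distribution imbalance across
columns perturbs r below the 3-point threshold.

Planted regulatory elements (300 bp, on a 1-kb grid ≥3.5 kb from any
TSS, clear of rearrangement-zone boundaries) copy their gene's profile
exactly (coupling 1.0); bimodal genes get two early-phase and two
late-phase elements with the opposite flank silenced. Each dynamic gene
carries 2 elements (4 when its B profile is bimodal): 1,140 conserved
elements (including 40 planted conserved promoter peaks), 310
divergent-state, 280 genome-specific, 200 newly emerged, 30 translocated
(B partner present so only synteny rejects them), 20 ambiguous. Planted
conserved elements are verified at placement to lift uniquely, to stay
within the pairing window in both species, and to satisfy the synteny
check — near inversion boundaries the nearest flanking orthologs
genuinely change, which is a property of the geometry, not an error.
Archetype labels are interleaved along the chromosome with an even
spacing per label, so genes sharing an archetype rarely fall into each
other's ±1 Mb candidate windows; this keeps the false-pair rate
interpretable as the correlation test's type-I error rather than a
statement about co-regulated neighbors.

SNPs are Poisson-placed at 1 per kb, ×3 inside newly emerged elements.
Alternating genes are CpG-rich (8 CpG/100 bp promoter density,
methylation level ~ Beta(2, 8)) or CpG-poor (1/100 bp, Beta(8, 2)),
emulating the CpG-density/methylation anticorrelation; per-site counts
are binomial at Poisson(20) coverage. Hi-C records cover a random 60%
of planted pairs plus 200 decoy anchor pairs. One planted GO term
collects three quarters of the stage-0-active genes plus noise among 30
random terms.

Measurement noise is Gaussian (sd `noise_sd`, default 0) added on the
log2 scale when matrices are emitted, then mapped back to FPKM. The two
regimes exercised by the tests and the acceptance script are noise-free
(exact recovery of all planted labels and pairs) and sd 0.2 (pair recall
and false-pair rate in the 6-stage species; the 3-stage species is
excluded from noisy pair metrics because the 3-point test's r > 0.9969
requirement leaves it without power under any appreciable noise, as
noted above).

What passing these tests does *not* show: robustness to peak-calling
noise, to fragmented or many-to-many orthology, to gapped or low-quality
alignment chains, to FPKM estimation error structure (noise here is
homoscedastic on the log scale), or to biologically clustered
co-regulated genes. The generator plants none of these.

## Pipeline mechanics and determinism

Stages run in a fixed order (annotate, normalize, dynamics, pair,
crossmap, groups, enrich); each writes sorted TSVs with fixed float
formatting, so a rerun with the same inputs, configuration and seed is
byte-identical (the run manifest's timestamp is the one excepted field).
Partial reruns (`--from-stage`, or the per-stage CLI subcommands)
recompute in memory and rewrite only from the named stage onward, which
guarantees downstream outputs identical to a full run. The CLI is a thin
wrapper; `chromcompare.analyze` on in-memory inputs is the primary
interface and is what the test suite and acceptance script drive.

Problem sizes used by the test suite: unit tests run on a reduced
configuration (two 2-Mb chromosomes, 60 genes, ~230 elements); the
end-to-end acceptance checks run the full default scale (two 10-Mb
chromosomes, 300 genes, ~2,000 elements), once noise-free and once at
noise sd 0.2, plus a 1,000-replicate Monte-Carlo calibration of the SNP
enrichment score under uniform placement.

## Known limitations

* One TSS per gene; no isoform resolution.
* Orthology is strictly 1-to-1; paralogs are out of scope.
* The chain reader assumes ungapped blocks within chains built from
  UCSC chain records; exotic chain features (overlapping target blocks)
  are not modeled.
* The 3-stage species' pairing uses stage means (n = 3). A
  replicates-as-samples mode would raise power but replicate-level
  matrices are not part of the input contract.
* VCF input for SNP catalogs is not implemented; positions arrive as
  BED/TSV.
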