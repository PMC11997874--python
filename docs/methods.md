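# Methods

## Model

`spliceoutlier` treats aberrant splicing detection in tumor cohorts as a
per-sample outlier problem rather than a group-mean comparison. The unit of
analysis is the splice junction — the intron interval an aligner reports for
reads spanning an exon–exon boundary — because junction-spanning reads
pinpoint the specific splicing event, unlike whole-exon coverage. The
implicit model is:

* normal samples define, per junction, a reference distribution of
  normalized junction usage;
* a tumor harbors an aberrant event at a junction when its normalized usage
  is far outside that reference (robust fences), is expressed at a
  biologically meaningful level (absolute floor), and differs from the
  typical normal level by a large factor (fold-change cutoff);
* an event is cohort-level significant when outliers concentrate in the
  tumor group beyond what a hypergeometric draw explains.

This deliberately detects events present in a *subset* of tumors; an event
present in every tumor and every normal is invisible, as is intron
retention (a junction-only data model has no non-split reads).

## Normalization

Two steps map raw junction counts onto a scale comparable across samples
and genes:

1. **Library size.** Counts are divided by the sample's total uniquely
   mapped reads, times 10⁶ (reads per million). Only uniquely mapping
   junction reads are counted; multimapper columns in `SJ.out.tab` are
   ignored, consistent with using uniquely-mapped totals as the
   denominator.
2. **Gene expression.** Junction RPM is divided by the host gene's
   upper-quartile-normalized expression (expected counts scaled so the 75th
   percentile of expressed genes is `uq_target`, default 1000), so that a
   junction's signal reflects splicing usage rather than overall
   transcription of its gene.

On this default scale a typical expressed junction sits near 1 and the
outlier floor of 10⁻⁵ acts as a weak minimum-expression filter. A plain
proportion scale (`rpm_scale="proportion"`, values 10⁶-fold smaller) is
available; the floor is interpreted on whichever scale is configured, so
users changing the scale should rescale `min_norm_expr` accordingly. The
per-million default was chosen because it is the only scale on which the
conventional 10⁻⁵ floor is operative rather than discarding every junction.

The upper-quartile percentile uses the exclusive (type-6, `h = (n+1)p`)
interpolation rule over genes with nonzero expression; computing the
quartile over expressed genes only avoids the normalization target being
dragged by annotation size in sparse data. Both choices are configurable.
Zero gene expression with a nonzero junction count yields an *undefined*
cell (not infinity): such cells are excluded from both the fences and the
Fisher table, shrinking that junction's effective sample sizes. Junctions
that map to no gene are carried through un-normalized with divisor 1 and
flagged `no_gene`, keeping novel intergenic junctions discoverable.

## Outlier statistic

The reference summary per junction is median and Tukey-style fences over
the normal panel: upper fence `Q(1−t) + k·IQR`, lower fence `Q(t) − k·IQR`
with `t = 0.25`, `k = 1.5` by default (numpy's default linear quantile
rule). The exact fence construction of the classic outlier-sum family
varies between implementations, so both `t` and `k` are exposed; the two
absolute modifications — the expression floor and the fold-change-vs-median
requirement — are always applied on top. Details that matter numerically:

* fence comparisons are strict, so constant junctions produce no outliers;
* the fold-change denominator is guarded with ε = 10⁻¹² — over an all-zero
  normal background any cell clearing the floor counts as an over-outlier;
* normal samples are labeled with leave-one-out fences: a normal compared
  against a distribution containing itself could never be extreme, and the
  Fisher test needs honest normal outlier counts;
* junctions with fewer than two defined normal values are wholly undefined.

Per junction, one-sided Fisher's exact tests (hypergeometric upper tail)
are computed separately for over- and under-enrichment in tumors, because
over- and under-expressed events are biologically distinct findings.
Benjamini–Hochberg correction is pooled across all tested (junction,
direction) pairs — the conservative choice relative to per-direction
families. Junctions on chrX/chrY are dropped by default so sex composition
differences between cohorts cannot masquerade as tumor biology.

## Event classification

Junctions map to the gene whose span contains the intron interval, strand
permitting (undetermined-strand junctions match either strand). When
overlapping genes both qualify, the gene sharing an annotated splice site
wins, then the smaller span, then the lexicographically smaller identifier
— a deterministic tie-break that can be disabled to report ambiguity.
Classification is boundary-based and ordered; the first match wins:
`annotated` (equals an annotated intron), `skipping` (both boundaries on
annotated splice sites of one transcript, at least one full exon inside),
`deletion` (a boundary strictly inside an annotated exon), `insertion`
(remaining novel junctions with boundaries in intronic sequence). "Strictly
inside" excludes exon endpoints, since a junction boundary abutting an exon
edge removes no exonic sequence. With a two-exon transcript, `skipping` is
impossible by construction — a property the tests assert exhaustively.

## Synthetic cohorts

The simulator reproduces a benchmark design at the junction-count level: it
skips read synthesis, alignment and quantification, and instead draws
counts directly around the design's expected values. Defaults are the
design conditions: 1000 genes with one canonical transcript each (3–8
exons), 200 genes with an additional alternative transcript skipping one
internal exon; 20 normals and 40 tumors; baseline 600 reads per transcript;
canonical transcripts at uniform 1–2× baseline in every sample; alternative
transcripts at 1× in normals, uniform 1–2× in 20 tumors and uniform 4–5× in
the other 20 — the latter 200 transcripts being the ground-truth
over-expressed events. A junction's expected count is the summed expected
reads of transcripts containing it; gene expression is simulated the same
way at the gene level; the library size is the total simulated reads of the
sample. Noise is Poisson by default, with a gamma-Poisson
(negative-binomial, `var = μ + d·μ²`) option for extra-Poisson variance and
a `none` option that uses expected counts directly for closed-form checks.
All randomness flows through one seeded generator, so equal configurations
give bitwise-identical cohorts and GTF exports.

What the generator does **not** emulate — and what passing benchmarks on it
therefore do not show about read-level data: mapping ambiguity and novel
junction artifacts from alignment, expected-count redistribution across
annotated but unsimulated transcripts during quantification, fragment-level
biases, and annotation realism (real alternative transcripts often share
every junction with the canonical form or differ only in ways invisible to
junctions; the simulated alternative is always a cleanly detectable exon
skip). The count-level cohort is consequently close to perfectly separable
for this detector: the two canonical-only junctions flanking the skipped
exon are strongly under-expressed (relative to gene expression) in
high-expressing tumors, so with fold-change cutoff 2 the benchmark and
acceptance runs recover essentially all true genes with essentially no
false positives. Read-level benchmarks of the same design report far less
favorable operating characteristics; the difference measures the upstream
noise sources listed above, not the statistic itself.

## Evaluation

Gene-level scoring uses two call levels: *identified* — the gene has at
least one junction with at least one tumor outlier call surviving all
filters (an `identified_rule="tested"` variant counts any tested junction)
— and *identified and significant* — at least one junction at BH-FDR ≤
0.05. Sensitivity is TP over truth-positive genes, specificity TN over
truth-negative genes, FDR the fraction of called genes without a true event
(0 when nothing is called). All 1000 simulated genes enter the denominators;
the simulator produces no genes that would need exclusion rules.

## Problem sizes and budgets

The shipped benchmark (`scripts/acceptance.py`, `spliceoutlier benchmark`)
runs 10 replicate seeds of the full 1000-gene design (~4700 junctions × 60
samples each, ~9400 Fisher tests per replicate), about 1.5 minutes on one
CPU. The test suite uses 25–30-gene cohorts for end-to-end checks and
exhaustive small grids (all 2×2 tables with margins ≤ 12; every placement
of a 5-value grid on 6-sample cohorts) for the exactness checks.

## Known limitations

* No PSI computation and no rare-disease single-outlier mode; the method
  is tumor-vs-normal-panel by design and needs ≥ 2 normals (more for stable
  fences).
* The fence rule is one member of the outlier-sum family; results depend
  mildly on `tail_quantile`/`iqr_multiplier` and the quantile
  interpolation rule.
* Event labels for junctions spanning multiple overlapping genes depend on
  the documented tie-break.
* With very small normal panels the leave-one-out reference can degenerate
  to a single value, making normal outlier calls conservative.
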