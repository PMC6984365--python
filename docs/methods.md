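# Methods

This note records the models, defaults, and numerical choices behind
`lncevo`, and what the synthetic fixtures do and do not establish.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GTF I/O converts to and
from the 1-based inclusive convention. A gene is one or more transcripts
sharing a chromosome and strand; its TSS is the 5′-most isoform start on
the gene strand, so promoters (default 400 bp upstream, truncated at the
chromosome edge and flagged) are per-gene, not per-isoform. Exon blocks
are the minimal disjoint interval set covering every exon base of every
isoform; they are the unit projected between genomes. Splice sites are
the first and last two bases of each intron. "Bidirectional promoter"
uses a 1 kb window between opposite-strand TSSs — no canonical distance
exists, so the window is a parameter; protein-coding partners take
precedence over noncoding ones when both are present.

## Coding potential

The codon substitution frequency model holds two multinomial tables over
ordered codon-pair states (61 sense codons plus one pooled stop state;
pooling avoids sparse stop×stop cells), estimated from aligned training
pairs with additive smoothing (pseudocount 0.5, so log-ratios are always
finite). Codon pairs containing gaps or ambiguity codes contribute zero —
the statistic is about substitutions, not indels. A window of 75 bp
sliding by 3 bp is scored per strand as the maximum over the three
reading frames of the summed log(f_coding/f_noncoding); the minus strand
scores the reverse complement of the window, so reverse-complementing
both sequences swaps the strand score vectors. "Positive score" is
strictly > 0. Transcript classification needs ≥150 bp of unmasked exonic
sequence under positive windows; exonic regions of other genes are masked
because the partial strand symmetry of the genetic code leaks coding
signal onto the antisense strand. The training corpus and smoothing are
not canonical anywhere; both are explicit parameters, and the synthetic
training generator (synonymous-biased codon evolution vs uniform base
substitution) states its rates in the function signature.

## lncRNA selection

Filters are computed independently and recorded per gene, so the audit is
order-independent by construction; a locus is a lncRNA only if no
applicable filter fails. Reference (annotation-derived) loci skip the
novel-locus-only filters (exonic length, unmappable overlap, intergenic
distance, junction support), which are reported NA. Read support ("at
least ten uniquely mapped reads") is summed across samples. "Intergenic"
means no exonic overlap with a protein-coding gene on either strand plus
≥5 kb span-to-span distance from same-strand protein-coding genes.
Overlap fractions follow the wording that differs between filters:
exonic length for unmappable regions, locus span for retrogenes and
RNA-type repeats. A zero-variance expression vector makes the antisense
concordance undefined; the locus fails with a flag rather than passing
silently.

## Orthology

Chains follow the UCSC format; projection uses the highest-scoring chain
covering the interval and requires ≥10% of reference bases to remap
(applied per exon block). Two chains that remap ≥10% each to distinct
target loci (>1 Mb apart or different chromosomes) make the projection
**ambiguous** when their reference coverage overlaps (a duplication
signature) and **split** when it does not (a breakpoint through the
block); a literal one-chain split cannot occur because a chain has a
single target chromosome and strand. Size-ratio bounds are selected per
species pair (0.33–3 rodent-like, 0.2–5 chicken-involving) and compare
projected span to reference span. The consensus chromosome/strand is the
projected-base majority (ties discard the gene); collinearity is tested
on block midpoints, orientation-corrected by the chain strand (the
biological strand of the projected gene is the reference strand composed
with the chain orientation — these differ, and conflating them breaks
minus-strand orthologs). Exactly one offending block is dropped;
two or more discard the gene. Percent identity and percent gapless
alignment use the reference exonic length as denominator, so each RBH
direction is computed independently; the default aligner is biopython's
affine-gap global aligner (match 1, mismatch −1, open −4, extend −0.5)
and is pluggable.

## Expression

Scaling normalization ranks genes within samples, takes as candidates the
genes whose mean expression lies in the across-gene interquartile range,
and selects the 100 candidates with the lowest across-sample rank
variance. Candidate means are computed on library-size-prescaled columns:
a data-dependent candidate window would otherwise shift when a single
sample is rescaled, making the procedure non-idempotent. The common
median target is, by default, the mean of the per-sample pre-scaling
medians (keeps the output on the input's TPM scale); any data-dependent
target necessarily follows a global rescaling of the input, so strict
output invariance is available by passing a numeric `target`. Rank ties
use average ranks. Read resampling to a common condition depth draws
without replacement (multivariate hypergeometric over the flattened
gene × replicate cells), so zeros stay zero and totals are exact; class
depth matching multiplies counts by r = mean(lnc)/mean(pc) per sample
with stochastic rounding (floor + Bernoulli on the fraction), preserving
proportionality and integrality with the right mean in expectation.
Specificity uses τ = Σ(1 − x_i/x_max)/(n−1), threshold 0.8 by default —
"narrow expression distribution" has no canonical statistic, so this is
an interpretation and a parameter.

## Stage differential expression

Per gene, a negative-binomial model with one mean per developmental stage
is compared with a single-mean null by likelihood ratio. With dispersion
held fixed, the NB maximum-likelihood group mean is the sample mean (the
score is a constant-weighted residual sum within a group), so no
iterative fitting is needed. Dispersion is method-of-moments per gene
(pooled within-group variance; Poisson fallback when variance ≤ mean),
then moderated toward the across-gene median with prior df d₀ = 20,
weighted by residual df: a pure per-gene estimate at 2–4 replicates is
simultaneously anti-conservative under a chi-square reference and
underpowered under an honestly calibrated per-gene reference (a ceiling
near 80% detection at FDR < 0.01 for 8-fold effects, at any depth), which
is exactly why DESeq2 and edgeR share dispersion information across
genes. The LRT statistic is referred to a quasi-likelihood F distribution,
LRT/(k−1) ~ F(k−1, n−k+d₀). Measured on null simulations (2,000 genes,
negative-binomial dispersion 0.05), type-I error at nominal 0.05 is
0.037–0.054 across designs and seeds, and planted 8-fold effects at
3 replicates are detected at FDR < 0.01. Consecutive-stage contrasts use
a Wald z on the log fold change with a delta-method standard error and
the same moderated dispersion. Externally computed DE tables (e.g. from
DESeq2) can replace these results in all downstream steps.

## Conservation and divergence

Conservation tracks are sparse scored intervals; unscored bases are
missing, not zero. Region scores are means over unmasked, scored bases;
group summaries report the median with a percentile bootstrap 95% CI
(conservative floor/ceiling percentile selection; measured coverage ≈0.95
for groups of ~200 genes, flagged unstable below 10 genes).

The expression conservation index is EC = ρ_between/ρ_within on
log2(TPM+1): ρ_between averages Spearman correlations over cross-species
replicate pairs, ρ_within over within-species pairs pooled across both
species. Positionally matched cross-species pairs (replicate i vs
replicate i) are skipped — replicate labels carry no biological pairing,
and skipping them makes EC exactly 1 when one species' replicates are
literal copies of the other's, while leaving the estimate unchanged in
expectation for exchangeable replicates. The bootstrap resamples gene
pairs (the error bars should shrink with the gene category size) and
reports the envelope (min and max over 100 replicates). EC is undefined
(flagged) when ρ_within ≤ 0.

Expression divergence is the Euclidean distance between sum-normalized
condition-mean profiles; per-condition contributions are the squared
difference shares (p_Ac − p_Bc)²/d² — the unique decomposition of a
squared Euclidean distance whose parts sum to 1. Distance is regressed on
the pair's average log2 expression by OLS; residuals quantify divergence
beyond what expression level predicts. Genes with d = 0 are excluded from
contribution averages. Species-specific loci require ≥100 uniquely mapped
reads in the focal species and exactly zero over the resolved projected
region in the other; loci whose projection was discarded are excluded
rather than called.

## Synthetic fixtures: what they emulate and what they don't

The genome simulator derives species B from species A's layout with
per-base substitutions (default 0.03) and planted structural events, and
writes chains expressing the true homology directly — tests target
pipeline logic, not aligner quality. Planted events, one class per gene:
dispersed duplications (ambiguous projections — planted on a different
chromosome, since the ambiguity rule defines distinct loci as >1 Mb apart
or different chromosomes and strictly tandem copies would evade it),
deletions (unmapped), whole-gene inversions (minus-strand chains),
single-exon displacements (rescued), double swaps (order_fail), one exon
translocated to another chromosome (consensus rescue — the smallest exon
moves, so the projected-base majority stays put), large insertions
(size-ratio failures), breakpoints through single-exon loci (split), and
species-specific loci whose sequence is conserved but which are annotated
and transcribed in one species only.

Expression means combine a log-normal baseline (lncRNAs scaled to 10% of
protein-coding abundance, floored at 2 expected counts per sample so loci
remain detectable), log-normal organ preferences, a 4-fold testis bias
for half of lncRNAs, and stage profiles (up/down/peak, 6-fold amplitude)
for a 30% DE fraction; species divergence multiplies condition means by a
log-normal factor (sd 0.4 by default, the dial for the EC gradient);
replicates are negative-binomial with dispersion 0.05 (gamma–Poisson),
matching the DE engine's assumptions so calibration is checkable.
Species-specific loci are boosted to ≥300 expected total reads so the
100-read support rule is met with margin — the planted on/off state, not
sampling noise, decides the call. The default design is 4 organs ×
3 stages × 3 replicates per species (~600 genes), which runs the whole
pipeline in seconds; DE calibration checks use the 5-stage design.
Conservation tracks paint a 0.07 baseline, 0.42 on constrained exons,
0.17 on promoters, 0.85 on splice sites, and 0.094 on unconstrained
lncRNA exons.

The fixtures do **not** emulate: read-level sampling (counts are drawn
per gene, not per read), alignment error, assembly artifacts beyond the
planted filter violations, isoform complexity (one transcript per
simulated gene; multi-isoform logic is exercised by unit fixtures),
indels within aligned gene bodies, or dispersion that varies across
genes. A green test therefore establishes that the pipeline's logic and
statistics behave as specified under their own model assumptions — not
that the defaults are optimal for any particular real dataset.

## Degenerate inputs and tie-breaks

Monoexonic transcripts have no splice sites; all-zero genes are untested
for DE, unassigned for maximum expression, and excluded from relative
profiles. Condition-mean argmax ties break by the fixed condition order
(brain, kidney, liver, testes; stages ascending) and are flagged.
Consensus votes that tie discard the gene. K-means uses k-means++
initialization with 50 restarts and a fixed seed; results are
deterministic given (seed, restarts).
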