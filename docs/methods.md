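# Methods

## Problem and model

In an allogeneic stem-cell transplant between HLA-matched individuals, the
donor T-cell repertoire can react to recipient peptides encoded outside the
MHC locus — minor histocompatibility antigens (mHA). The package models the
candidate-mHA load of a donor–recipient pair as a chain of deterministic
transformations:

SNV calls → directional sets → coding consequences → variant-centered
peptides → 9-mer windows → peptide–HLA IC50 → presentation classes →
summary statistics.

Each stage is a pure function of its inputs; the only stochastic component
is the synthetic-data generator.

### Directional variant sets

A variant is *present* in a sample when its genotype carries at least one
ALT copy; zygosity is ignored because one allele suffices to encode the
variant peptide. GVH = recipient \ donor, HVG = donor \ recipient, computed
on the identity (chrom, pos, ref, alt) after multiallelic decomposition.
Only SNVs participate: an indel has no single substituted residue to center
a peptide on, and the directional-set definition used throughout is an
SNP-level comparison. Missing genotypes (./.) count as *absent* by default
(no abstention mechanism exists downstream); the `missing_as_unknown` option
instead excludes such sites from both directional sets.

### Peptide construction

A nonsynonymous consequence at protein position p yields a padded peptide
with `min(8, p−1)` reference residues on the left and
`min(8, L−p)` on the right of the substituted residue — a 17-mer when both
flanks are full, which is exactly the window containing every 9-mer that
covers the variant (9 being the modal HLA class I ligand length). All
length-9 windows containing the variant offset are enumerated; for a full
17-mer the variant occupies nonamer positions 9, 8, …, 1. The window count
for a length-L peptide with variant at offset v is
`min(v, L−8) − max(1, v−8) + 1`.

Stop-gain and stop-loss variants are excluded from peptide generation (and
logged): a premature or destroyed stop has no single substituted residue and
its product is better treated by dedicated truncation models, which are out
of scope. Synonymous consequences never reach peptide construction; passing
one is a caller error, not a silent no-op.

One variant hitting k transcript isoforms yields up to k padded peptides.
Deduplication to unique (peptide sequence, HLA allele) complexes is a
separate stage: count statistics use unique complexes, while the rank-curve
potential is computed on the raw (duplicate-retaining) library. Both
behaviors sit behind config switches with those defaults.

### Binding model

The built-in scorer is a position-specific scoring matrix additive in
log10(IC50/nM) with an intercept — the standard form of published
stabilized-matrix-method (SMM) matrices:

    IC50(peptide) = 10 ^ (intercept + Σ_{i=1..9} M[i, aa_i])   [nM]

IC50 is clipped to [0.01, 50000] nM (configurable) to keep downstream
statistics finite under extreme matrix sums, and rounded at 1e-9 nM so a
score engineered to land exactly on a threshold classifies deterministically
across platforms. Presentation classes use strict inequalities — IC50 <
500 nM *presented*, < 50 nM *strongly presented* — so boundary values fall
to the weaker class; the classes are nested by construction. Each distinct
allele of a genotype is scored once (homozygosity does not double records).

A pan-specific predictor is consumed via its captured whitespace-delimited
result tables (column names configurable); live querying of external
services is deliberately out of scope. The *shared* set is the intersection
of the two predictors' presented complexes on the (peptide, allele) key,
keeping both IC50 values; duplicates collapse to the lowest IC50 per key.
The between-predictor Pearson correlation is computed on raw nM by default,
with a log10 option since affinities are log-distributed.

### Alloreactivity potential

Complexes with IC50 ≤ 100 nM (the cutoff is a parameter) are sorted by
ascending IC50 — ties broken lexicographically by (peptide, allele) for
reproducibility — and assigned ranks 1..N. Ordinary least squares fits
IC50 = c₂x² + c₁x + c₀ on the rank axis, and the potential is the
closed-form definite integral

    AUC = c₂(b³−a³)/3 + c₁(b²−a²)/2 + c₀(b−a),  a = 1, b = N,

in nM·Peptide. Integrating over *rank* rather than over IC50 is forced by
the unit (an area of peptides × nM) and by the curve's published axes
(complex count on x, IC50 on y); the bounds "lowest IC50 to the cutoff" map
onto rank 1..N under the ascending sort. With fewer than three retained
points the quadratic is unidentifiable: the trapezoid area of the raw
series is reported with a fallback flag (zero for an empty series). A
constant series at IC50 = c integrates exactly to c·(N−1).

The expression-weighted variant is Σ REU(gene, tissue)·(1/IC50) over
records, a per-clone antigenic-pressure proxy; genes missing from the
expression table contribute zero and are counted. The power-law fit
regresses log10(1/IC50) on log10(rank) with 1/IC50 sorted descending; its
exponent is scale-invariant and its intercept shifts by −log10 k when all
IC50 are multiplied by k.

### Group comparisons

For pooled sample sizes ≤ 20 without ties, the Mann–Whitney U null
distribution is built by complete enumeration of all C(n+m, n) labelings of
the pooled ranks, and the two-sided p-value is min(1, 2·min(P(U ≤ u),
P(U ≥ u))) — at nine pairs this is 126 labelings, so the exact test is both
feasible and necessary (printed p-values at these sizes are enumeration
artifacts like 2/126). With ties or larger samples a tie-corrected normal
approximation with continuity correction is used and flagged. Medians are
the standard order statistic (middle value for odd n, mean of the central
two for even n); ranges are min–max.

### Tissue expression

Per tissue, the count of *distinct* genes that contribute at least one
presented peptide and exceed the expression threshold (strictly > 10 REU,
configurable). Counting is gene-level, per tissue; genes absent from the
table are reported separately, never silently dropped.

## Synthetic data

The generator emulates a desk-scale exome comparison: 20 genes (CDS 120–300
nt, half multi-exon, 30% minus-strand, all valid ORFs), 40 recipient and 30
donor SNVs with half of the smaller call set shared, 80% nonsynonymous,
matrix targets of 10% presented / 1% strongly presented among random
nonamers, and lognormal REU (μ = 1.5, σ = 1.5 in log units) across the 16
body-map tissues. These sizes keep a full pipeline run around a second
while leaving every code path (strand handling, splice junctions, isoforms,
truncated flanks, presentation classes) exercised.

Matrix tuning is quantile-based: raw scores of 10,000 random nonamers are
sampled, the cells are scaled so one log10 unit separates the presented- and
strong-target quantiles, and the intercept pins the presented quantile at
log10(500). A zero presented-target pins the intercept above the ceiling
for the most favourable peptide. Variant planting resamples codon
positions until the requested consequence class is achieved, records every
per-isoform consequence in the truth table using the generator's own exon
bookkeeping (kept deliberately separate from the pipeline's coordinate
mapping, so end-to-end recovery is a genuine cross-check), and writes
single-sample VCFs via htslib.

What the generator does **not** emulate: human allele frequencies and
linkage, sequencing error and genotype uncertainty, realistic HLA binding
motifs (matrices are random up to the tuned quantiles), proteasomal
cleavage and TAP transport, and exome-wide scale. Passing tests therefore
demonstrate the correctness of the transformations and statistics, not the
biological accuracy of any particular affinity prediction on real data.

## Numerical choices

- Coordinates are 1-based inclusive genomically (VCF/GFF3 convention) and
  1-based for protein/peptide offsets; CDS offsets are 0-based internally.
- Minus-strand transcripts store segments 5′→3′ in transcript orientation
  and complement VCF alleles before codon substitution.
- Models whose CDS length is not a multiple of 3, or whose translation has
  an internal stop, are rejected at load with a report entry, never fatally.
- The quadratic fit uses `numpy.polyfit` (degree 2); RMSE is reported, and
  the integral is always the closed form, never numeric quadrature.
- JSON summaries are written with sorted keys and no timestamps, and all
  record orderings are total, so a rerun with the same inputs is
  byte-identical.
- Standard genetic code only; nonstandard residues (B, J, X, Z, U) are
  scoring errors naming the residue and position.

## Known limitations

- The built-in matrices are a scoring *contract*, not trained predictors;
  numeric agreement with any historical predictor version is out of scope.
- HLA class II, frameshift/indel consequences, splice-site effect
  prediction, phasing and quality filtering are out of scope.
- The exact Mann–Whitney path enumerates up to C(20,10) ≈ 184k labelings;
  beyond that the normal approximation takes over by design.
- Pearson correlation on raw nM is dominated by the affinity tail; the
  log10 option is usually the better-behaved choice and is exposed but not
  the default.
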