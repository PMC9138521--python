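# Methods

## Pipeline model and assumptions

`rsnpscan` treats a regulatory SNP prediction as a purely sequence-based
computation: a variant matters exactly insofar as it changes which PWM
windows in its 51-bp neighbourhood pass fixed similarity cutoffs. The
pipeline assumes biallelic single-nucleotide variants reported on the genome
plus strand (VCF/GVF convention), one TSS per gene taken from a configurable
GFF3 feature type (default `gene`: feature start on `+`, feature end on
`-`), and PWMs that describe independent per-position base preferences.
No TF expression context, chromatin state, or cooperative binding is
modelled; a "gain" is a prediction about sequence, not an assertion about
in-vivo binding.

### Coordinates

All external formats are converted at the file boundary to 0-based half-open
internal coordinates; user-facing positions (VCF `POS`, TSS, region queries)
stay 1-based. Promoter windows are inclusive at both ends, so an unclipped
window spans `upstream + downstream + 1` bases; a SNP exactly at the
upstream or downstream limit is inside. The TSS base itself has distance 0
and counts as the downstream side of the asymmetric −1 kb/+100 bp query
window.

## Scoring

Counts are regularised with a pseudocount (default **0.8 per base**, a
common choice for small-count TF matrices; the scoring scheme itself does
not prescribe one) and converted to row-stochastic frequencies. The
information vector `I(i) = Σ_b f(i,b) ln(4 f(i,b))` is 0 for a uniform
position and approaches `ln 4` for a degenerate one. Similarity scores are
min–max normalised information-weighted frequency sums, so the consensus
window scores exactly 1 and the anti-consensus exactly 0. Degenerate case:
a matrix whose Max and Min coincide (fully uninformative) scores every
window 1 by definition rather than 0/0.

The 5-position core is the consecutive window with maximal summed
information, leftmost on ties; a `core_start` annotation in the library file
overrides the computation (covering libraries that predefine cores). Both
orientations of every sequence are scanned by default, since double-stranded
DNA presents both; reverse matches are reported in the scanned sequence's
coordinates with the site shown as aligned to the matrix.

This module reimplements the published MATCH scoring scheme; numerical
identity with the proprietary MATCH binary and its minimum-false-positive
cutoff profiles is *not* claimed. Cutoffs are treated as data: read per
matrix from the library file when present, else defaults core 0.75 / matrix
0.85.

## Consequence semantics

Sites are paired across alleles by `(pwm_id, seq_offset, orientation)` —
for a 1-bp substitution this positional identity is the only pairing under
which gain/loss is well defined. Matrix scores are compared after rounding
to 3 decimals (the precision MATCH-style scores are printed at); equal
rounded scores are `no_change`, which also covers the rounding-only case of
a core-score difference with an equal matrix score. Records whose footprint
does not cover the variant base are provably `no_change` (the windows are
identical strings) and are pruned, so every stored consequence is
attributable to the variant. `no_change` rows are excluded from the
persistent store by default (`keep_no_change` retains them); they are still
computed, and rSNP flags never depend on them.

## Store and statistics

The SQLite store enforces referential integrity at build time (every link
references a known SNP and gene; every consequence joins to at least one
link on its gene strand) and records the build window in a metadata table so
narrower query windows can be validated as pure re-filters. Exports are
ordered by (chrom, pos, pwm_id, offset, orientation) and print scores at 3
decimals, making repeated builds byte-identical.

Summary statistics are computed inside a user window (default −1 kb/+100
bp): `rsnps_per_promoter` averages rSNP–gene links over *all* annotated
genes, so gene-poor promoters drag the average down rather than being
excluded; `pct_rsnp` is rSNPs over promoter SNPs; `tfbs_per_rsnp` counts
distinct affected `(pwm, offset, orientation, gene_strand)` sites. The
distance-to-TSS histogram covers [−750, +250) in 50-bp left-closed
right-open bins (the edge convention was an open choice; left-closed was
fixed and is tested).

## Synthetic fixtures

The generator emulates only what the pipeline's rules need: i.i.d.
background nucleotides at a configurable GC content (default 0.40, typical
of plant genomes), genes placed in evenly spaced slots with random strands,
and planted (SNP, site) constructions — consensus vs. consensus-breaking
base for gain/loss with sharp matrices, and a 70/30 mixed variant column for
score-change so both alleles bind with different scores. Defaults: one
60-kb chromosome, 3 genes, 10 background SNPs. Every plant is verified at
generation time by scanning the finished genome, and `none` plants are
rejection-sampled until their neighbourhood is genuinely effect-free, so the
truth table is never silently wrong. What a green recovery test therefore
establishes is that the pipeline recovers engineered allele effects under
i.i.d. background; it says nothing about repeat structure, promoter base
composition, linked variants, or real PWM libraries.

A fixed edge-case fixture exercises the three sequence discard rules
(contig edge, N run, catalog/genome reference mismatch) exactly once each.

## Known limitations

- Per-transcript promoters, indels, multiallelic sites and haplotype-aware
  sequences are out of scope by design.
- Chance background matches can add extra true consequence records around a
  planted site; recovery tests assert the planted class is found, not that
  it is unique.
- Score calibration (p-values for matches) is not provided; cutoffs are the
  only significance control.
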