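# rsnpscan

Regulatory SNPs (rSNPs) are single-nucleotide variants in gene promoter
regions that create, destroy, or weaken transcription factor binding sites
(TFBSs), and thereby change how strongly a gene is transcribed. For crop
geneticists interpreting GWAS hits or resequencing data, knowing that a
candidate SNP disrupts a predicted TFBS is often the first mechanistic lead.
`rsnpscan` annotates a whole SNP catalog this way: given a reference genome
(FASTA), gene models (GFF3), variants (VCF or GVF), and a position weight
matrix (PWM) library (TRANSFAC-dialect flat file), it predicts
allele-specific TFBS matches in promoter windows and classifies each SNP's
effect on each site as a **gain**, **loss**, **score-change**, or
**no-change**, storing the results in a queryable four-table SQLite database.

## Method

For each gene, a promoter window of 7.5 kb upstream to 2.5 kb downstream of
the transcription start site (TSS) is built, strand-aware, and every SNP in
it is linked to the gene with a signed distance to the TSS. For each
(SNP, gene-strand) context a 51-bp search sequence is extracted with the
variant at position 26 (reverse-complemented for minus-strand genes), plus a
second copy carrying the alternate allele. Contexts too close to a contig
edge, containing N, or whose genome base contradicts the catalog's reference
allele are discarded and counted.

Both allele sequences are scanned with a MATCH-style scheme. Counts are
regularised with a pseudocount *p* into frequencies
*f(i,b) = (n(i,b)+p) / (Σ_b n(i,b)+4p)*, each position weighted by its
information content *I(i) = Σ_b f(i,b) ln(4 f(i,b))*, and a window *w* scored
by min–max normalisation:

    score = (Current − Min) / (Max − Min),   Current = Σ_i I(i) f(i, w_i)

with Min/Max using the per-position minimum/maximum frequency. The **matrix
similarity score** uses all positions; the **core similarity score** is the
same quantity restricted to the five consecutive most-conserved positions.
A site is reported only if both scores reach the matrix's cutoffs (defaults
0.75 / 0.85 when the library file carries none).

Sites are paired across alleles by (PWM, offset, orientation): present only
for the alternate allele → gain; only for the reference → loss; present for
both with matrix scores differing after rounding to 3 decimals →
score-change; otherwise no-change. A SNP with at least one gain, loss or
score-change is flagged as an rSNP.

## Worked example

The package bundles a deterministic synthetic-fixture generator (toy genome,
genes, SNP catalog, and a small PWM library with planted allele effects):

```sh
rsnpscan fixtures --seed 42 --outdir demo
rsnpscan run --genome demo/genome.fa --gff3 demo/genes.gff3 \
             --snps demo/snps.vcf --pwms demo/pwms.txt --db demo/db.sqlite
rsnpscan stats --db demo/db.sqlite
rsnpscan query --db demo/db.sqlite --snp-ids "pl001 pl002 pl003"
```

The run prints the table sizes of the built store:

    snp_info: 13 rows
    gene_info: 3 rows
    snp_region: 13 rows
    TFBS_results: 3 rows

i.e. 13 catalog SNPs, 3 genes, 13 SNP–promoter links, and 3 stored
consequences. `stats` reports, inside the default −1 kb/+100 bp query
window: 7 promoter SNPs, 3 rSNPs (42.86%), 1.0 rSNPs per promoter, and 1.0
affected TFBSs per rSNP. The query returns one row per affected binding
site, e.g.

    pl001  gene01  -  -656  P$TATA_01  reverse  loss  1.000  1.000  TAT[A]Aa  ref:+,alt:-

— SNP `pl001`, 656 bp upstream of minus-strand `gene01`, destroys a
reverse-orientation TATA-box match (core/matrix similarity 1.000 for the
reference allele, below cutoff for the alternate). Core positions are
upper-case, flanks lower-case, and the variant base is bracketed. Queries by
`--position`, `--region chrom:start-end`, and `--gene` work the same way,
and `rsnpscan export --chrom` produces deterministic chromosome-wise TSVs.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a seeded synthetic input set, runs the complete pipeline
(promoter mapping → sequence extraction → PWM scan → consequence
classification → database build), and prints the resulting table counts and
summary statistics; the JSON output is written to `--out`.
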