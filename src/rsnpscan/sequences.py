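"""51-bp reference/alternate search sequences for each SNP context.

Each variant gets a window of 25 bp on either side of the SNP, giving a 51-bp
sequence with the variant at 1-based position 26; the alternate sequence is
that window with the variant base substituted. For minus-strand gene contexts
the window is reverse-complemented (alleles complemented) so the variant stays
at position 26.

Windows are discarded — and the reason counted — when the SNP sits closer
than 25 bp to a chromosome edge (``too_short``), when the window contains an N
(``contains_N``), or when the genome base at the SNP position does not match
the catalog's reference allele (``ref_mismatch``). The rules are checked in
that order and the first failure is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

from .io import Genome
from .types import (
    CENTER_INDEX_0,
    FLANK,
    SEQ_LENGTH,
    AlleleSequencePair,
    FilterLog,
    SnpRecord,
    SnpRegionLink,
    revcomp,
)

DISCARD_REASONS = ("too_short", "contains_N", "ref_mismatch")


@dataclass(frozen=True)
class Discard:
    """A rejected SNP context, with the first filter rule it failed."""

    snp_id: str
    reason: str


def extract_pair(
    snp: SnpRecord, gene_strand: str, genome: Genome
) -> Union[AlleleSequencePair, Discard]:
    """Build the 51-bp ref/alt sequence pair for one (SNP, gene-strand) context,
    or a :class:`Discard` carrying the first failed filter rule."""
    chrom_len = genome.chrom_length(snp.chrom)
    start = snp.pos - 1 - FLANK
    end = snp.pos + FLANK
    if start < 0 or end > chrom_len:
        return Discard(snp.snp_id, "too_short")
    window = genome.fetch(snp.chrom, start, end)
    if "N" in window:
        return Discard(snp.snp_id, "contains_N")
    if window[CENTER_INDEX_0] != snp.ref_allele:
        return Discard(snp.snp_id, "ref_mismatch")

    ref_seq, alt = window, snp.alt_allele
    if gene_strand == "-":
        ref_seq, alt = revcomp(window), revcomp(alt)
    alt_seq = ref_seq[:CENTER_INDEX_0] + alt + ref_seq[CENTER_INDEX_0 + 1 :]
    return AlleleSequencePair(
        snp_id=snp.snp_id, gene_strand=gene_strand, ref_seq=ref_seq, alt_seq=alt_seq
    )


def extract_pairs(
    snps: Iterable[SnpRecord],
    links: Iterable[SnpRegionLink],
    genes_by_id: dict,
    genome: Genome,
) -> tuple[list[AlleleSequencePair], FilterLog]:
    """Build sequence pairs for every (SNP, gene-strand) context implied by the
    promoter links, deduplicated across genes sharing a strand.

    Scan results depend only on the sequence, which depends only on the gene
    strand, so at most two pairs are built per SNP; consequences are joined
    back to every linked gene later via the snp_region table. Returns the
    pairs and a :class:`FilterLog` of discard counts (a discarded context is
    counted once per (SNP, strand), mirroring the dedup of emitted pairs).
    """
    snps_by_id = {s.snp_id: s for s in snps}
    contexts = sorted(
        {(link.snp_id, genes_by_id[link.gene_id].strand) for link in links}
    )
    pairs: list[AlleleSequencePair] = []
    log = FilterLog()
    for snp_id, strand in contexts:
        result = extract_pair(snps_by_id[snp_id], strand, genome)
        if isinstance(result, Discard):
            log[result.reason] += 1
        else:
            pairs.append(result)
    return pairs, log


def pair_to_fasta_records(pair: AlleleSequencePair) -> list[tuple[str, str]]:
    """(id, sequence) FASTA records for external inspection of one pair."""
    return [
        (f"{pair.snp_id}|{pair.gene_strand}|ref", pair.ref_seq),
        (f"{pair.snp_id}|{pair.gene_strand}|alt", pair.alt_seq),
    ]


def write_pairs_fasta(pairs: Iterable[AlleleSequencePair], path: str) -> None:
    """Export search sequences as FASTA, two records per pair."""
    with open(path, "w") as fh:
        for pair in pairs:
            for name, seq in pair_to_fasta_records(pair):
                fh.write(f">{name}\n{seq}\n")
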