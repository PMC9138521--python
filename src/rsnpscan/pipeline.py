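"""End-to-end orchestration: files in, four-table store out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import consequences as cq
from . import io, promoters, scan, sequences
from .store import RsnpDatabase, build_database
from .types import (
    AlleleSequencePair,
    ConsequenceRecord,
    FilterLog,
    GeneRecord,
    SnpRecord,
    SnpRegionLink,
)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, plus its filter bookkeeping."""

    snps: list[SnpRecord]
    genes: list[GeneRecord]
    links: list[SnpRegionLink]
    pairs: list[AlleleSequencePair]
    consequences: list[ConsequenceRecord]
    catalog_filter_log: FilterLog = field(default_factory=FilterLog)
    sequence_filter_log: FilterLog = field(default_factory=FilterLog)
    db: Optional[RsnpDatabase] = None


def run_pipeline(
    genome_path: str,
    gff3_path: str,
    snp_path: str,
    pwm_path: str,
    db_path: str = ":memory:",
    feature_type: str = "gene",
    upstream_bp: int = promoters.DEFAULT_BUILD_UPSTREAM,
    downstream_bp: int = promoters.DEFAULT_BUILD_DOWNSTREAM,
    pseudocount: float = scan.DEFAULT_PSEUDOCOUNT,
    default_core_cutoff: float = io.DEFAULT_CORE_CUTOFF,
    default_matrix_cutoff: float = io.DEFAULT_MATRIX_CUTOFF,
    orientations: Sequence[str] = scan.ORIENTATIONS,
    keep_no_change: bool = False,
    build_db: bool = True,
) -> PipelineResult:
    """Run the five pipeline stages over a set of input files.

    1. promoter windows (``upstream_bp``/``downstream_bp`` around each TSS)
       and SNP containment links;
    2-3. 51-bp ref/alt search sequences per (SNP, gene-strand) context, with
       edge/N/reference-mismatch discards counted;
    4. PWM scanning of both allele sequences against the library;
    5. consequence classification, restriction to variant-overlapping sites,
       and rSNP flagging; results land in a SQLite store at ``db_path``
       unless ``build_db=False``.
    """
    genome = io.read_genome(genome_path)
    genes = io.read_gene_annotations(gff3_path, feature=feature_type)
    snps, catalog_log = io.read_snp_catalog(snp_path)
    pwms = io.read_pwm_library(
        pwm_path,
        default_core_cutoff=default_core_cutoff,
        default_matrix_cutoff=default_matrix_cutoff,
    )

    windows = [
        promoters.build_window(
            g, upstream_bp, downstream_bp, chrom_length=genome.chrom_length(g.chrom)
        )
        for g in genes
        if g.chrom in genome
    ]
    links = promoters.assign_snps(snps, windows)

    genes_by_id = {g.gene_id: g for g in genes}
    pairs, seq_log = sequences.extract_pairs(snps, links, genes_by_id, genome)

    spwms = [scan.prepare(p, pseudocount=pseudocount) for p in pwms]
    widths = {p.pwm_id: p.width for p in pwms}
    records: list[ConsequenceRecord] = []
    for pair in pairs:
        ref_matches = scan.scan_library(spwms, pair.ref_seq, orientations)
        alt_matches = scan.scan_library(spwms, pair.alt_seq, orientations)
        recs = cq.classify(pair.snp_id, pair.gene_strand, ref_matches, alt_matches)
        records.extend(cq.restrict_to_snp_overlap(recs, widths))

    db = None
    if build_db:
        db = build_database(
            snps,
            genes,
            links,
            records,
            path=db_path,
            keep_no_change=keep_no_change,
            built_upstream_bp=upstream_bp,
            built_downstream_bp=downstream_bp,
        )
    return PipelineResult(
        snps=snps,
        genes=genes,
        links=links,
        pairs=pairs,
        consequences=records,
        catalog_filter_log=catalog_log,
        sequence_filter_log=seq_log,
        db=db,
    )
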