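"""Promoter windows around the TSS and SNP-to-promoter assignment.

A promoter window spans ``upstream_bp`` before to ``downstream_bp`` after the
TSS *in gene orientation*, inclusive at both ends, so an unclipped window
covers ``upstream_bp + downstream_bp + 1`` bases. Distances to the TSS are
signed in gene orientation: negative upstream, 0 at the TSS base, positive
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .types import GeneRecord, SnpRecord, SnpRegionLink

#: promoter window used to build the database: 7.5 kb upstream / 2.5 kb downstream
DEFAULT_BUILD_UPSTREAM = 7500
DEFAULT_BUILD_DOWNSTREAM = 2500
#: default user-facing query window: -1 kb / +100 bp
DEFAULT_QUERY_UPSTREAM = 1000
DEFAULT_QUERY_DOWNSTREAM = 100


@dataclass(frozen=True)
class PromoterWindow:
    """A gene's promoter interval on the genome (0-based half-open), clipped
    to the chromosome."""

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based
    upstream_bp: int
    downstream_bp: int
    start: int
    end: int


def build_window(
    gene: GeneRecord,
    upstream_bp: int = DEFAULT_BUILD_UPSTREAM,
    downstream_bp: int = DEFAULT_BUILD_DOWNSTREAM,
    chrom_length: Optional[int] = None,
) -> PromoterWindow:
    """Build the promoter window for one gene.

    For a plus-strand gene the genomic interval covers
    ``[tss - upstream_bp, tss + downstream_bp]`` (1-based inclusive); for a
    minus-strand gene upstream/downstream are mirrored. The interval is
    clipped to ``[0, chrom_length)`` when a chromosome length is given.
    """
    tss0 = gene.tss - 1
    if gene.strand == "+":
        start, end = tss0 - upstream_bp, tss0 + downstream_bp + 1
    else:
        start, end = tss0 - downstream_bp, tss0 + upstream_bp + 1
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        tss=gene.tss,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        start=start,
        end=max(end, start),
    )


def distance_to_tss(pos: int, tss: int, strand: str) -> int:
    """Signed distance (bp) of 1-based position ``pos`` from the TSS in gene
    orientation."""
    return pos - tss if strand == "+" else tss - pos


def assign_snps(
    snps: Iterable[SnpRecord], windows: Iterable[PromoterWindow]
) -> list[SnpRegionLink]:
    """Link every SNP to every promoter window containing it (many-to-many).

    A SNP inside two overlapping promoters yields two links, one per gene;
    bounds are inclusive on both sides of the window.
    """
    by_chrom: dict[str, list[PromoterWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    links: list[SnpRegionLink] = []
    for snp in snps:
        pos0 = snp.pos - 1
        for w in by_chrom.get(snp.chrom, ()):
            if w.start <= pos0 < w.end:
                links.append(
                    SnpRegionLink(
                        snp_id=snp.snp_id,
                        gene_id=w.gene_id,
                        distance_to_tss=distance_to_tss(snp.pos, w.tss, w.strand),
                    )
                )
    return links


def filter_links_by_window(
    links: Iterable[SnpRegionLink],
    upstream_bp: int = DEFAULT_QUERY_UPSTREAM,
    downstream_bp: int = DEFAULT_QUERY_DOWNSTREAM,
    built_upstream_bp: int = DEFAULT_BUILD_UPSTREAM,
    built_downstream_bp: int = DEFAULT_BUILD_DOWNSTREAM,
) -> list[SnpRegionLink]:
    """Re-filter links to a narrower user window (pure filter, no re-scan).

    The requested window must lie inside the window the links were built with;
    otherwise results would be incomplete and an error is raised.
    """
    if upstream_bp > built_upstream_bp or downstream_bp > built_downstream_bp:
        raise ValueError(
            f"requested window (-{upstream_bp}, +{downstream_bp}) exceeds the built "
            f"window (-{built_upstream_bp}, +{built_downstream_bp}); re-run the scan"
        )
    return [l for l in links if -upstream_bp <= l.distance_to_tss <= downstream_bp]
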