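"""Core domain types shared across the pipeline stages.

Coordinate convention: all *external* formats (GFF3, GVF, VCF, user-facing
positions) are 1-based; conversion to 0-based half-open intervals happens at
the file boundary and everything internal uses 0-based arithmetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

NUCLEOTIDES = "ACGT"
#: index of the variant base inside a 51-bp search sequence (0-based; 1-based 26)
CENTER_INDEX_0 = 25
#: total length of a search sequence: 25 bp flank + SNP + 25 bp flank
SEQ_LENGTH = 51
FLANK = 25

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic single-nucleotide variant in genome coordinates.

    ``pos`` is the 1-based position of the variant base; alleles are reported
    on the genome plus strand, as in VCF/GVF.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele not in ("A", "C", "G", "T"):
                raise ValueError(f"{self.snp_id}: {name} {allele!r} is not a single ACGT base")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its strand and transcription start site (TSS, 1-based).

    The TSS anchors the promoter window: it is the feature start for plus-strand
    genes and the feature end for minus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    name: Optional[str] = None
    source_feature: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: TSS must be >= 1, got {self.tss}")


class FilterLog(Counter):
    """Counts of records removed during catalog/sequence filtering, by reason."""

    def total_removed(self) -> int:
        return sum(self.values())


@dataclass
class Pwm:
    """A positional count matrix over (A, C, G, T) with MATCH-style cutoffs.

    ``counts`` is a width x 4 nonnegative array; ``core_cutoff`` and
    ``matrix_cutoff`` are the minimum core/matrix similarity scores a window
    must reach to be reported as a binding-site match. An optional
    ``core_start`` annotation (0-based) overrides the computed most-conserved
    5-mer core window.
    """

    pwm_id: str
    counts: np.ndarray
    core_cutoff: float
    matrix_cutoff: float
    core_start: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"{self.pwm_id}: counts must be width x 4")
        if self.width < 5:
            raise ValueError(
                f"{self.pwm_id}: matrix width {self.width} < 5, no 5-position core definable"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"{self.pwm_id}: negative count")
        for cutoff, label in ((self.core_cutoff, "core"), (self.matrix_cutoff, "matrix")):
            if not 0.0 <= cutoff <= 1.0:
                raise ValueError(f"{self.pwm_id}: {label} cutoff {cutoff} outside [0, 1]")
        if self.core_start is not None and not 0 <= self.core_start <= self.width - 5:
            raise ValueError(f"{self.pwm_id}: annotated core_start {self.core_start} out of range")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        """Highest-count base at each position (ties resolved to A<C<G<T order)."""
        return "".join(NUCLEOTIDES[i] for i in np.argmax(self.counts, axis=1))


@dataclass(frozen=True)
class SnpRegionLink:
    """A SNP contained in one gene's promoter window.

    ``distance_to_tss`` is signed in gene orientation: negative upstream of the
    TSS, 0 at the TSS base, positive downstream.
    """

    snp_id: str
    gene_id: str
    distance_to_tss: int


@dataclass(frozen=True)
class AlleleSequencePair:
    """The 51-bp reference and alternate search sequences for one SNP context.

    ``gene_strand`` is the strand of the gene(s) whose promoter contains the
    SNP; minus-strand contexts hold the reverse complement of the genomic
    window, with the variant still at 1-based position 26.
    """

    snp_id: str
    gene_strand: str
    ref_seq: str
    alt_seq: str

    def __post_init__(self) -> None:
        if len(self.ref_seq) != SEQ_LENGTH or len(self.alt_seq) != SEQ_LENGTH:
            raise ValueError(f"{self.snp_id}: search sequences must be {SEQ_LENGTH} bp")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diffs != [CENTER_INDEX_0]:
            raise ValueError(
                f"{self.snp_id}: ref/alt sequences must differ exactly at index {CENTER_INDEX_0}"
            )


@dataclass(frozen=True)
class TfbsMatch:
    """One predicted binding site in a 51-bp search sequence.

    ``seq_offset`` is the 0-based start of the match footprint in the scanned
    sequence; ``orientation`` is 'forward' or 'reverse' relative to that
    sequence. ``site_seq`` is the matched substring as aligned to the matrix
    (reverse-complemented for reverse matches) with the core positions in
    upper case and flanks in lower case.
    """

    pwm_id: str
    seq_offset: int
    orientation: str
    core_score: float
    matrix_score: float
    site_seq: str


@dataclass(frozen=True)
class ConsequenceRecord:
    """Classified effect of one SNP on one binding site.

    Scores/sequences for an allele are ``None`` when the site does not pass the
    cutoffs for that allele (gain: no reference site; loss: no alternate site).
    """

    snp_id: str
    gene_strand: str
    pwm_id: str
    seq_offset: int
    orientation: str
    consequence: str
    ref_core_score: Optional[float] = None
    ref_matrix_score: Optional[float] = None
    alt_core_score: Optional[float] = None
    alt_matrix_score: Optional[float] = None
    ref_site_seq: Optional[str] = None
    alt_site_seq: Optional[str] = None


@dataclass(frozen=True)
class RsnpFlag:
    """Per-SNP regulatory flag: a SNP is an rSNP if it gains, loses, or changes
    the score of at least one predicted binding site."""

    snp_id: str
    is_rsnp: bool
    n_affected_tfbs: int
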