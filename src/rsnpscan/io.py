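"""Readers and writers for the external formats the pipeline touches.

FASTA access goes through :mod:`pyfaidx`, GFF3/GVF records through
:mod:`gffutils`, and VCF records through :mod:`pysam`. All coordinates are
converted to the internal 0-based half-open convention at this boundary;
the domain types keep 1-based positions only where the field is defined that
way (``SnpRecord.pos``, ``GeneRecord.tss``).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from gffutils.iterators import DataIterator
from pyfaidx import Fasta

from .types import FilterLog, GeneRecord, Pwm, SnpRecord

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

#: default MATCH-style cutoffs applied when the library file carries none
DEFAULT_CORE_CUTOFF = 0.75
DEFAULT_MATRIX_CUTOFF = 0.85


class Genome:
    """Random-access view of a FASTA genome; slices are 0-based half-open,
    clipped at chromosome bounds, and returned upper-cased."""

    def __init__(self, path: str):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            self._fasta = Fasta(path, as_raw=True, sequence_always_upper=True)
        except ValueError as exc:  # pyfaidx raises on duplicate record names
            raise ValueError(f"invalid FASTA {path}: {exc}") from exc

    @property
    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)``; out-of-range parts are truncated."""
        start = max(start, 0)
        end = min(end, self.chrom_length(chrom))
        if end <= start:
            return ""
        return str(self._fasta[chrom][start:end])

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 1-based position ``pos``."""
        return self.fetch(chrom, pos - 1, pos)


def read_genome(path: str) -> Genome:
    """Open a FASTA genome for random access (builds a .fai index if absent)."""
    return Genome(path)


def read_gene_annotations(path: str, feature: str = "gene") -> list[GeneRecord]:
    """Read gene records of the given feature type from a GFF3 file.

    The TSS is the feature start for plus-strand genes and the feature end for
    minus-strand genes (GFF3 coordinates are 1-based inclusive). Features with
    an unknown strand ('.' or '?') are skipped with a warning; duplicate gene
    IDs are an error.
    """
    genes: list[GeneRecord] = []
    seen: dict[str, int] = {}
    for feat in DataIterator(path):
        if feat.featuretype != feature:
            continue
        gene_id = feat.attributes.get("ID", [None])[0] or feat.id
        if gene_id is None:
            raise ValueError(f"{path}: {feature} feature without ID at {feat.seqid}:{feat.start}")
        if feat.strand not in ("+", "-"):
            logger.warning("skipping %s: unknown strand %r", gene_id, feat.strand)
            continue
        seen[gene_id] = seen.get(gene_id, 0) + 1
        tss = feat.start if feat.strand == "+" else feat.end
        name = feat.attributes.get("Name", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                tss=tss,
                name=name,
                source_feature=feature,
            )
        )
    dupes = sorted(g for g, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate gene IDs in {path}: {', '.join(dupes)}")
    return genes


def _classify_alleles(ref: Optional[str], alts: Sequence[str]) -> Optional[str]:
    """Return the removal reason for a (ref, alts) pair, or None if it is a
    biallelic ACGT SNV. Reasons are checked in a fixed order: indel, then
    multiallelic, then non-ACGT allele."""
    if ref is None:
        return "non_acgt"
    alleles = [ref, *alts]
    if any(len(a) != 1 or a == "-" for a in alleles):
        return "indel"
    if len(alts) > 1:
        return "multiallelic"
    if len(alts) == 0 or any(a not in _ACGT for a in alleles):
        return "non_acgt"
    return None


def synthesize_snp_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """chr-pos-ref-alt identifier for catalogs without SNP IDs (e.g. A01-1093-A-G)."""
    return f"{chrom}-{pos}-{ref}-{alt}"


def _looks_like_gvf(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gvf-version"):
                return True
            if line.startswith("##fileformat=VCF"):
                return False
            if not line.startswith("#") and line.strip():
                return len(line.split("\t")) == 9 and "Variant_seq" in line
    return False


def _read_vcf(path: str) -> Iterable[tuple[Optional[str], str, int, Optional[str], list[str]]]:
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = [a for a in (rec.alts or [])]
            yield rec.id, rec.chrom, rec.pos, rec.ref, alts


def _read_gvf(path: str) -> Iterable[tuple[Optional[str], str, int, Optional[str], list[str]]]:
    for feat in DataIterator(path):
        ref = feat.attributes.get("Reference_seq", [None])[0]
        variant_seqs = feat.attributes.get("Variant_seq", [])
        # GVF lists the observed alleles; the reference allele may be among them
        alts = [v for v in variant_seqs if v != ref]
        snp_id = feat.attributes.get("ID", [None])[0]
        yield snp_id, feat.seqid, feat.start, ref, alts


def read_snp_catalog(path: str) -> tuple[list[SnpRecord], FilterLog]:
    """Read a SNP catalog (VCF or GVF), keeping only biallelic ACGT SNVs.

    Insertions/deletions, records with more than one alternate allele, and
    records with non-ACGT alleles are removed and counted in the returned
    :class:`FilterLog`; unparseable records are counted, never silently
    dropped. Records without an ID get a synthesized chr-pos-ref-alt ID.
    """
    reader = _read_gvf if _looks_like_gvf(path) else _read_vcf
    kept: list[SnpRecord] = []
    log = FilterLog()
    for item in reader(path):
        try:
            snp_id, chrom, pos, ref, alts = item
            reason = _classify_alleles(ref, alts)
            if reason is not None:
                log[reason] += 1
                continue
            alt = alts[0]
            if not snp_id or snp_id == ".":
                snp_id = synthesize_snp_id(chrom, pos, ref, alt)
            kept.append(SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt))
        except (ValueError, KeyError, IndexError, TypeError) as exc:
            logger.warning("skipping unparseable variant record: %s", exc)
            log["unparseable"] += 1
    return kept, log


def filter_snp_records(records: Iterable[SnpRecord]) -> tuple[list[SnpRecord], FilterLog]:
    """Re-apply the catalog filter to in-memory records (idempotent on any
    catalog produced by :func:`read_snp_catalog`)."""
    kept: list[SnpRecord] = []
    log = FilterLog()
    for rec in records:
        reason = _classify_alleles(rec.ref_allele, [rec.alt_allele])
        if reason is None:
            kept.append(rec)
        else:
            log[reason] += 1
    return kept, log


# ---------------------------------------------------------------------------
# TRANSFAC-dialect PWM flat file
# ---------------------------------------------------------------------------
#
# Blocks are separated by '//'. Within a block:
#   ID  P$NAME_01                    matrix identifier
#   P0      A      C      G      T   column order header
#   01     10      0      0      0   per-position counts (row label ignored)
#   ...
#   CC  core_cutoff=0.75 matrix_cutoff=0.85 core_start=2   (all optional)
# Unrecognised two-letter tags are ignored, so real TRANSFAC exports parse.


def read_pwm_library(
    path: str,
    default_core_cutoff: float = DEFAULT_CORE_CUTOFF,
    default_matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF,
) -> list[Pwm]:
    """Parse a TRANSFAC-dialect matrix flat file into :class:`Pwm` objects.

    Per-matrix cutoffs (and an optional annotated core start) are read from
    ``CC key=value`` lines; matrices without them get the given defaults.
    Matrices narrower than 5 positions or with negative counts are rejected.
    """
    pwms: list[Pwm] = []
    block: dict = {}

    def flush() -> None:
        if not block:
            return
        if "id" not in block:
            raise ValueError(f"{path}: matrix block without ID line")
        rows = block.get("rows", [])
        if not rows:
            raise ValueError(f"{path}: matrix {block['id']} has no count rows")
        order = block.get("order", list("ACGT"))
        perm = [order.index(b) for b in "ACGT"]
        counts = np.array(rows, dtype=float)[:, perm]
        pwms.append(
            Pwm(
                pwm_id=block["id"],
                counts=counts,
                core_cutoff=block.get("core_cutoff", default_core_cutoff),
                matrix_cutoff=block.get("matrix_cutoff", default_matrix_cutoff),
                core_start=block.get("core_start"),
            )
        )
        block.clear()

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("//"):
                flush()
                continue
            if not line.strip():
                continue
            tag, _, rest = line.partition(" ")
            tag = tag.strip()
            rest = rest.strip()
            if tag == "ID":
                block["id"] = rest
            elif tag == "P0":
                order = rest.split()
                if sorted(order) != ["A", "C", "G", "T"]:
                    raise ValueError(f"{path}: bad P0 column header {rest!r}")
                block["order"] = order
            elif tag == "CC":
                for token in rest.split():
                    key, _, value = token.partition("=")
                    if key in ("core_cutoff", "matrix_cutoff"):
                        block[key] = float(value)
                    elif key == "core_start":
                        block[key] = int(value)
            elif tag.isdigit():
                fields = rest.split()
                block.setdefault("rows", []).append([float(v) for v in fields[:4]])
            # any other two-letter tag (AC, NA, DE, BF, XX, ...) is ignored
    flush()
    return pwms


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_pwm_library(pwms: Iterable[Pwm], path: str) -> None:
    """Write matrices back to the TRANSFAC-dialect flat file (exact round trip
    of counts, cutoffs, and any annotated core start)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.pwm_id}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.counts, start=1):
                cells = "".join(f"{_fmt_count(v):>7}" for v in row)
                fh.write(f"{i:02d}{cells}\n")
            cc = f"CC core_cutoff={pwm.core_cutoff!r} matrix_cutoff={pwm.matrix_cutoff!r}"
            if pwm.core_start is not None:
                cc += f" core_start={pwm.core_start}"
            fh.write(cc + "\n//\n")
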