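"""Classification of each SNP's effect on each predicted binding site.

Reference- and alternate-allele match sets from the same 51-bp sequence pair
are paired by positional identity (pwm_id, seq_offset, orientation) — the only
identity under which gain/loss is well defined for a single-base substitution:

* gain — the site passes the cutoffs only for the alternate allele;
* loss — the site passes only for the reference allele;
* score_change — the site passes for both alleles with differing matrix
  similarity (compared after rounding to 3 decimals, the precision MATCH-style
  scores are reported at);
* no_change — the site passes for both alleles with equal rounded score.

A SNP is flagged as regulatory (rSNP) when at least one of its sites is a
gain, loss or score_change.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .types import CENTER_INDEX_0, ConsequenceRecord, RsnpFlag, TfbsMatch

#: decimals at which matrix scores are compared for score_change vs no_change
SCORE_DECIMALS = 3

AFFECTING = frozenset({"gain", "loss", "score_change"})


def _keyed(matches: Iterable[TfbsMatch], allele: str) -> dict:
    out: dict[tuple, TfbsMatch] = {}
    for m in matches:
        key = (m.pwm_id, m.seq_offset, m.orientation)
        if key in out:
            raise ValueError(f"duplicate {allele} match for site {key}: scanner contract violation")
        out[key] = m
    return out


def classify(
    snp_id: str,
    gene_strand: str,
    ref_matches: Iterable[TfbsMatch],
    alt_matches: Iterable[TfbsMatch],
    score_decimals: int = SCORE_DECIMALS,
) -> list[ConsequenceRecord]:
    """Pair the two allele match sets and emit one consequence per site key."""
    ref = _keyed(ref_matches, "ref")
    alt = _keyed(alt_matches, "alt")
    records: list[ConsequenceRecord] = []
    for key in sorted(ref.keys() | alt.keys()):
        pwm_id, seq_offset, orientation = key
        r, a = ref.get(key), alt.get(key)
        if r is not None and a is None:
            consequence = "loss"
        elif r is None and a is not None:
            consequence = "gain"
        elif round(r.matrix_score, score_decimals) != round(a.matrix_score, score_decimals):
            consequence = "score_change"
        else:
            consequence = "no_change"
        records.append(
            ConsequenceRecord(
                snp_id=snp_id,
                gene_strand=gene_strand,
                pwm_id=pwm_id,
                seq_offset=seq_offset,
                orientation=orientation,
                consequence=consequence,
                ref_core_score=r.core_score if r else None,
                ref_matrix_score=r.matrix_score if r else None,
                alt_core_score=a.core_score if a else None,
                alt_matrix_score=a.matrix_score if a else None,
                ref_site_seq=r.site_seq if r else None,
                alt_site_seq=a.site_seq if a else None,
            )
        )
    return records


def restrict_to_snp_overlap(
    records: Iterable[ConsequenceRecord], pwm_widths: Mapping[str, int]
) -> list[ConsequenceRecord]:
    """Keep only records whose site footprint covers the variant base.

    Footprints not covering index 25 (0-based) are identical strings for both
    alleles, so any gain/loss/score_change record necessarily overlaps the
    SNP; this restriction only prunes no_change records, guaranteeing that
    every stored consequence is attributable to the variant.
    """
    kept = []
    for rec in records:
        width = pwm_widths[rec.pwm_id]
        if rec.seq_offset <= CENTER_INDEX_0 < rec.seq_offset + width:
            kept.append(rec)
    return kept


def flag_rsnps(records: Iterable[ConsequenceRecord]) -> list[RsnpFlag]:
    """Flag each SNP seen in the records; one flag per SNP.

    ``n_affected_tfbs`` counts distinct affected sites across both gene-strand
    contexts, keyed by (pwm_id, seq_offset, orientation, gene_strand).
    """
    affected: dict[str, set] = defaultdict(set)
    seen: set[str] = set()
    for rec in records:
        seen.add(rec.snp_id)
        if rec.consequence in AFFECTING:
            affected[rec.snp_id].add(
                (rec.pwm_id, rec.seq_offset, rec.orientation, rec.gene_strand)
            )
    return [
        RsnpFlag(snp_id=s, is_rsnp=len(affected[s]) >= 1, n_affected_tfbs=len(affected[s]))
        for s in sorted(seen)
    ]
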