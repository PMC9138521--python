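"""Four-table relational store for regulatory-SNP results, with query modes
and summary statistics.

The schema mirrors the pipeline's result structure: ``snp_info`` (one row per
catalog SNP, with its regulatory flag), ``gene_info`` (one row per annotated
gene), ``snp_region`` (the many-to-many SNP-promoter containment links with
signed TSS distances), and ``TFBS_results`` (one row per classified
SNP-binding-site consequence). The store is a single SQLite file; all exports
use a deterministic row ordering (chrom, pos, pwm_id, offset) so repeated
builds from identical inputs are byte-identical.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .consequences import AFFECTING, flag_rsnps
from .promoters import (
    DEFAULT_BUILD_DOWNSTREAM,
    DEFAULT_BUILD_UPSTREAM,
    DEFAULT_QUERY_DOWNSTREAM,
    DEFAULT_QUERY_UPSTREAM,
)
from .types import ConsequenceRecord, GeneRecord, SnpRecord, SnpRegionLink

TABLE_NAMES = ("snp_info", "gene_info", "snp_region", "TFBS_results")

#: proximal promoter histogram: [-750, +250) in 50-bp bins
HIST_LO, HIST_HI, HIST_BIN = -750, 250, 50

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE snp_info (
    snp_id TEXT PRIMARY KEY,
    chrom TEXT NOT NULL,
    pos INTEGER NOT NULL,
    ref_allele TEXT NOT NULL,
    alt_allele TEXT NOT NULL,
    is_rsnp INTEGER NOT NULL DEFAULT 0,
    n_affected_tfbs INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE gene_info (
    gene_id TEXT PRIMARY KEY,
    name TEXT,
    chrom TEXT NOT NULL,
    strand TEXT NOT NULL,
    tss INTEGER NOT NULL,
    source_feature TEXT NOT NULL
);
CREATE TABLE snp_region (
    snp_id TEXT NOT NULL REFERENCES snp_info(snp_id),
    gene_id TEXT NOT NULL REFERENCES gene_info(gene_id),
    distance_to_tss INTEGER NOT NULL,
    PRIMARY KEY (snp_id, gene_id)
);
CREATE TABLE TFBS_results (
    snp_id TEXT NOT NULL REFERENCES snp_info(snp_id),
    gene_strand TEXT NOT NULL,
    pwm_id TEXT NOT NULL,
    seq_offset INTEGER NOT NULL,
    orientation TEXT NOT NULL,
    consequence TEXT NOT NULL,
    ref_core_score REAL,
    ref_matrix_score REAL,
    alt_core_score REAL,
    alt_matrix_score REAL,
    ref_site_seq TEXT,
    alt_site_seq TEXT,
    PRIMARY KEY (snp_id, gene_strand, pwm_id, seq_offset, orientation)
);
CREATE INDEX idx_region_gene ON snp_region(gene_id);
CREATE INDEX idx_snp_pos ON snp_info(chrom, pos);
"""

_RESULT_QUERY = """
SELECT s.snp_id, s.chrom, s.pos, s.ref_allele, s.alt_allele,
       r.gene_id, g.name AS gene_name, t.gene_strand, r.distance_to_tss,
       t.pwm_id, t.seq_offset, t.orientation, t.consequence,
       t.ref_core_score, t.ref_matrix_score, t.alt_core_score, t.alt_matrix_score,
       t.ref_site_seq, t.alt_site_seq
FROM TFBS_results t
JOIN snp_info s ON s.snp_id = t.snp_id
JOIN snp_region r ON r.snp_id = t.snp_id
JOIN gene_info g ON g.gene_id = r.gene_id AND g.strand = t.gene_strand
WHERE r.distance_to_tss BETWEEN -:up AND :down
"""

_ORDER = (
    " ORDER BY s.chrom, s.pos, t.pwm_id, t.seq_offset, t.orientation,"
    " t.gene_strand, r.gene_id"
)


@dataclass
class SummaryStats:
    """Window-restricted summary of a built database.

    ``rsnps_per_promoter`` averages over *all* annotated genes (genes without
    promoter SNPs contribute zero); ``pct_rsnp`` is the percentage of promoter
    SNPs flagged regulatory; ``tss_histogram`` counts rSNP-gene links per
    50-bp bin over [-750, +250), left-closed right-open.
    """

    n_snps: int = 0
    n_genes: int = 0
    n_rsnps: int = 0
    rsnps_per_promoter: float = 0.0
    pct_rsnp: float = 0.0
    tfbs_per_rsnp: float = 0.0
    tss_histogram: list[int] = field(
        default_factory=lambda: [0] * ((HIST_HI - HIST_LO) // HIST_BIN)
    )

    @staticmethod
    def bin_edges() -> list[int]:
        return list(range(HIST_LO, HIST_HI + HIST_BIN, HIST_BIN))


def _mark_snp(site: str, snp_index: int) -> str:
    """Bracket the variant base inside a displayed site sequence (the web
    interface shows it in red; TSV has no colour)."""
    if not 0 <= snp_index < len(site):
        return site
    return site[:snp_index] + "[" + site[snp_index] + "]" + site[snp_index + 1 :]


def format_site_display(row: pd.Series) -> str:
    """Human-readable sequence column: core upper-case, flanks lower-case,
    variant base bracketed; both alleles shown (ref/alt) when both bind."""
    parts = []
    for which in ("ref", "alt"):
        site = row[f"{which}_site_seq"]
        if site is None or (isinstance(site, float) and np.isnan(site)):
            continue
        width = len(site)
        inner = 25 - row["seq_offset"]
        if row["orientation"] == "reverse":
            inner = width - 1 - inner
        parts.append(_mark_snp(site, int(inner)))
    return "/".join(parts)


def _binding_site_display(row: pd.Series) -> str:
    present = {"gain": ("-", "+"), "loss": ("+", "-")}.get(row["consequence"], ("+", "+"))
    return f"ref:{present[0]},alt:{present[1]}"


class RsnpDatabase:
    """Handle over a built SQLite store. Use :func:`build_database` to create
    one, or ``RsnpDatabase(path)`` to open an existing file."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- construction -------------------------------------------------------

    def _init_schema(self) -> None:
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "RsnpDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def table_names(self) -> tuple[str, ...]:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name != 'meta'"
        ).fetchall()
        found = {r[0] for r in rows}
        return tuple(t for t in TABLE_NAMES if t in found)

    def table_counts(self) -> dict[str, int]:
        return {
            t: self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in self.table_names
        }

    def meta(self, key: str) -> Optional[str]:
        row = self.conn.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return row[0] if row else None

    @property
    def built_window(self) -> tuple[int, int]:
        return int(self.meta("built_upstream_bp")), int(self.meta("built_downstream_bp"))

    # -- queries ------------------------------------------------------------

    def _check_window(self, upstream_bp: int, downstream_bp: int) -> None:
        up, down = self.built_window
        if upstream_bp > up or downstream_bp > down:
            raise ValueError(
                f"query window (-{upstream_bp}, +{downstream_bp}) exceeds the built "
                f"window (-{up}, +{down})"
            )

    def _run_result_query(
        self, extra_where: str, params: dict, upstream_bp: int, downstream_bp: int
    ) -> pd.DataFrame:
        self._check_window(upstream_bp, downstream_bp)
        sql = _RESULT_QUERY + extra_where + _ORDER
        df = pd.read_sql_query(
            sql, self.conn, params={"up": upstream_bp, "down": downstream_bp, **params}
        )
        if len(df):
            df["sequence"] = df.apply(format_site_display, axis=1)
            df["binding_site"] = df.apply(_binding_site_display, axis=1)
        else:
            df["sequence"] = pd.Series(dtype=str)
            df["binding_site"] = pd.Series(dtype=str)
        return df

    def query(
        self,
        mode: str,
        args: str,
        upstream_bp: int = DEFAULT_QUERY_UPSTREAM,
        downstream_bp: int = DEFAULT_QUERY_DOWNSTREAM,
    ) -> pd.DataFrame:
        """Query joined results by ``snp_ids``, ``position``, ``region`` or
        ``gene``, re-filtered to the given user window.

        ``snp_ids`` takes a whitespace-separated ID list (duplicates are
        collapsed); ``position`` takes ``chrom:pos``; ``region`` takes
        ``chrom:start-end`` (1-based inclusive); ``gene`` matches a gene ID or
        name. Unknown IDs yield an empty result, not an error.
        """
        if mode == "snp_ids":
            ids = sorted(set(args.split()))
            placeholders = ",".join(f":id{i}" for i in range(len(ids)))
            params = {f"id{i}": v for i, v in enumerate(ids)}
            where = f" AND t.snp_id IN ({placeholders})" if ids else " AND 0"
        elif mode == "position":
            chrom, _, pos = args.partition(":")
            where = " AND s.chrom = :chrom AND s.pos = :pos"
            params = {"chrom": chrom, "pos": int(pos)}
        elif mode == "region":
            chrom, _, span = args.partition(":")
            start, _, end = span.partition("-")
            where = " AND s.chrom = :chrom AND s.pos BETWEEN :start AND :end"
            params = {"chrom": chrom, "start": int(start), "end": int(end)}
        elif mode == "gene":
            where = " AND (r.gene_id = :gene OR g.name = :gene)"
            params = {"gene": args}
        else:
            raise ValueError(f"unknown query mode {mode!r}")
        return self._run_result_query(where, params, upstream_bp, downstream_bp)

    def export_chromosome(
        self,
        chrom: str,
        upstream_bp: int = DEFAULT_QUERY_UPSTREAM,
        downstream_bp: int = DEFAULT_QUERY_DOWNSTREAM,
    ) -> pd.DataFrame:
        """Chromosome-wise bulk export of joined results (same columns and
        window semantics as :meth:`query`)."""
        return self._run_result_query(
            " AND s.chrom = :chrom", {"chrom": chrom}, upstream_bp, downstream_bp
        )

    def chromosomes(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT DISTINCT chrom FROM snp_info ORDER BY chrom"
            ).fetchall()
        ]

    def export_tsv(self, df: pd.DataFrame, path: str) -> None:
        """Write an export frame as TSV with scores at 3 decimals (the
        precision MATCH-style scores are reported at)."""
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")

    # -- statistics ---------------------------------------------------------

    def summarize(
        self,
        upstream_bp: int = DEFAULT_QUERY_UPSTREAM,
        downstream_bp: int = DEFAULT_QUERY_DOWNSTREAM,
    ) -> SummaryStats:
        """Compute the summary statistics inside the given promoter window."""
        self._check_window(upstream_bp, downstream_bp)
        n_genes = self.conn.execute("SELECT COUNT(*) FROM gene_info").fetchone()[0]
        links = pd.read_sql_query(
            "SELECT r.snp_id, r.gene_id, r.distance_to_tss, s.is_rsnp, s.n_affected_tfbs "
            "FROM snp_region r JOIN snp_info s ON s.snp_id = r.snp_id "
            "WHERE r.distance_to_tss BETWEEN ? AND ?",
            self.conn,
            params=(-upstream_bp, downstream_bp),
        )
        stats = SummaryStats(n_genes=n_genes)
        if n_genes == 0 and links.empty:
            return stats
        per_snp = links.drop_duplicates("snp_id")
        stats.n_snps = len(per_snp)
        rsnps = per_snp[per_snp["is_rsnp"] == 1]
        stats.n_rsnps = len(rsnps)
        if n_genes:
            rsnp_links = links[links["is_rsnp"] == 1]
            stats.rsnps_per_promoter = float(len(rsnp_links)) / n_genes
        if stats.n_snps:
            stats.pct_rsnp = 100.0 * stats.n_rsnps / stats.n_snps
        if stats.n_rsnps:
            stats.tfbs_per_rsnp = float(rsnps["n_affected_tfbs"].mean())
        d = links.loc[links["is_rsnp"] == 1, "distance_to_tss"]
        d = d[(d >= HIST_LO) & (d < HIST_HI)]
        nbins = (HIST_HI - HIST_LO) // HIST_BIN
        counts = np.bincount(((d - HIST_LO) // HIST_BIN).astype(int), minlength=nbins)
        stats.tss_histogram = [int(c) for c in counts]
        return stats

    def plot_tss_histogram(self, stats: SummaryStats, path: str) -> None:
        """Bar plot of the rSNP distance-to-TSS histogram (PNG/PDF by suffix)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        edges = SummaryStats.bin_edges()
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.bar(edges[:-1], stats.tss_histogram, width=HIST_BIN, align="edge",
               edgecolor="black", color="#4878a8")
        ax.set_xlabel("distance to TSS (bp)")
        ax.set_ylabel("number of rSNPs")
        ax.axvline(0, color="red", linestyle="--", linewidth=1)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_database(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    links: Sequence[SnpRegionLink],
    consequences: Sequence[ConsequenceRecord],
    path: str = ":memory:",
    keep_no_change: bool = False,
    built_upstream_bp: int = DEFAULT_BUILD_UPSTREAM,
    built_downstream_bp: int = DEFAULT_BUILD_DOWNSTREAM,
) -> RsnpDatabase:
    """Materialise one pipeline run into the four-table store.

    Referential integrity is enforced: every link must reference a known SNP
    and gene, and every consequence must reference a known SNP that is linked
    to at least one gene on its gene strand; violations abort with the
    offending row. By default only gain/loss/score_change consequences are
    persisted; ``keep_no_change=True`` retains the no_change rows as well.
    """
    snp_ids = {s.snp_id for s in snps}
    gene_ids = {g.gene_id for g in genes}
    strand_by_gene = {g.gene_id: g.strand for g in genes}
    linked_strands: dict[str, set] = {}
    for link in links:
        if link.snp_id not in snp_ids:
            raise ValueError(f"snp_region references unknown SNP: {link}")
        if link.gene_id not in gene_ids:
            raise ValueError(f"snp_region references unknown gene: {link}")
        linked_strands.setdefault(link.snp_id, set()).add(strand_by_gene[link.gene_id])
    for rec in consequences:
        if rec.snp_id not in snp_ids:
            raise ValueError(f"TFBS_results references unknown SNP: {rec}")
        if rec.gene_strand not in linked_strands.get(rec.snp_id, ()):
            raise ValueError(
                f"TFBS_results row has no snp_region link on its gene strand: {rec}"
            )

    flags = {f.snp_id: f for f in flag_rsnps(consequences)}
    stored = [
        r for r in consequences if keep_no_change or r.consequence in AFFECTING
    ]

    db = RsnpDatabase(path)
    db._init_schema()
    with db.conn:
        db.conn.executemany(
            "INSERT INTO meta VALUES (?, ?)",
            [
                ("built_upstream_bp", str(built_upstream_bp)),
                ("built_downstream_bp", str(built_downstream_bp)),
                ("keep_no_change", str(int(keep_no_change))),
            ],
        )
        try:
            db.conn.executemany(
                "INSERT INTO snp_info VALUES (?,?,?,?,?,?,?)",
                [
                    (
                        s.snp_id, s.chrom, s.pos, s.ref_allele, s.alt_allele,
                        int(flags[s.snp_id].is_rsnp) if s.snp_id in flags else 0,
                        flags[s.snp_id].n_affected_tfbs if s.snp_id in flags else 0,
                    )
                    for s in snps
                ],
            )
        except sqlite3.IntegrityError as exc:
            raise ValueError(f"duplicate snp_id in snp_info: {exc}") from exc
        db.conn.executemany(
            "INSERT INTO gene_info VALUES (?,?,?,?,?,?)",
            [
                (g.gene_id, g.name, g.chrom, g.strand, g.tss, g.source_feature)
                for g in genes
            ],
        )
        db.conn.executemany(
            "INSERT INTO snp_region VALUES (?,?,?)",
            [(l.snp_id, l.gene_id, l.distance_to_tss) for l in links],
        )
        db.conn.executemany(
            "INSERT INTO TFBS_results VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            [
                (
                    r.snp_id, r.gene_strand, r.pwm_id, r.seq_offset, r.orientation,
                    r.consequence, r.ref_core_score, r.ref_matrix_score,
                    r.alt_core_score, r.alt_matrix_score, r.ref_site_seq, r.alt_site_seq,
                )
                for r in stored
            ],
        )
    return db
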