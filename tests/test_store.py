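"""Four-table store: integrity, query modes, exports, and summary statistics."""

import numpy as np
import pytest

from rsnpscan.store import TABLE_NAMES, RsnpDatabase, SummaryStats, build_database
from rsnpscan.types import ConsequenceRecord, GeneRecord, SnpRecord, SnpRegionLink


def snp(snp_id, pos, chrom="chr1"):
    return SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, ref_allele="A", alt_allele="G")


def gene(gene_id, tss, strand="+", chrom="chr1", name=None):
    return GeneRecord(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, name=name)


def cons(snp_id, consequence="loss", strand="+", pwm_id="P$A_01", offset=22,
         orientation="forward"):
    kwargs = {}
    if consequence != "gain":
        kwargs.update(ref_core_score=0.9, ref_matrix_score=0.93, ref_site_seq="acGTCAt")
    if consequence != "loss":
        kwargs.update(alt_core_score=0.9, alt_matrix_score=0.91, alt_site_seq="acGTGAt")
    return ConsequenceRecord(
        snp_id=snp_id, gene_strand=strand, pwm_id=pwm_id, seq_offset=offset,
        orientation=orientation, consequence=consequence, **kwargs,
    )


@pytest.fixture
def toy_db():
    snps = [snp("s1", 9500), snp("s2", 9900), snp("s3", 20_500)]
    genes = [gene("gA", 10_000, "+", name="alpha"), gene("gB", 20_000, "-", name="beta")]
    links = [
        SnpRegionLink("s1", "gA", -500),
        SnpRegionLink("s2", "gA", -100),
        SnpRegionLink("s3", "gB", -500),
        SnpRegionLink("s1", "gB", 10_500 - 500 * 21),  # s1 also near gB? keep simple:
    ]
    # replace the awkward fourth link with a real overlap case
    links[3] = SnpRegionLink("s2", "gB", 10_100)
    consequences = [
        cons("s1", "loss"),
        cons("s2", "score_change"),
        cons("s3", "gain", strand="-"),
        cons("s2", "no_change", pwm_id="P$B_01", offset=24),
    ]
    return snps, genes, links, consequences


class TestBuild:
    def test_table_counts(self, toy_db):
        snps, genes, links, consequences = toy_db
        db = build_database(snps, genes, links, consequences)
        # no_change rows are not persisted by default
        assert db.table_counts() == {
            "snp_info": 3, "gene_info": 2, "snp_region": 4, "TFBS_results": 3,
        }
        assert db.table_names == TABLE_NAMES

    def test_keep_no_change(self, toy_db):
        snps, genes, links, consequences = toy_db
        db = build_database(snps, genes, links, consequences, keep_no_change=True)
        assert db.table_counts()["TFBS_results"] == 4

    def test_duplicate_snp_id_rejected(self, toy_db):
        snps, genes, links, consequences = toy_db
        with pytest.raises(ValueError, match="duplicate"):
            build_database(snps + [snp("s1", 123)], genes, links, consequences)

    def test_unknown_reference_rejected(self, toy_db):
        snps, genes, links, consequences = toy_db
        with pytest.raises(ValueError, match="unknown gene"):
            build_database(snps, genes, links + [SnpRegionLink("s1", "ghost", 0)], consequences)
        with pytest.raises(ValueError, match="unknown SNP"):
            build_database(snps, genes, links, consequences + [cons("ghost")])

    def test_consequence_needs_link_on_its_strand(self, toy_db):
        snps, genes, links, consequences = toy_db
        bad = cons("s3", "gain", strand="+")  # s3 only links to minus-strand gB
        with pytest.raises(ValueError, match="gene strand"):
            build_database(snps, genes, links, consequences + [bad])

    def test_rsnp_flags_materialized(self, toy_db):
        snps, genes, links, consequences = toy_db
        db = build_database(snps, genes, links, consequences)
        rows = dict(
            db.conn.execute("SELECT snp_id, is_rsnp FROM snp_info").fetchall()
        )
        assert rows == {"s1": 1, "s2": 1, "s3": 1}

    def test_rebuild_is_byte_identical(self, toy_db, tmp_path):
        snps, genes, links, consequences = toy_db
        outs = []
        for i in (1, 2):
            db = build_database(snps, genes, links, consequences)
            out = tmp_path / f"export{i}.tsv"
            db.export_tsv(db.export_chromosome("chr1"), str(out))
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]


class TestQuery:
    def test_snp_id_retrieval(self, toy_db):
        db = build_database(*toy_db)
        df = db.query("snp_ids", "s1")
        assert len(df) == 1
        row = df.iloc[0]
        assert row["consequence"] == "loss"
        assert row["pwm_id"] == "P$A_01"
        assert row["binding_site"] == "ref:+,alt:-"
        # core upper-case, SNP base bracketed (site offset 22, width 7 covers 25)
        assert "[" in row["sequence"]

    def test_multi_id_union_without_duplicates(self, toy_db):
        db = build_database(*toy_db)
        df = db.query("snp_ids", "s1 s2 s2")
        assert sorted(df["snp_id"].unique()) == ["s1", "s2"]
        assert len(df) == len(df.drop_duplicates())

    def test_unknown_id_empty_not_error(self, toy_db):
        db = build_database(*toy_db)
        assert db.query("snp_ids", "nope").empty
        assert db.query("gene", "nope").empty

    def test_position_and_gene_modes(self, toy_db):
        db = build_database(*toy_db)
        assert db.query("position", "chr1:9500")["snp_id"].tolist() == ["s1"]
        by_id = db.query("gene", "gA")
        by_name = db.query("gene", "alpha")
        assert by_id.equals(by_name)
        assert set(by_id["snp_id"]) == {"s1", "s2"}

    def test_window_refilter(self, toy_db):
        db = build_database(*toy_db)
        # s1 is at distance -500: outside a -100/+100 window
        assert db.query("snp_ids", "s1", upstream_bp=100).empty
        assert len(db.query("snp_ids", "s1", upstream_bp=1000)) == 1

    def test_window_wider_than_build_errors(self, toy_db):
        db = build_database(*toy_db)
        with pytest.raises(ValueError, match="exceeds"):
            db.query("snp_ids", "s1", upstream_bp=8000)

    def test_region_query_equals_chromosome_export(self, toy_db):
        db = build_database(*toy_db)
        region = db.query("region", "chr1:1-999999")
        export = db.export_chromosome("chr1")
        assert region.equals(export)
        # union of per-chromosome exports covers all windowed TFBS joins
        assert len(export) == len(db.query("snp_ids", "s1 s2 s3"))


class TestSummarize:
    def test_mean_over_all_genes(self):
        # gene A promoter holds 3 rSNPs, gene B none -> 1.5 per promoter
        snps = [snp(f"s{i}", 9000 + i) for i in range(3)] + [snp("q", 9500)]
        genes = [gene("gA", 9600), gene("gB", 50_000)]
        links = [SnpRegionLink(f"s{i}", "gA", 9000 + i - 9600) for i in range(3)]
        links.append(SnpRegionLink("q", "gA", -100))
        consequences = [cons(f"s{i}", "loss") for i in range(3)]
        db = build_database(snps, genes, links, consequences)
        stats = db.summarize()
        assert stats.rsnps_per_promoter == pytest.approx(1.5)
        assert stats.n_snps == 4  # promoter SNPs in window
        assert stats.n_rsnps == 3
        assert stats.pct_rsnp == pytest.approx(75.0)
        assert stats.tfbs_per_rsnp == pytest.approx(1.0)

    def test_pct_rsnp_ten_percent(self):
        snps = [snp(f"s{i}", 9000 + i) for i in range(10)]
        genes = [gene("gA", 9600)]
        links = [SnpRegionLink(s.snp_id, "gA", s.pos - 9600) for s in snps]
        consequences = [cons("s0", "gain")]
        db = build_database(snps, genes, links, consequences)
        assert db.summarize().pct_rsnp == pytest.approx(10.0)

    def test_bin_edges_left_closed(self):
        # distance -749 belongs to bin [-750, -700); -750 and +249 are inside,
        # +250 is out
        snps = [snp("a", 100), snp("b", 101), snp("c", 102), snp("d", 103)]
        genes = [gene("gA", 849, "+")]  # distances: -749, -748, -747, -746
        links = [
            SnpRegionLink("a", "gA", -749),
            SnpRegionLink("b", "gA", -750),
            SnpRegionLink("c", "gA", 249),
            SnpRegionLink("d", "gA", 250),
        ]
        consequences = [cons(x, "loss") for x in "abcd"]
        db = build_database(snps, genes, links, consequences, built_upstream_bp=7500)
        stats = db.summarize(upstream_bp=7500, downstream_bp=2500)
        hist = stats.tss_histogram
        assert sum(hist) == 3  # d at +250 is outside [-750, +250)
        assert hist[0] == 2  # -750 and -749 both in the first bin
        assert hist[-1] == 1  # +249 in the last bin [200, 250)

    def test_empty_database_all_zero(self):
        db = build_database([], [], [], [])
        stats = db.summarize()
        assert stats == SummaryStats()

    def test_narrowing_window_never_increases_counts(self, toy_db):
        db = build_database(*toy_db)
        wide = db.summarize(1000, 100)
        narrow = db.summarize(200, 50)
        assert narrow.n_snps <= wide.n_snps
        assert narrow.n_rsnps <= wide.n_rsnps
        assert sum(narrow.tss_histogram) <= sum(wide.tss_histogram)
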