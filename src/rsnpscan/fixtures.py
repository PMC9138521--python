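"""Self-contained synthetic fixtures with known ground truth.

The generator writes a toy genome (FASTA), gene annotation (GFF3), SNP catalog
(VCF), PWM library (TRANSFAC-dialect flat file) and a truth table (TSV) into a
directory. Background sequence is i.i.d. with a configurable GC content;
planted variant/binding-site constructions are built analytically from the
bundled matrices (consensus vs. consensus-breaking base for gain/loss, a
mixed-frequency column for score-change) and verified at generation time by
scanning both allele sequences, so the truth table is never silently wrong.
Generation is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import consequences as cq
from . import scan
from .io import DEFAULT_CORE_CUTOFF, DEFAULT_MATRIX_CUTOFF, write_pwm_library
from .promoters import DEFAULT_BUILD_DOWNSTREAM, DEFAULT_BUILD_UPSTREAM
from .types import CENTER_INDEX_0, FLANK, NUCLEOTIDES, Pwm, revcomp

EFFECTS = ("loss", "gain", "score_change", "none")

#: matrix used for score-change plants (mixed-frequency variant column)
MIXED_PWM_ID = "P$MIX_01"


def fixture_pwm_library() -> list[Pwm]:
    """The bundled toy library: three sharp 6-mer matrices plus one matrix
    with a 70/30 mixed final column for score-change constructions.

    Sharp columns put all 100 counts on the consensus base, so at the default
    cutoffs a single consensus-breaking substitution drops a site below the
    matrix cutoff — which is what makes gain/loss plants constructible.
    None of the consensi is palindromic.
    """

    def sharp(consensus: str) -> np.ndarray:
        counts = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus):
            counts[i, NUCLEOTIDES.index(b)] = 100
        return counts

    mixed = sharp("GGTCCA")
    mixed[5] = [70.0, 30.0, 0.0, 0.0]  # A-heavy, C still bindable
    kw = dict(core_cutoff=DEFAULT_CORE_CUTOFF, matrix_cutoff=DEFAULT_MATRIX_CUTOFF)
    return [
        Pwm("P$TATA_01", sharp("TATAAA"), **kw),
        Pwm("P$GATA_01", sharp("GATAAG"), **kw),
        Pwm("P$CACG_01", sharp("CACGTA"), **kw),
        Pwm(MIXED_PWM_ID, mixed, **kw),
    ]


@dataclass(frozen=True)
class PlantedSite:
    """One engineered (SNP, binding site) with its intended consequence."""

    pwm_id: str
    gene_id: str
    distance_to_tss: int
    allele_effect: str


@dataclass
class FixtureSpec:
    """Parameters of one synthetic world.

    Defaults describe a small but realistic promoter landscape: one 60-kb
    chromosome, three genes, ten background SNPs, and 40% GC (typical of
    plant genomes). ``planted_sites=None`` auto-plants one site per gene,
    cycling through the four effects.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 60_000
    n_genes: int = 3
    n_snps: int = 10
    planted_sites: Optional[list[PlantedSite]] = None
    gc_content: float = 0.40
    upstream_bp: int = DEFAULT_BUILD_UPSTREAM
    downstream_bp: int = DEFAULT_BUILD_DOWNSTREAM


@dataclass
class Fixture:
    """Paths of the generated file set plus the in-memory truth rows."""

    genome: str
    gff3: str
    vcf: str
    pwms: str
    truth: str
    truth_rows: list[dict] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _place_genes(spec: FixtureSpec, rng: np.random.Generator) -> list[dict]:
    genes = []
    per_chrom = -(-spec.n_genes // spec.n_chroms)
    slot = spec.chrom_length // per_chrom
    for i in range(spec.n_genes):
        chrom = f"chr{i % spec.n_chroms + 1}"
        k = i // spec.n_chroms
        tss = slot * k + slot // 2  # 1-based, central in its slot
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append({"gene_id": f"gene{i + 1:02d}", "chrom": chrom, "tss": tss, "strand": strand})
    return genes


def _default_plants(spec: FixtureSpec, genes: list[dict], pwms: list[Pwm],
                    rng: np.random.Generator) -> list[PlantedSite]:
    sharp_ids = [p.pwm_id for p in pwms if p.pwm_id != MIXED_PWM_ID]
    plants = []
    for i, gene in enumerate(genes):
        effect = EFFECTS[i % len(EFFECTS)]
        pwm_id = MIXED_PWM_ID if effect == "score_change" else sharp_ids[i % len(sharp_ids)]
        distance = int(rng.integers(-900, 81))
        plants.append(PlantedSite(pwm_id, gene["gene_id"], distance, effect))
    return plants


class _MemGenome:
    """Minimal in-memory stand-in matching the Genome fetch API, used for
    generation-time verification before the FASTA is written."""

    def __init__(self, seqs: dict):
        self._seqs = seqs

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        s = self._seqs[chrom]
        return s[max(start, 0) : min(end, len(s))].tobytes().decode()


def _verify_plant(
    plant: PlantedSite,
    snp: dict,
    seqs: dict,
    spwms: list[scan.ScoredPwm],
    widths: dict,
) -> None:
    genome = _MemGenome(seqs)
    pos0 = snp["pos"] - 1
    window = genome.fetch(snp["chrom"], pos0 - FLANK, pos0 + FLANK + 1)
    if len(window) != 51 or "N" in window:
        raise ValueError(f"unrealizable plant {plant}: bad 51-bp window")
    if window[CENTER_INDEX_0] != snp["ref"]:
        raise ValueError(f"unrealizable plant {plant}: genome/ref mismatch")
    alt_window = window[:CENTER_INDEX_0] + snp["alt"] + window[CENTER_INDEX_0 + 1 :]
    records = cq.classify(
        snp["snp_id"],
        "+",
        scan.scan_library(spwms, window),
        scan.scan_library(spwms, alt_window),
    )
    records = cq.restrict_to_snp_overlap(records, widths)
    classes = {r.consequence for r in records if r.pwm_id == plant.pwm_id}
    if plant.allele_effect == "none":
        affecting = {r.consequence for r in records} & cq.AFFECTING
        if affecting:
            raise ValueError(f"unrealizable plant {plant}: chance effect {affecting}")
    elif plant.allele_effect not in classes:
        raise ValueError(
            f"unrealizable plant {plant}: scan yields {classes or 'no site'}"
        )


def generate(spec: FixtureSpec, outdir: str) -> Fixture:
    """Generate the fixture file set into ``outdir`` and return its paths.

    Raises at generation time if any planted effect is not realised by an
    actual scan of the finished genome (including a chance background hit on
    an ``allele_effect='none'`` plant), so the truth TSV can be trusted.
    """
    rng = np.random.default_rng(spec.seed)
    pwms = fixture_pwm_library()
    pwms_by_id = {p.pwm_id: p for p in pwms}
    spwms = [scan.prepare(p) for p in pwms]
    widths = {p.pwm_id: p.width for p in pwms}

    seqs = {
        f"chr{c + 1}": _random_seq(rng, spec.chrom_length, spec.gc_content)
        for c in range(spec.n_chroms)
    }
    genes = _place_genes(spec, rng)
    genes_by_id = {g["gene_id"]: g for g in genes}
    plants = spec.planted_sites
    if plants is None:
        plants = _default_plants(spec, genes, pwms, rng)

    snps: list[dict] = []
    truth_rows: list[dict] = []
    used_pos: set = set()
    used_footprints: list[tuple] = []

    for n, plant in enumerate(plants):
        if plant.allele_effect not in EFFECTS:
            raise ValueError(f"unknown allele_effect {plant.allele_effect!r}")
        if not -spec.upstream_bp <= plant.distance_to_tss <= spec.downstream_bp:
            raise ValueError(f"plant outside the promoter window: {plant}")
        gene = genes_by_id[plant.gene_id]
        pwm = pwms_by_id[plant.pwm_id]
        w = pwm.width
        consensus = pwm.consensus()
        pos = (
            gene["tss"] + plant.distance_to_tss
            if gene["strand"] == "+"
            else gene["tss"] - plant.distance_to_tss
        )
        chrom, seq = gene["chrom"], seqs[gene["chrom"]]
        if not FLANK + 1 <= pos <= len(seq) - FLANK:
            raise ValueError(f"plant too close to a contig edge: {plant}")
        if (chrom, pos) in used_pos:
            raise ValueError(f"plant position collision: {plant}")

        if plant.allele_effect == "score_change":
            j = w - 1  # the mixed column
            high, low = "A", "C"  # 70 vs 30 counts: both bind, scores differ
            planted_site = consensus[: j] + high
            ref, alt = high, low
        elif plant.allele_effect in ("loss", "gain"):
            j = w // 2
            col = pwm.counts[j]
            broken = NUCLEOTIDES[int(np.argmin(col))]
            if plant.allele_effect == "loss":
                planted_site = consensus
                ref, alt = consensus[j], broken
            else:
                planted_site = consensus[:j] + broken + consensus[j + 1 :]
                ref, alt = broken, consensus[j]
        else:  # none: background only, rejection-sampled until truly effect-free
            j = 0
            planted_site = None
            pos0 = pos - 1
            for _ in range(50):
                ref = seq[pos0].decode()
                alt = str(rng.permutation([b for b in "ACGT" if b != ref])[0])
                window = seq[pos0 - FLANK : pos0 + FLANK + 1].tobytes().decode()
                alt_window = window[:CENTER_INDEX_0] + alt + window[CENTER_INDEX_0 + 1 :]
                recs = cq.restrict_to_snp_overlap(
                    cq.classify(
                        "candidate",
                        "+",
                        scan.scan_library(spwms, window),
                        scan.scan_library(spwms, alt_window),
                    ),
                    widths,
                )
                if not any(r.consequence in cq.AFFECTING for r in recs):
                    break
                # chance binding site near the SNP: redraw the local background
                seq[pos0 - FLANK : pos0 + FLANK + 1] = _random_seq(
                    rng, 2 * FLANK + 1, spec.gc_content
                )
            else:
                raise ValueError(f"unrealizable plant {plant}: background never clean")

        if planted_site is not None:
            start0 = pos - 1 - j
            if start0 < 0 or start0 + w > len(seq):
                raise ValueError(f"plant footprint outside the contig: {plant}")
            for c0, s0, e0 in used_footprints:
                if c0 == chrom and s0 < start0 + w and start0 < e0:
                    raise ValueError(f"overlapping plant footprints: {plant}")
            used_footprints.append((chrom, start0, start0 + w))
            seq[start0 : start0 + w] = np.frombuffer(planted_site.encode(), dtype="S1")
            ref, alt = planted_site[j], alt

        snp_id = f"pl{n + 1:03d}"
        snp = {"snp_id": snp_id, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        snps.append(snp)
        used_pos.add((chrom, pos))
        truth_rows.append(
            {
                "snp_id": snp_id,
                "gene_id": plant.gene_id,
                "pwm_id": plant.pwm_id,
                "distance_to_tss": plant.distance_to_tss,
                "allele_effect": plant.allele_effect,
            }
        )

    # every plant is verified against the *finished* genome
    for plant, snp in zip(plants, snps):
        _verify_plant(plant, snp, seqs, spwms, widths)

    # background SNPs: reference-matching, random alternate allele
    for n in range(spec.n_snps):
        for _ in range(100):
            gene = genes[int(rng.integers(len(genes)))]
            d = int(rng.integers(-spec.upstream_bp, spec.downstream_bp + 1))
            pos = gene["tss"] + d if gene["strand"] == "+" else gene["tss"] - d
            chrom, seq = gene["chrom"], seqs[gene["chrom"]]
            if FLANK + 1 <= pos <= len(seq) - FLANK and (chrom, pos) not in used_pos:
                break
        else:
            raise ValueError("could not place background SNP")
        ref = seq[pos - 1].decode()
        alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
        snps.append({"snp_id": f"bg{n + 1:03d}", "chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
        used_pos.add((chrom, pos))

    os.makedirs(outdir, exist_ok=True)
    paths = Fixture(
        genome=os.path.join(outdir, "genome.fa"),
        gff3=os.path.join(outdir, "genes.gff3"),
        vcf=os.path.join(outdir, "snps.vcf"),
        pwms=os.path.join(outdir, "pwms.txt"),
        truth=os.path.join(outdir, "truth.tsv"),
        truth_rows=truth_rows,
    )

    with open(paths.genome, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = seqs[chrom].tobytes().decode()
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    with open(paths.gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = (
                (g["tss"], min(g["tss"] + 999, spec.chrom_length))
                if g["strand"] == "+"
                else (max(g["tss"] - 999, 1), g["tss"])
            )
            fh.write(
                f"{g['chrom']}\tsynthetic\tgene\t{start}\t{end}\t.\t{g['strand']}\t.\t"
                f"ID={g['gene_id']};Name={g['gene_id']}-name\n"
            )

    with open(paths.vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(seqs):
            fh.write(f"##contig=<ID={chrom},length={len(seqs[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: (s["chrom"], s["pos"])):
            fh.write(
                f"{s['chrom']}\t{s['pos']}\t{s['snp_id']}\t{s['ref']}\t{s['alt']}\t.\tPASS\t.\n"
            )

    write_pwm_library(pwms, paths.pwms)

    with open(paths.truth, "w") as fh:
        fh.write("snp_id\tgene_id\tpwm_id\tdistance_to_tss\tallele_effect\n")
        for row in truth_rows:
            fh.write(
                f"{row['snp_id']}\t{row['gene_id']}\t{row['pwm_id']}\t"
                f"{row['distance_to_tss']}\t{row['allele_effect']}\n"
            )
    return paths


def edge_case_fixture(outdir: str) -> Fixture:
    """Fixed fixture exercising the three sequence discard rules.

    One 12-kb contig with a plus-strand gene at TSS 6000, and three SNPs in
    its promoter: one 10 bp from the contig start (too_short), one inside a
    planted N-run (contains_N), and one whose catalog reference allele
    contradicts the genome (ref_mismatch).
    """
    rng = np.random.default_rng(2024)
    seq = _random_seq(rng, 12_000, 0.40)
    seq[4000:4010] = np.frombuffer(b"N" * 10, dtype="S1")
    seq[9] = b"A"
    seq[4999] = b"T"  # catalog will claim ref=A here -> mismatch

    snps = [
        {"snp_id": "edge_short", "chrom": "chr1", "pos": 10, "ref": "A", "alt": "G"},
        {"snp_id": "edge_n", "chrom": "chr1", "pos": 4005, "ref": "A", "alt": "G"},
        {"snp_id": "edge_mismatch", "chrom": "chr1", "pos": 5000, "ref": "A", "alt": "G"},
    ]

    os.makedirs(outdir, exist_ok=True)
    paths = Fixture(
        genome=os.path.join(outdir, "genome.fa"),
        gff3=os.path.join(outdir, "genes.gff3"),
        vcf=os.path.join(outdir, "snps.vcf"),
        pwms=os.path.join(outdir, "pwms.txt"),
        truth=os.path.join(outdir, "truth.tsv"),
    )
    with open(paths.genome, "w") as fh:
        fh.write(">chr1\n")
        s = seq.tobytes().decode()
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")
    with open(paths.gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("chr1\tsynthetic\tgene\t6000\t6999\t.\t+\t.\tID=geneE;Name=geneE-name\n")
    with open(paths.vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=12000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s['chrom']}\t{s['pos']}\t{s['snp_id']}\t{s['ref']}\t{s['alt']}\t.\tPASS\t.\n")
    write_pwm_library(fixture_pwm_library(), paths.pwms)
    with open(paths.truth, "w") as fh:
        fh.write("snp_id\treason\n")
        fh.write("edge_short\ttoo_short\nedge_n\tcontains_N\nedge_mismatch\tref_mismatch\n")
    return paths
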