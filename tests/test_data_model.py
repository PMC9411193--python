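"""Core types, coordinate conventions and format round trips."""

import numpy as np
import pandas as pd
import pytest

from episcreen.data_model import (
    ContactPair,
    GenomicInterval,
    SnpRecord,
    bin_contacts,
    canonicalize_pairs,
    normalize_chrom,
    pairs_to_frame,
    read_bed,
    read_expression_table,
    read_gene_models,
    read_gwas_table,
    read_pairs,
    write_bed,
    write_expression_table,
    write_gene_models,
    write_gwas_table,
    write_pairs,
    ExpressionTable,
    GeneRecord,
    fetch_sequence,
    write_fasta,
)


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        assert len(GenomicInterval("chr1", 0, 5)) == 5

    def test_snp_invariants(self):
        with pytest.raises(ValueError):
            SnpRecord("rs1", "chr1", 5, "A", "A", 0.5, 1.0)
        with pytest.raises(ValueError):
            SnpRecord("rs1", "chr1", 5, "AT", "A", 0.5, 1.0)
        with pytest.raises(ValueError):
            SnpRecord("rs1", "chr1", 5, "A", "G", 0.0, 1.0)

    def test_contact_pair_canonical_order(self):
        with pytest.raises(ValueError):
            ContactPair("chr2", 5, "chr1", 3)
        ContactPair("chr1", 5, "chr1", 5)  # equal is fine

    def test_normalize_chrom(self):
        assert normalize_chrom("1") == "chr1"
        assert normalize_chrom("chrX") == "chrX"
        assert normalize_chrom(" 2 ") == "chr2"


class TestGwasTable:
    def test_one_based_conversion(self, tmp_path):
        # rs560789-style row: 1-based 117228892 becomes 0-based 117228891
        path = tmp_path / "g.tsv"
        path.write_text(
            "rsid\tchrom\tpos\tref\talt\tpvalue\todds_ratio\n"
            "rs560789\tchr11\t117228892\tA\tG\t4e-4\t1.3\n"
        )
        (snp,) = read_gwas_table(path)
        assert snp.pos == 117228891
        assert (snp.ref, snp.alt) == ("A", "G")

    def test_empty_table(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("rsid\tchrom\tpos\tref\talt\tpvalue\todds_ratio\n")
        assert read_gwas_table(path) == []

    def test_bad_rows_rejected_with_rest_returned(self, tmp_path, caplog):
        path = tmp_path / "g.tsv"
        path.write_text(
            "rsid\tchrom\tpos\tref\talt\tpvalue\todds_ratio\n"
            "rs1\tchr1\t100\tA\tG\t1.5\t1.0\n"  # p out of domain
            "rs2\tchr1\t200\tAT\tG\t0.5\t1.0\n"  # indel
            "rs3\tchr1\t300\tC\tT\t0.5\t1.0\n"
        )
        with caplog.at_level("WARNING"):
            snps = read_gwas_table(path)
        assert [s.rsid for s in snps] == ["rs3"]
        assert sum("rejecting" in r.message for r in caplog.records) == 2


class TestGeneModels:
    def _write(self, tmp_path, lines):
        path = tmp_path / "g.gtf"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_tss_strand_conversion(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "gp";',
                'chr1\tx\texon\t101\t150\t.\t+\t.\tgene_id "gp";',
                'chr1\tx\tgene\t101\t200\t.\t-\t.\tgene_id "gm";',
                'chr1\tx\texon\t101\t200\t.\t-\t.\tgene_id "gm";',
            ],
        )
        genes = {g.gene_id: g for g in read_gene_models(path)}
        assert genes["gp"].tss == 100  # GTF 101 -> 0-based 100
        assert genes["gm"].tss == 199  # strand symmetry
        assert (genes["gp"].exons[0].start, genes["gp"].exons[0].end) == (100, 150)

    def test_missing_gene_id_names_line(self, tmp_path):
        path = self._write(tmp_path, ["chr1\tx\tgene\t1\t10\t.\t+\t.\tfoo bar;"])
        with pytest.raises(ValueError, match="line 1"):
            read_gene_models(path)


class TestBinContacts:
    SIZES = {"chr1": 100_000, "chr2": 50_000}

    def test_floor_division_bins(self):
        pairs = pairs_to_frame(
            [ContactPair("chr1", 0, "chr1", 9_999), ContactPair("chr1", 0, "chr1", 10_000)]
        )
        m = bin_contacts(pairs, 10_000, self.SIZES).chrom_matrix("chr1")
        assert m[0, 0] == 1 and m[0, 1] == 1 and m[1, 0] == 1

    def test_symmetry(self):
        pairs = pairs_to_frame([ContactPair("chr1", 100, "chr1", 25_000, count=2)])
        m = bin_contacts(pairs, 10_000, self.SIZES).chrom_matrix("chr1")
        assert m[0, 2] == 2 and m[2, 0] == 2

    def test_total_count_conserved(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(1, 40))
            df = pd.DataFrame(
                {
                    "chromA": rng.choice(["chr1", "chr2"], n),
                    "posA": rng.integers(0, 50_000, n),
                    "chromB": "chr1",
                    "posB": rng.integers(0, 50_000, n),
                    "count": rng.integers(1, 5, n),
                }
            )
            df = canonicalize_pairs(df)
            cm = bin_contacts(df, 7_000, self.SIZES)
            cis = df[df.chromA == df.chromB]["count"].sum()
            assert cm.total_cis == cis
            assert cm.trans_count == df["count"].sum() - cis

    def test_position_beyond_chromosome_errors(self):
        pairs = pairs_to_frame([ContactPair("chr2", 10, "chr2", 60_000)])
        with pytest.raises(ValueError, match="beyond"):
            bin_contacts(pairs, 10_000, self.SIZES)


class TestRoundTrips:
    def test_bed(self, tmp_path):
        rng = np.random.default_rng(0)
        ivs = [
            GenomicInterval(
                f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(1, 500)),
                name=f"n{i}", score=float(np.round(rng.random(), 3)),
                strand="+" if rng.random() < 0.5 else "-",
            )
            for i, s in enumerate(rng.integers(0, 10_000, 25))
        ]
        write_bed(ivs, tmp_path / "x.bed")
        assert read_bed(tmp_path / "x.bed") == ivs

    def test_pairs_both_dialects(self, tmp_path):
        rng = np.random.default_rng(1)
        df = canonicalize_pairs(
            pd.DataFrame(
                {
                    "chromA": rng.choice(["chr1", "chr2"], 30),
                    "posA": rng.integers(0, 99_000, 30),
                    "chromB": rng.choice(["chr1", "chr2"], 30),
                    "posB": rng.integers(0, 99_000, 30),
                    "count": rng.integers(1, 9, 30),
                }
            )
        )
        for dialect in ("pairs", "bedpe"):
            write_pairs(df, tmp_path / f"x.{dialect}", dialect)
            back = read_pairs(tmp_path / f"x.{dialect}", dialect)
            pd.testing.assert_frame_equal(back, df)

    def test_gwas(self, tmp_path):
        snps = [
            SnpRecord(f"rs{i}", "chr1", 100 + 7 * i, "A", "G", 0.25, 1.1)
            for i in range(10)
        ]
        write_gwas_table(snps, tmp_path / "g.tsv")
        assert read_gwas_table(tmp_path / "g.tsv") == snps

    def test_expression(self, tmp_path):
        table = ExpressionTable({"g1": 0.0, "g2": 12.25, "g3": 0.5})
        write_expression_table(table, tmp_path / "e.tsv")
        back = read_expression_table(tmp_path / "e.tsv")
        assert dict(back.items()) == dict(table.items())

    def test_gene_models(self, tmp_path):
        genes = [
            GeneRecord(
                "g1", "S1", "chr1", "+", 100,
                exons=[GenomicInterval("chr1", 100, 200, "g1"),
                       GenomicInterval("chr1", 400, 500, "g1")],
            ),
            GeneRecord("g2", "S2", "chr2", "-", 999,
                       exons=[GenomicInterval("chr2", 300, 1000, "g2")]),
        ]
        write_gene_models(genes, tmp_path / "g.gtf")
        back = read_gene_models(tmp_path / "g.gtf")
        assert [(g.gene_id, g.tss, g.strand, g.exons) for g in back] == [
            (g.gene_id, g.tss, g.strand, g.exons) for g in genes
        ]

    def test_fasta_softmask_preserved(self, tmp_path):
        seqs = {"chr1": "ACGTacgtNNACGT" * 10}
        write_fasta(seqs, tmp_path / "g.fa")
        got = fetch_sequence(tmp_path / "g.fa", GenomicInterval("chr1", 2, 30))
        assert got == seqs["chr1"][2:30]  # case preserved
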