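"""tRNA reference construction: parsing, maturation, dedupe, expression."""

import pandas as pd
import pytest
from Bio.Seq import Seq

from trnamod.reference import (
    TRNAGene,
    TrnascanFormatError,
    dedupe_pre,
    exclusive_sets,
    expression_calls,
    mature_sequence,
    parse_trnascan,
    read_fasta,
    write_fasta,
)
from trnamod.simulate import make_tpm_table, make_trna_genes

HEADER = (
    "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\t\n"
    "Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
    "--------\t------\t-----\t----\t----\t-----\t-----\t----\t------\t----\n"
)


@pytest.fixture
def toy_genome():
    # chr1: plus-strand gene at 11..40 with intron at genomic 21..25
    # chr2: minus-strand gene at 60..31 (begin > end), no intron
    chr1 = "A" * 10 + "GCGGAUUUAG" + "CUCAG" + "UUGGGAGAGC".replace("U", "T") + "T" * 20
    chr1 = chr1.replace("U", "T")
    chr2 = "C" * 30 + "GATTACAGATTACAGATTACAGATTACAGA" + "G" * 20
    return {"chr1": chr1, "chr2": chr2}


@pytest.fixture
def scan_file(tmp_path, toy_genome):
    rows = [
        "chr1\t1\t11\t40\tTyr\tGTA\t21\t25\t55.0\t",
        "chr2\t1\t60\t31\tAla\tAGC\t0\t0\t60.0\t",
        "chr1\t2\t45\t50\tLeu\tCAA\t0\t0\t20.0\tpseudo",
    ]
    path = tmp_path / "toy.out"
    path.write_text(HEADER + "\n".join(rows) + "\n")
    return path


class TestParseTrnascan:
    def test_gene_count_and_intron(self, scan_file, toy_genome):
        genes = parse_trnascan(scan_file, toy_genome)
        assert len(genes) == 3
        with_intron = [g for g in genes if g.has_intron]
        assert len(with_intron) == 1
        assert with_intron[0].isotype == "Tyr"

    def test_plus_strand_coordinates(self, scan_file, toy_genome):
        genes = parse_trnascan(scan_file, toy_genome)
        tyr = next(g for g in genes if g.isotype == "Tyr")
        assert tyr.sequence == toy_genome["chr1"][10:40].upper()
        # genomic 21..25 -> local 11..15 for a gene starting at 11
        assert tyr.intron == (11, 15)

    def test_minus_strand_reverse_complemented(self, scan_file, toy_genome):
        genes = parse_trnascan(scan_file, toy_genome)
        ala = next(g for g in genes if g.isotype == "Ala")
        expected = str(Seq(toy_genome["chr2"][30:60]).reverse_complement())
        assert ala.sequence == expected

    def test_minus_strand_intron_localized(self, tmp_path, toy_genome):
        # minus-strand gene 60..31 with genomic intron 40..44:
        # local coordinates count from the 5' end of the transcribed strand
        path = tmp_path / "minus.out"
        path.write_text(HEADER + "chr2\t1\t60\t31\tTyr\tGTA\t40\t44\t55.0\t\n")
        gene = parse_trnascan(path, toy_genome)[0]
        assert gene.intron == (60 - 44 + 1, 60 - 40 + 1)
        length = 60 - 31 + 1
        lo, hi = gene.intron
        assert 1 <= lo <= hi <= length

    def test_high_confidence_filtering(self, scan_file, toy_genome):
        genes = parse_trnascan(scan_file, toy_genome)
        assert sum(not g.high_confidence for g in genes) == 1
        kept = parse_trnascan(scan_file, toy_genome, high_confidence_only=True)
        assert len(kept) == 2

    def test_malformed_row_reports_line(self, tmp_path, toy_genome):
        path = tmp_path / "bad.out"
        path.write_text(HEADER + "chr1\t1\tnope\t40\tTyr\tGTA\t0\t0\t55.0\t\n")
        with pytest.raises(TrnascanFormatError, match="line 4"):
            parse_trnascan(path, toy_genome)


class TestMatureSequence:
    def test_intron_excised_cca_added(self):
        gene = TRNAGene("Tyr-GTA-1-1", "Tyr", "GTA", "A" * 85, intron=(39, 51))
        mature = mature_sequence(gene)
        assert len(mature) == 85 - 13 + 3
        assert mature.endswith("CCA")

    def test_intronless(self):
        gene = TRNAGene("Ala-AGC-1-1", "Ala", "AGC", "G" * 72)
        assert len(mature_sequence(gene)) == 75

    def test_intron_substring_absent(self):
        genes, truth = make_trna_genes(n_genes=60, n_duplicates=10, seed=5)
        by_id = {g.gene_id: g for g in genes}
        for row in truth.itertuples():
            gene = by_id[row.gene_id]
            if row.has_intron:
                intron_seq = gene.sequence[row.intron_start - 1 : row.intron_end]
                mature = mature_sequence(gene)
                body = mature[:-3]
                assert (
                    body
                    == gene.sequence[: row.intron_start - 1]
                    + gene.sequence[row.intron_end :]
                )
                assert len(intron_seq) == row.intron_end - row.intron_start + 1

    def test_intron_bounds_validated(self):
        with pytest.raises(ValueError):
            TRNAGene("x", "Tyr", "GTA", "ACGT", intron=(2, 9))


class TestDedupe:
    def test_exact_duplicates_collapsed(self):
        a = TRNAGene("Tyr-GTA-1-1", "Tyr", "GTA", "ACGTACGT")
        b = TRNAGene("Tyr-GTA-2-1", "Tyr", "GTA", "ACGTACGT")
        unique, report = dedupe_pre([a, b])
        assert [g.gene_id for g in unique] == ["Tyr-GTA-1-1"]
        assert report.iloc[0]["duplicate_id"] == "Tyr-GTA-2-1"

    def test_isodecoders_retained(self):
        a = TRNAGene("Tyr-GTA-1-1", "Tyr", "GTA", "ACGTACGT")
        b = TRNAGene("Tyr-GTA-2-1", "Tyr", "GTA", "ACGTACGA")
        unique, report = dedupe_pre([a, b])
        assert len(unique) == 2 and report.empty

    def test_planted_duplicate_count_recovered(self):
        genes, truth = make_trna_genes(n_genes=200, n_duplicates=42, seed=0)
        unique, report = dedupe_pre(genes)
        assert len(unique) == 158
        assert len(report) == 42


class TestExpression:
    @pytest.mark.parametrize("tpm,expressed", [(1.0, False), (1.01, True), (0.0, False)])
    def test_strict_threshold(self, tpm, expressed):
        calls = expression_calls(pd.DataFrame({"transcript": ["t"], "tpm": [tpm]}))
        assert calls[0].expressed is expressed

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            expression_calls(pd.DataFrame({"transcript": ["t"], "tpm": [-1.0]}))

    def test_exclusive_sets_recovered(self):
        tpm, truth = make_tpm_table(n_exclusive=8, seed=2)
        excl = exclusive_sets(tpm)
        expected = set(truth[truth["exclusive_to"] == "PBF"]["transcript"])
        assert set(excl["PBF"]) == expected
        assert excl["NBF"] == []


class TestFastaRoundTrip:
    def test_byte_exact_ids_and_sequences(self, tmp_path):
        genes, _ = make_trna_genes(n_genes=20, n_duplicates=3, seed=1)
        records = {g.gene_id: mature_sequence(g) for g in genes}
        path = tmp_path / "mature.fasta"
        write_fasta(records, path)
        again = read_fasta(path)
        assert again == records
        assert all(seq.endswith("CCA") for seq in again.values())

    def test_intron_families_restricted(self):
        genes, truth = make_trna_genes(n_genes=120, n_duplicates=20, seed=9)
        intronic = truth[truth["has_intron"]]
        families = set(intronic["isotype"] + "-" + intronic["anticodon"])
        assert families <= {"Ile-TAT", "Leu-CAA", "Tyr-GTA"}
        assert len(families) > 0
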