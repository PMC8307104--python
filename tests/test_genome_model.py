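"""Annotation model: coordinates, spacers, strand accounting, I/O."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from mitocompare.errors import (
    AlphabetError,
    CoordinateError,
    EmptyTableError,
    OrderingError,
    ParseError,
)
from mitocompare.genome_model import (
    FeatureTable,
    GeneFeature,
    MitoGenome,
    compute_spacers,
    extract_feature_sequence,
    read_feature_table,
    read_genbank,
    summarize_gene_counts,
    write_feature_table,
)

# Printed per-gene sizes for the reference species (annotation table,
# reference column), used to pin the fixture transcription.
SUNANENSIS_SIZES = {
    "trnI": 68, "trnQ": 69, "trnM": 69, "ND2": 1023, "trnW": 67, "trnC": 65,
    "trnY": 66, "COI": 1534, "trnL(UUR)": 66, "COII": 684, "trnD": 69,
    "trnK": 71, "ATP8": 162, "ATP6": 678, "COIII": 792, "trnG": 67,
    "ND3": 354, "trnA": 66, "trnR": 64, "trnN": 65, "trnS(AGN)": 67,
    "trnE": 69, "trnF": 65, "ND5": 1717, "trnH": 70, "ND4": 1334,
    "ND4L": 294, "trnT": 68, "trnP": 66, "ND6": 522, "CytB": 1143,
    "trnS(UCN)": 70, "ND1": 945, "trnL(CUN)": 66, "lrRNA": 1320,
    "trnV": 70, "srRNA": 852, "AT_rich": 748,
}


class TestFixtureAccounting:
    def test_every_feature_length_matches_printed_size(self, sunanensis_table):
        for feature in sunanensis_table:
            assert feature.length() == SUNANENSIS_SIZES[feature.name], feature.name

    def test_genome_length(self, sunanensis_table):
        assert sunanensis_table.genome_length == 15656

    @pytest.mark.parametrize(
        "upstream,expected",
        [("trnI", 0), ("trnQ", -1), ("trnK", 17), ("ATP8", -7), ("ND5", 15),
         ("trnS(UCN)", 26), ("AT_rich", 0)],
    )
    def test_printed_spacers(self, sunanensis_table, upstream, expected):
        gaps = {s.upstream_gene: s.spacer_length
                for s in compute_spacers(sunanensis_table)}
        assert gaps[upstream] == expected

    def test_circular_conservation_all_species(self, all_fixture_tables):
        # sum of feature lengths plus signed spacers closes the circle exactly
        for name, table in all_fixture_tables.items():
            total = sum(f.length(table.genome_length) for f in table)
            total += sum(s.spacer_length for s in compute_spacers(table))
            assert total == table.genome_length, name

    def test_strand_tallies(self, sunanensis_table):
        counts = summarize_gene_counts(sunanensis_table)
        assert counts["PCG"] == {"J": 9, "N": 4}
        assert counts["tRNA"] == {"J": 14, "N": 8}
        assert counts["rRNA"] == {"J": 0, "N": 2}

    def test_gene_inventory_all_species(self, all_fixture_tables):
        for table in all_fixture_tables.values():
            assert len(table.pcgs) == 13
            assert len(table.trnas) == 22
            assert len(table.rrnas) == 2
            assert table.control_region is not None


class TestExtraction:
    def test_j_strand_slice(self):
        genome = MitoGenome("x", "x", "ATGCCC")
        f = GeneFeature("g", "rRNA", "J", 1, 3)
        assert extract_feature_sequence(genome, f) == "ATG"

    def test_n_strand_reverse_complement(self):
        genome = MitoGenome("x", "x", "ATGCCC")
        f = GeneFeature("g", "rRNA", "N", 1, 3)
        assert extract_feature_sequence(genome, f) == "CAT"

    def test_nd5_length_from_synthetic_genome(self, synthetic_reference):
        genome, table = synthetic_reference
        assert len(extract_feature_sequence(genome, table.get("ND5"))) == 1717

    def test_wrapping_feature(self):
        genome = MitoGenome("x", "x", "AATTGGCC")
        f = GeneFeature("g", "rRNA", "J", 7, 2)
        assert extract_feature_sequence(genome, f) == "CCAA"

    def test_double_reverse_complement_is_identity(self, synthetic_reference):
        from mitocompare.genetics import reverse_complement

        genome, table = synthetic_reference
        for f in table:
            if f.strand == "N":
                sense = extract_feature_sequence(genome, f)
                original = genome.sequence[f.start - 1 : f.end]
                assert reverse_complement(reverse_complement(original)) == original
                assert reverse_complement(sense) == original


class TestTableIO:
    def test_round_trip(self, tmp_path, sunanensis_table):
        path = tmp_path / "table.tsv"
        write_feature_table(sunanensis_table, path)
        again = read_feature_table(path)
        assert again.features == sunanensis_table.features
        assert again.genome_length == sunanensis_table.genome_length

    def test_header_only_is_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "name\tcategory\tstrand\tstart\tend\tanticodon\t"
            "initiation_codon\ttermination_codon\n"
        )
        with pytest.raises(EmptyTableError):
            read_feature_table(path)

    def test_end_before_start_is_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "name\tcategory\tstrand\tstart\tend\tanticodon\t"
            "initiation_codon\ttermination_codon\n"
            "g\trRNA\tJ\t100\t10\t\t\t\n"
        )
        with pytest.raises(CoordinateError):
            read_feature_table(path)

    def test_unordered_table_spacer_error(self):
        feats = [
            GeneFeature("a", "rRNA", "J", 100, 200),
            GeneFeature("b", "rRNA", "J", 10, 50),
        ]
        # constructing out of order is allowed; spacer computation is not
        with pytest.raises(OrderingError):
            compute_spacers(FeatureTable(features=feats, genome_length=300))

    def test_feature_beyond_genome_is_error(self):
        with pytest.raises(CoordinateError):
            FeatureTable(
                features=[GeneFeature("a", "rRNA", "J", 1, 500)],
                genome_length=100,
            )

    def test_non_acgtn_sequence_rejected(self):
        with pytest.raises(AlphabetError):
            MitoGenome("x", "x", "ATGXX")


class TestGenBank:
    def _write_record(self, tmp_path, synthetic_reference):
        genome, table = synthetic_reference
        record = SeqRecord(Seq(genome.sequence), id="SYN1", name="SYN1",
                           description="synthetic mitogenome",
                           annotations={"molecule_type": "DNA",
                                        "organism": "synthetic"})
        type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
        for f in table:
            if f.category == "control":
                record.features.append(
                    SeqFeature(
                        FeatureLocation(f.start - 1, f.end, strand=1),
                        type="misc_feature",
                        qualifiers={"note": ["A+T-rich region"]},
                    )
                )
                continue
            qualifiers = {"gene": [f.name]}
            if f.anticodon:
                qualifiers["anticodon"] = [f"(pos:0..0,aa:X,seq:{f.anticodon.lower()})"]
            record.features.append(
                SeqFeature(
                    FeatureLocation(f.start - 1, f.end,
                                    strand=1 if f.strand == "J" else -1),
                    type=type_of[f.category],
                    qualifiers=qualifiers,
                )
            )
        path = tmp_path / "syn.gb"
        SeqIO.write([record], str(path), "genbank")
        return path

    def test_genbank_round_trip_features(self, tmp_path, synthetic_reference):
        path = self._write_record(tmp_path, synthetic_reference)
        genome, table = read_genbank(path)
        _, expected = synthetic_reference
        assert len(table) == 38
        assert len(table.pcgs) == 13 and len(table.trnas) == 22
        by_name = {f.name: f for f in table}
        for f in expected:
            assert by_name[f.name].start == f.start
            assert by_name[f.name].end == f.end
            assert by_name[f.name].strand == f.strand

    def test_incomplete_stop_read_from_cds(self, tmp_path, synthetic_reference):
        path = self._write_record(tmp_path, synthetic_reference)
        _, table = read_genbank(path)
        assert table.get("COI").termination_codon == "T"
        assert table.get("ND4").termination_codon == "TA"

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.gb"
        path.write_text("")
        with pytest.raises(ParseError):
            read_genbank(path)
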