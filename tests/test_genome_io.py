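"""Genome loading, coordinate conventions, translation and masking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genostream import io as gio
from genostream.io import (
    Feature,
    GenomeFormatError,
    GenomeRecord,
    GenomeValidationError,
    Replicon,
    extract_proteins,
    load_genome,
    mask_intervals,
    merge_intervals,
)


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestLoadGenome:
    def test_gff3_coordinates_become_zero_based_half_open(self, tmp_path):
        fa = _write(tmp_path / "g.fna", ">c1\n" + "ATGC" * 250 + "\n")
        gff = _write(tmp_path / "g.gff3",
                     "##gff-version 3\n"
                     "c1\tsrc\tCDS\t1\t300\t.\t+\t0\tID=cds1;product=p\n")
        rec = load_genome(fa, gff)
        assert rec.genome_size == 1000
        (cds,) = rec.features_of_type("CDS")
        assert (cds.start, cds.end, cds.strand) == (0, 300, "+")

    def test_cds_beyond_contig_is_rejected(self, tmp_path):
        fa = _write(tmp_path / "g.fna", ">c1\nACGTACGTAC\n")
        gff = _write(tmp_path / "g.gff3",
                     "c1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=cds1\n")
        with pytest.raises(GenomeValidationError):
            load_genome(fa, gff)

    def test_unknown_seqid_is_a_format_error(self, tmp_path):
        fa = _write(tmp_path / "g.fna", ">c1\nACGTACGTAC\n")
        gff = _write(tmp_path / "g.gff3",
                     "cX\tsrc\tCDS\t1\t6\t.\t+\t0\tID=bad1\n")
        with pytest.raises(GenomeFormatError, match="bad1"):
            load_genome(fa, gff)

    def test_genbank_round_trip_with_annotated_translation(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        seq = Seq("ATGAAAAAATAA" + "ACGT" * 22)
        rec = SeqRecord(seq, id="synthrec1", name="synthrec1",
                        description="synthetic test record",
                        annotations={"molecule_type": "DNA",
                                     "topology": "circular"})
        rec.features.append(SeqFeature(
            FeatureLocation(0, 12, strand=1), type="CDS",
            qualifiers={"locus_tag": ["cds1"], "product": ["demo"],
                        "translation": ["MKK"]}))
        gb = tmp_path / "g.gbk"
        SeqIO.write([rec], str(gb), "genbank")
        loaded = load_genome(annotation_path=gb)
        assert loaded.genome_size == 100
        assert loaded.replicons[0].circular
        (cds,) = loaded.features_of_type("CDS")
        assert cds.protein == "MKK"
        assert extract_proteins(loaded).as_dict() == {"cds1": "MKK"}

    def test_fasta_gff3_write_read_round_trip(self, tmp_path, metric_genome):
        genome, _, _ = metric_genome
        fa, gff = tmp_path / "rt.fna", tmp_path / "rt.gff3"
        gio.write_genome_fasta(fa, genome)
        gio.write_gff3(gff, genome)
        back = load_genome(fa, gff, genome_id=genome.genome_id)
        assert back.replicons[0].sequence == genome.replicons[0].sequence
        assert len(back.features) == len(genome.features)
        orig = {(f.feature_id, f.start, f.end, f.strand, f.ftype)
                for f in genome.features}
        got = {(f.feature_id, f.start, f.end, f.strand, f.ftype)
               for f in back.features}
        assert got == orig
        # conversion is self-inverse: writing again reproduces the bytes
        gff2 = tmp_path / "rt2.gff3"
        gio.write_gff3(gff2, back)
        assert gff2.read_text() == gff.read_text()


class TestExtractProteins:
    def test_forward_cds_translates_with_bacterial_code(self):
        g = GenomeRecord("t", [Replicon("c", "ATGAAAAAATAA" + "A" * 8, False)],
                         [Feature("f1", "c", 0, 12, "+", "CDS")])
        assert extract_proteins(g).as_dict() == {"f1": "MKK"}

    def test_reverse_cds_translates_reverse_complement(self):
        # revcomp(TTATTTTTTCAT) = ATGAAAAAATAA -> MKK
        g = GenomeRecord("t", [Replicon("c", "TTATTTTTTCAT" + "A" * 8, False)],
                         [Feature("f1", "c", 0, 12, "-", "CDS")])
        assert extract_proteins(g).as_dict() == {"f1": "MKK"}

    def test_internal_stop_excluded_with_warning(self):
        g = GenomeRecord("t", [Replicon("c", "ATGTAAAAATAA" + "A" * 8, False)],
                         [Feature("f1", "c", 0, 12, "+", "CDS"),
                          Feature("f2", "c", 12, 18, "+", "CDS")])
        with pytest.warns(UserWarning, match="internal stop"):
            prot = extract_proteins(g)
        assert "f1" not in prot.as_dict()

    def test_one_protein_per_cds(self, small_genome):
        genome, proteins, truth = small_genome
        assert len(extract_proteins(genome)) == truth["n_cds"]


class TestMasking:
    @pytest.mark.parametrize("intervals,expected", [
        ([(2, 4)], "ACNNACGT"),
        ([], "ACGTACGT"),
        ([(0, 8)], "NNNNNNNN"),
    ])
    def test_masking_examples(self, intervals, expected):
        rep = Replicon("r", "ACGTACGT", False)
        assert mask_intervals(rep, intervals).sequence == expected

    def test_out_of_bounds_rejected(self):
        with pytest.raises(GenomeValidationError):
            mask_intervals(Replicon("r", "ACGT", False), [(2, 9)])

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mask_preserves_length_and_counts_union(self, raw):
        seq = ("ACGT" * 13)[:50]
        intervals = [(min(s, e), max(s, e)) for s, e in raw]
        masked = mask_intervals(Replicon("r", seq, False), intervals)
        assert len(masked.sequence) == len(seq)
        union = sum(e - s for s, e in merge_intervals(intervals))
        assert masked.sequence.count("N") == union

    def test_mask_rrna_records_intervals(self, metric_genome):
        genome, _, _ = metric_genome
        masked = gio.mask_rrna(genome)
        assert masked.metadata["rrna_masked"]
        ivs = masked.metadata["masked_intervals"][genome.replicons[0].id]
        total = sum(e - s for s, e in ivs)
        rrna = sum(f.length for f in genome.features_of_type("rRNA"))
        assert total == rrna
        assert masked.replicons[0].sequence.count("N") >= total
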