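"""Transcript model construction, region queries and isoform choice."""

import pytest

from riboprof.annotation import (
    AnnotationError,
    Region,
    TranscriptModel,
    load_transcripts,
    region_of,
    representative_transcript,
)
from tests.conftest import make_model

GFF_HEADER = "##gff-version 3\n"


def _write(tmp_path, text, name="test.gff3"):
    p = tmp_path / name
    p.write_text(GFF_HEADER + text)
    return p


class TestLoadTranscripts:
    def test_single_transcript_extents(self, tmp_path):
        """300-nt exon with CDS at 1-based 101-250 -> (100, 150, 50)."""
        gff = _write(
            tmp_path,
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\tCDS\t101\t250\t.\t+\t0\tParent=t1\n",
        )
        ts = load_transcripts(gff)
        m = ts["t1"]
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (100, 150, 50)
        assert m.gene_id == "g1"
        assert m.cds_complete

    def test_cds_spanning_whole_transcript(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\tCDS\t1\t300\t.\t+\t0\tParent=t1\n",
        )
        m = load_transcripts(gff)["t1"]
        assert (m.utr5_len, m.utr3_len) == (0, 0)

    def test_no_cds_transcript_excluded(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=t1\n",
        )
        assert len(load_transcripts(gff)) == 0

    def test_incomplete_cds_downgrades_flag(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\tCDS\t101\t251\t.\t+\t0\tParent=t1\n",
        )
        m = load_transcripts(gff)["t1"]
        assert m.cds_len == 151 and not m.cds_complete

    def test_multi_exon_minus_strand_projection(self, tmp_path):
        """Two exons on '-': transcript runs right-to-left; CDS parts at
        genomic 201-280 and 61-100 splice to transcript [20, 140)."""
        gff = _write(
            tmp_path,
            "chr1\tsrc\tmRNA\t1\t300\t.\t-\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t201\t300\t.\t-\t.\tParent=t1\n"
            "chr1\tsrc\texon\t1\t100\t.\t-\t.\tParent=t1\n"
            "chr1\tsrc\tCDS\t201\t280\t.\t-\t0\tParent=t1\n"
            "chr1\tsrc\tCDS\t61\t100\t.\t-\t1\tParent=t1\n",
        )
        m = load_transcripts(gff)["t1"]
        assert m.length == 200
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (20, 120, 60)

    def test_fasta_mismatch_drops_transcript(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\tmRNA\t1\t6\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t6\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\tCDS\t1\t6\t.\t+\t0\tParent=t1\n",
        )
        fasta = tmp_path / "seq.fa"
        fasta.write_text(">t1\nATG\n")  # length 3 != annotated 6
        assert len(load_transcripts(gff, fasta)) == 0

    def test_unparsable_gff_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("not\tgff\n")
        with pytest.raises(AnnotationError):
            load_transcripts(bad)

    def test_simulator_round_trip_exact(self, sim_dataset):
        """Reloading the simulator's FASTA/GFF3 reproduces every configured
        (utr5, cds, utr3) extent exactly, with sequences attached."""
        ts = sim_dataset["transcripts"]
        spec = sim_dataset["transcriptome"].spec
        assert len(ts) == len(spec)
        for row in spec.itertuples():
            m = ts[row.transcript_id]
            assert (m.utr5_len, m.cds_len, m.utr3_len) == (
                row.utr5_len, row.cds_len, row.utr3_len)
            assert m.gene_id == row.gene_id
            assert m.sequence == sim_dataset["transcriptome"].sequences[row.transcript_id]


class TestRegionOf:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (0, Region.UTR5),
            (99, Region.UTR5),
            (100, Region.CDS),
            (699, Region.CDS),
            (700, Region.UTR3),
            (999, Region.UTR3),
        ],
    )
    def test_half_open_boundaries(self, toy_model, pos, expected):
        assert region_of(toy_model, pos) is expected

    @pytest.mark.parametrize("pos", [-1, 1000])
    def test_out_of_range(self, toy_model, pos):
        with pytest.raises(IndexError):
            region_of(toy_model, pos)

    def test_partition_covers_transcript(self, toy_model):
        """region_of partitions [0, length) into three contiguous blocks whose
        sizes are the annotated extents."""
        regions = [region_of(toy_model, p) for p in range(toy_model.length)]
        sizes = {r: regions.count(r) for r in Region}
        assert sizes[Region.UTR5] == toy_model.utr5_len
        assert sizes[Region.CDS] == toy_model.cds_len
        assert sizes[Region.UTR3] == toy_model.utr3_len
        # contiguity: no region reappears after it has ended
        assert regions == sorted(regions, key=[Region.UTR5, Region.CDS, Region.UTR3].index)


class TestRepresentativeTranscript:
    def test_singleton(self):
        m = make_model(transcript_id="t1")
        assert representative_transcript([m]) == "t1"

    def test_longest_cds_wins(self):
        a = make_model(cds=300, transcript_id="a")
        b = make_model(cds=450, transcript_id="b")
        assert representative_transcript([a, b]) == "b"

    def test_cds_tie_broken_by_transcript_length(self):
        a = make_model(cds=300, utr3=100, transcript_id="a")  # length 500
        b = make_model(cds=300, utr3=200, transcript_id="b")  # length 600
        assert representative_transcript([a, b]) == "b"

    def test_full_tie_broken_lexicographically(self):
        a = make_model(transcript_id="zzz")
        b = make_model(transcript_id="aaa")
        assert representative_transcript([a, b]) == "aaa"

    def test_empty_collection_is_logic_error(self):
        with pytest.raises(ValueError):
            representative_transcript([])


class TestModelInvariants:
    def test_extent_sum_enforced(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("t", "g", length=100, utr5_len=10, cds_len=60, utr3_len=40)

    def test_sequence_length_enforced(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("t", "g", 9, 3, 3, 3, sequence="ATG")
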