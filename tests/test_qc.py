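"""Region distribution, start-codon metagene profiles and periodicity."""

import numpy as np
import pytest

from riboprof.alignments import (
    FootprintRecord,
    LengthWindows,
    RPF_WINDOWS,
    filter_by_length,
    read_alignments,
)
from riboprof.annotation import Region, TranscriptSet, load_transcripts
from riboprof.psite import annotate_stream, assign_sites
from riboprof.qc import (
    FrameDistribution,
    frame_distribution,
    metagene_start_profile,
    periodicity_score,
    region_distribution,
)
from riboprof.simulate import SimConfig, make_transcriptome, simulate_rna
from tests.conftest import make_model


@pytest.fixture(scope="module")
def uniform_rna(tmp_path_factory):
    """Uniform RNA-seq coverage on a single (100, 600, 300)-nt transcript."""
    out = tmp_path_factory.mktemp("rna_uniform")
    config = SimConfig(
        n_genes=1,
        utr5_range=(100, 100),
        cds_codons_range=(200, 200),
        utr3_range=(300, 300),
        n_reads=50_000,
        seed=11,
    )
    tx = make_transcriptome(config, out)
    simulate_rna(config, tx, out / "rna.sam", library_index=101)
    ts = load_transcripts(out / "annotation.gff3")
    return ts, out / "rna.sam"


class TestRegionDistribution:
    def test_all_cds_psites(self, toy_model, toy_set):
        records = [
            assign_sites(FootprintRecord("txA", toy_model.utr5_len - 12 + 3 * k, 28),
                         toy_model)
            for k in range(50)
        ]
        dist = region_distribution(records, toy_set, mode="psite")
        assert dist.fractions[Region.CDS] == 1.0
        assert dist.counts[Region.UTR5] == dist.counts[Region.UTR3] == 0

    def test_uniform_rna_tracks_region_lengths(self, uniform_rna):
        """5'-end-anchored fractions on a (100, 600, 300) transcript approach
        (0.1, 0.6, 0.3), the multinomial expectation."""
        ts, sam = uniform_rna
        dist = region_distribution(read_alignments(sam, ts), ts, mode="five_prime")
        assert dist.fractions[Region.UTR5] == pytest.approx(0.1, abs=0.02)
        assert dist.fractions[Region.CDS] == pytest.approx(0.6, abs=0.02)
        assert dist.fractions[Region.UTR3] == pytest.approx(0.3, abs=0.02)

    def test_empty_input_flagged_undefined(self, toy_set):
        dist = region_distribution([], toy_set, mode="psite")
        assert not dist.defined
        assert all(np.isnan(v) for v in dist.fractions.values())

    def test_order_and_duplication_invariance(self, toy_model, toy_set):
        records = [
            assign_sites(FootprintRecord("txA", fp, 28), toy_model)
            for fp in (10, 200, 500, 850)
        ]
        base = region_distribution(records, toy_set).fractions
        shuffled = region_distribution(records[::-1], toy_set).fractions
        doubled = region_distribution(records * 2, toy_set).fractions
        assert base == shuffled == doubled


class TestMetageneProfile:
    def test_modal_position_is_minus_offset(self, sim_dataset):
        """Simulated initiating ribosomes put the 5'-end mode exactly 12 nt
        upstream of the start codon, in both RPF length classes."""
        ts = sim_dataset["transcripts"]
        records = filter_by_length(
            read_alignments(sim_dataset["ribo_sam"], ts), RPF_WINDOWS
        )
        profiles = metagene_start_profile(records, ts, length_classes=RPF_WINDOWS)
        assert profiles["20-22"].modal_position() == -12
        assert profiles["27-29"].modal_position() == -12

    def test_out_of_window_records_not_counted(self, toy_set):
        records = [FootprintRecord("txA", 500, 28)]  # rel = +400
        profiles = metagene_start_profile(records, toy_set, window=(-40, 60))
        assert profiles["all"].total == 0

    def test_window_keys_exactly_cover_range(self, toy_set):
        profiles = metagene_start_profile([], toy_set, window=(-5, 7))
        assert sorted(profiles["all"].counts) == list(range(-5, 8))

    def test_counts_never_exceed_input(self, sim_dataset):
        ts = sim_dataset["transcripts"]
        records = list(read_alignments(sim_dataset["ribo_sam"], ts))
        profiles = metagene_start_profile(records, ts, length_classes=RPF_WINDOWS)
        assert sum(p.total for p in profiles.values()) <= len(records)

    def test_uniform_rna_has_no_dominant_position(self, uniform_rna):
        """Flat coverage leaves no single window position holding >5% of the
        metagene mass."""
        ts, sam = uniform_rna
        profiles = metagene_start_profile(read_alignments(sam, ts), ts)
        fractions = profiles["all"].fractions()
        assert max(fractions.values()) < 0.05


class TestFrameDistribution:
    def test_pure_frame_zero(self, toy_model):
        records = [
            assign_sites(FootprintRecord("txA", toy_model.utr5_len - 12 + 3 * k, 28),
                         toy_model)
            for k in range(30)
        ]
        fd = frame_distribution(records)
        assert fd.fractions("all") == (1.0, 0.0, 0.0)

    def test_fidelity_sets_frame_zero_fraction(self, sim_dataset):
        """Fidelity 0.9 with ±1-nt jitter on the remainder gives a frame-0
        fraction within a binomial bound of 0.9 in each length class."""
        ts = sim_dataset["transcripts"]
        records = filter_by_length(
            read_alignments(sim_dataset["ribo_sam"], ts), RPF_WINDOWS
        )
        fd = frame_distribution(annotate_stream(records, ts), RPF_WINDOWS)
        for label in ("20-22", "27-29"):
            assert fd.fractions(label)[0] == pytest.approx(0.9, abs=0.015)

    def test_rna_frames_uniform(self, uniform_rna):
        """RNA-seq reads processed identically show no triplet phasing."""
        ts, sam = uniform_rna
        fd = frame_distribution(annotate_stream(read_alignments(sam, ts), ts))
        for frac in fd.fractions("all"):
            assert frac == pytest.approx(1 / 3, abs=0.02)


class TestPeriodicityScore:
    @pytest.mark.parametrize(
        "counts,expected",
        [([100, 0, 0], 1.0), ([100, 100, 100], 1 / 3), ([90, 6, 4], 0.9)],
    )
    def test_max_frame_fraction(self, counts, expected):
        fd = FrameDistribution(counts={"all": counts})
        assert periodicity_score(fd)["all"] == pytest.approx(expected)

    def test_empty_class_flagged_undefined(self):
        fd = FrameDistribution(counts={"all": [0, 0, 0]})
        assert periodicity_score(fd)["all"] is None
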