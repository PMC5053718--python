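"""Transcript models, coordinate mapping, BED/TSV I/O, event assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipribo.annotation import (
    AnnotationError,
    GeneClass,
    GeneCountTable,
    RTStopRecord,
    TranscriptModel,
    canonical_transcripts,
    classify_rt_stops,
    read_count_table,
    read_rt_stops,
    read_transcripts,
    region_distribution,
    transcript_sequence,
    write_count_table,
    write_rt_stops,
    write_transcripts,
)
from conftest import make_model


def brute_force_region_lengths(blocks, cds, strand):
    """Independent oracle: enumerate every exonic genomic position and
    count positions before/inside/after the thick interval in
    transcript orientation."""
    positions = [p for s, e in blocks for p in range(s, e)]
    if strand == "-":
        positions = positions[::-1]
    u5 = sum(1 for p in positions if (p < cds[0]) == (strand == "+") and not cds[0] <= p < cds[1])
    inside = sum(1 for p in positions if cds[0] <= p < cds[1])
    return u5, inside, len(positions) - u5 - inside


class TestReadTranscripts:
    def write_bed(self, tmp_path, lines):
        p = tmp_path / "tx.bed"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_single_exon_plus(self, tmp_path):
        p = self.write_bed(
            tmp_path,
            ["chr1\t0\t300\tT1|G1|mRNA\t0\t+\t100\t250\t0\t1\t300\t0"],
        )
        (m,) = read_transcripts(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (100, 150, 50)
        assert m.mature_length == 300

    def test_single_exon_minus_mirrors(self, tmp_path):
        p = self.write_bed(
            tmp_path,
            ["chr1\t0\t300\tT1|G1|mRNA\t0\t-\t100\t250\t0\t1\t300\t0"],
        )
        (m,) = read_transcripts(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (50, 150, 100)

    def test_two_exon_matches_brute_force(self, tmp_path):
        p = self.write_bed(
            tmp_path,
            ["chr1\t0\t300\tT1|G1|mRNA\t0\t+\t50\t250\t0\t2\t100,100\t0,200"],
        )
        (m,) = read_transcripts(p)
        assert m.mature_length == 200
        assert m.cds_len == 100
        expected = brute_force_region_lengths([(0, 100), (200, 300)], (50, 250), "+")
        assert (m.utr5_len, m.cds_len, m.utr3_len) == expected

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = self.write_bed(
            tmp_path,
            [
                "chr1\t0\t300\tT1\t0\t+\t100\t250\t0\t1\t300\t0",
                "chr1\tnot_an_int\t300\tT2\t0\t+",
            ],
        )
        with pytest.raises(AnnotationError, match=":2"):
            read_transcripts(p)

    def test_thick_outside_exons_rejected(self, tmp_path):
        p = self.write_bed(
            tmp_path,
            ["chr1\t100\t300\tT1\t0\t+\t50\t250\t0\t1\t200\t0"],
        )
        with pytest.raises(AnnotationError, match="thick"):
            read_transcripts(p)

    def test_roundtrip_through_writer(self, tmp_path, two_exon_model):
        p = tmp_path / "out.bed"
        write_transcripts([two_exon_model], p)
        (m,) = read_transcripts(p)
        assert m == two_exon_model


class TestCoordinateMapping:
    def test_plus_strand_identity(self, toy_model):
        assert toy_model.genomic_to_transcript(10) == 10

    def test_minus_strand_mirror(self, toy_model_minus):
        assert toy_model_minus.genomic_to_transcript(10) == 289

    def test_intronic_is_absent(self, two_exon_model):
        assert two_exon_model.genomic_to_transcript(150) is None

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.data(),
        strand=st.sampled_from("+-"),
        n_exons=st.integers(1, 4),
    )
    def test_round_trip_all_exonic_positions(self, data, strand, n_exons):
        """genomic->transcript->genomic is the identity on every exonic
        position, for randomized exon structures on both strands."""
        bounds = sorted(
            data.draw(
                st.lists(
                    st.integers(0, 500),
                    min_size=2 * n_exons,
                    max_size=2 * n_exons,
                    unique=True,
                )
            )
        )
        blocks = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
        m = make_model(blocks, strand=strand)
        tpositions = set()
        for s, e in blocks:
            for g in range(s, e):
                t = m.genomic_to_transcript(g)
                assert t is not None
                assert m.transcript_to_genomic(t) == g
                tpositions.add(t)
        assert tpositions == set(range(m.mature_length))

    def test_flank_projection_both_strands(self):
        m_plus = make_model([(100, 200)], cds=(120, 180))
        assert m_plus.genomic_to_transcript_with_flank(95, 10) == -5
        assert m_plus.genomic_to_transcript_with_flank(205, 10) == 105
        m_minus = make_model([(100, 200)], cds=(120, 180), strand="-")
        assert m_minus.genomic_to_transcript_with_flank(205, 10) == -6
        assert m_minus.genomic_to_transcript_with_flank(95, 10) == 104
        assert m_plus.genomic_to_transcript_with_flank(80, 10) is None


class TestPartitionRegions:
    def test_basic_partition(self, toy_model):
        assert toy_model.partition_regions() == {
            "UTR5": (0, 100),
            "CDS": (100, 250),
            "UTR3": (250, 300),
        }

    def test_zero_length_utr5(self):
        m = make_model([(0, 200)], cds=(0, 150))
        assert m.partition_regions()["UTR5"] == (0, 0)

    def test_two_exon_partition_via_projection(self, two_exon_model):
        assert two_exon_model.partition_regions() == {
            "UTR5": (0, 50),
            "CDS": (50, 150),
            "UTR3": (150, 200),
        }

    def test_noncoding_raises(self):
        m = make_model([(0, 200)], cls=GeneClass.LNCRNA)
        with pytest.raises(AnnotationError, match="CDS"):
            m.partition_regions()

    @settings(max_examples=50, deadline=None)
    @given(
        u5=st.integers(0, 50),
        cds=st.integers(1, 60).map(lambda k: 3 * k),
        u3=st.integers(0, 50),
        strand=st.sampled_from("+-"),
    )
    def test_partition_tiles_mature_length(self, u5, cds, u3, strand):
        total = u5 + cds + u3
        if strand == "+":
            thick = (u5, u5 + cds)
        else:
            thick = (u3, u3 + cds)
        m = make_model([(0, total)], cds=thick, strand=strand)
        parts = m.partition_regions()
        assert parts["UTR5"][0] == 0
        assert parts["UTR5"][1] == parts["CDS"][0]
        assert parts["CDS"][1] == parts["UTR3"][0]
        assert parts["UTR3"][1] == m.mature_length
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (u5, cds, u3)


def _class_fixture_models():
    """Five sense-strand transcripts, one per RNA class, on disjoint loci."""
    classes = [
        GeneClass.MRNA,
        GeneClass.RRNA,
        GeneClass.PSEUDOGENE,
        GeneClass.LNCRNA,
        GeneClass.OTHER,
    ]
    models = []
    for i, cls in enumerate(classes):
        lo = 1000 * i
        cds = (lo + 100, lo + 250) if cls == GeneClass.MRNA else None
        models.append(
            make_model(
                [(lo, lo + 300)], cds=cds, tid=f"T{i}", gid=f"G{i}", cls=cls
            )
        )
    return models


class TestClassifyRTStops:
    def test_all_mrna(self, toy_model):
        stops = [RTStopRecord("chr1", p, "+", 1) for p in (5, 120, 260)]
        frac = classify_rt_stops(stops, [toy_model])
        assert frac["mRNA"] == 1.0

    def test_paper_style_class_fractions(self):
        """Counts 639/274/55/1/31 over the five classes reproduce the
        63.9/27.4/5.5/0.1/3.1 percent split."""
        models = _class_fixture_models()
        counts = [639, 274, 55, 1, 31]
        stops = [
            RTStopRecord("chr1", 1000 * i + 150, "+", c)
            for i, c in enumerate(counts)
        ]
        frac = classify_rt_stops(stops, models)
        assert frac == pytest.approx(
            {
                "mRNA": 0.639,
                "rRNA": 0.274,
                "pseudogene": 0.055,
                "lncRNA": 0.001,
                "other": 0.031,
            }
        )
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_priority_on_overlap_conserves_total(self):
        """A stop under both an mRNA and a pseudogene is assigned once,
        to the higher-priority class; totals are conserved."""
        mrna = make_model([(0, 300)], cds=(100, 250), tid="Tm", gid="Gm")
        pseudo = make_model(
            [(0, 300)], tid="Tp", gid="Gp", cls=GeneClass.PSEUDOGENE
        )
        stops = [RTStopRecord("chr1", 150, "+", 4), RTStopRecord("chr1", 150, "+", 6)]
        frac = classify_rt_stops(stops, [mrna, pseudo])
        assert frac["mRNA"] == 1.0
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_antisense_falls_to_other(self, toy_model):
        stops = [RTStopRecord("chr1", 150, "-", 3)]
        frac = classify_rt_stops(stops, [toy_model])
        assert frac["other"] == 1.0

    def test_unique_weighting_flag(self, toy_model):
        other = make_model(
            [(1000, 1300)], tid="T2", gid="G2", cls=GeneClass.LNCRNA
        )
        stops = [
            RTStopRecord("chr1", 150, "+", 99),
            RTStopRecord("chr1", 1100, "+", 1),
        ]
        by_count = classify_rt_stops(stops, [toy_model, other])
        by_pos = classify_rt_stops(stops, [toy_model, other], weight="unique")
        assert by_count["mRNA"] == 0.99
        assert by_pos["mRNA"] == 0.5

    def test_empty_raises(self, toy_model):
        with pytest.raises(AnnotationError):
            classify_rt_stops([], [toy_model])


class TestRegionDistribution:
    def test_all_utr5(self, toy_model):
        stops = [RTStopRecord("chr1", p, "+", 1) for p in (0, 50, 99)]
        frac = region_distribution(stops, [toy_model])
        assert frac == {"UTR5": 1.0, "CDS": 0.0, "UTR3": 0.0}

    def test_hand_counted_fractions(self, toy_model):
        stops = [RTStopRecord("chr1", 10, "+", 2), RTStopRecord("chr1", 120, "+", 1)]
        frac = region_distribution(stops, [toy_model])
        assert frac["UTR5"] == pytest.approx(2 / 3)
        assert frac["CDS"] == pytest.approx(1 / 3)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_stops_match_region_lengths(self, toy_model, rng):
        """With many uniform events the fractions approach region-length
        proportions (law of large numbers)."""
        n = 100_000
        positions = rng.integers(0, 300, n)
        agg = pd.Series(positions).value_counts()
        stops = [
            RTStopRecord("chr1", int(p), "+", int(c)) for p, c in agg.items()
        ]
        frac = region_distribution(stops, [toy_model])
        assert frac["UTR5"] == pytest.approx(100 / 300, abs=0.01)
        assert frac["CDS"] == pytest.approx(150 / 300, abs=0.01)
        assert frac["UTR3"] == pytest.approx(50 / 300, abs=0.01)

    def test_no_coding_stops_raises(self, toy_model):
        with pytest.raises(AnnotationError):
            region_distribution([RTStopRecord("chr2", 5, "+", 1)], [toy_model])


class TestCanonicalTranscripts:
    def test_longest_per_gene(self):
        short = make_model([(0, 200)], cds=(50, 150), tid="Ta", gid="G")
        long_ = make_model([(0, 400)], cds=(50, 350), tid="Tb", gid="G")
        assert canonical_transcripts([short, long_])["G"] is long_


class TestCountTableIO:
    def test_roundtrip_and_metadata(self, tmp_path):
        counts = pd.DataFrame(
            {"s1": [10, 20], "s2": [5, 0]}, index=["G1", "G2"]
        )
        samples = pd.DataFrame(
            {
                "assay": ["RPF", "RNA"],
                "condition": ["untreated", "untreated"],
                "cell_line": ["Rluc", "Rluc"],
            },
            index=["s1", "s2"],
        )
        table = GeneCountTable(counts=counts, samples=samples)
        write_count_table(table, tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = read_count_table(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, counts, check_names=False)
        assert back.select(assay="RPF") == ["s1"]

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["G1", "G2"])
        samples = pd.DataFrame(
            {"assay": ["RPF"], "condition": ["untreated"], "cell_line": ["Rluc"]},
            index=["s1"],
        )
        with pytest.raises(AnnotationError, match="library size"):
            GeneCountTable(counts=counts, samples=samples)


class TestStopIO:
    def test_roundtrip(self, tmp_path):
        stops = [RTStopRecord("chr1", 5, "+", 3), RTStopRecord("chr1", 9, "-", 1)]
        write_rt_stops(stops, tmp_path / "s.bed")
        back = read_rt_stops(tmp_path / "s.bed")
        assert [(s.chrom, s.pos, s.strand, s.count) for s in back] == [
            ("chr1", 5, "+", 3),
            ("chr1", 9, "-", 1),
        ]

    def test_wide_record_rejected(self, tmp_path):
        (tmp_path / "bad.bed").write_text("chr1\t5\t8\t.\t3\t+\n")
        with pytest.raises(AnnotationError, match="1 nt"):
            read_rt_stops(tmp_path / "bad.bed")


def test_transcript_sequence_minus_strand_revcomp():
    m = make_model([(0, 4)], cds=None, strand="-", cls=GeneClass.LNCRNA)
    assert transcript_sequence(m, {"chr1": "ACGT"}) == "ACGT"
    m2 = make_model([(0, 4)], cds=None, strand="-", cls=GeneClass.LNCRNA)
    assert transcript_sequence(m2, {"chr1": "AAGT"}) == "ACTT"
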