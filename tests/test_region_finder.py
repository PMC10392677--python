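"""Genomic interval logic: promoter selection, methylation intersection,
model-region assembly, BED conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnamech import (GenomicInterval, assemble_model_region,
                     intersect_methylation, promoters_with_peaks, read_bed,
                     write_bed)
from dnamech.region_finder import Promoter
from dnamech.synthetic_data import (NDUFA13_REGION, generate_intervals,
                                    ndufa13_region_fixture)


def _brute_force_qualifying(tss, tracks, window, min_tracks=2):
    """O(n^2) all-pairs oracle for the promoter-peak intersection."""
    out = []
    for t in tss:
        lo, hi = t.start - window, t.end + window
        hit = 0
        for track in tracks:
            if any(p.chromosome == t.chromosome
                   and p.start <= hi and p.end >= lo for p in track):
                hit += 1
        if hit >= min_tracks:
            out.append(t.start)
    return out


class TestIntervals:
    def test_studied_region_is_49_bp(self):
        chrom, start, end = NDUFA13_REGION
        region = GenomicInterval(chrom, start, end)
        assert region.length == 49

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 50)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 10**6), st.integers(0, 10**4))
    def test_length_arithmetic_exact(self, start, span):
        iv = GenomicInterval("chr1", start, start + span)
        assert iv.length == span + 1


class TestPromoterSelection:
    def test_peak_50bp_from_tss_retained(self):
        tss = [GenomicInterval("chr1", 10_000, 10_000)]
        near = [GenomicInterval("chr1", 10_050, 10_090)]
        out = promoters_with_peaks(tss, [near, near], window=200)
        assert len(out) == 1

    def test_peak_300bp_away_dropped(self):
        tss = [GenomicInterval("chr1", 10_000, 10_000)]
        far = [GenomicInterval("chr1", 10_300, 10_340)]
        out = promoters_with_peaks(tss, [far, far], window=200)
        assert out == []

    def test_single_track_insufficient(self):
        tss = [GenomicInterval("chr1", 10_000, 10_000)]
        near = [GenomicInterval("chr1", 10_050, 10_090)]
        assert promoters_with_peaks(tss, [near, []], window=200) == []

    def test_fixture_matches_brute_force_oracle(self, tmp_path):
        truth = generate_intervals(tmp_path, n_promoters=10,
                                   n_qualifying=3, seed=7)
        tss = read_bed(truth["paths"]["tss"])
        tracks = [read_bed(truth["paths"]["peaks1"]),
                  read_bed(truth["paths"]["peaks2"])]
        got = promoters_with_peaks(tss, tracks, window=truth["window"])
        brute = _brute_force_qualifying(tss, tracks, truth["window"])
        assert sorted(p.tss.start for p in got) == sorted(brute)
        assert sorted(p.tss.start for p in got) == sorted(truth["qualifying_tss"])

    def test_random_fixtures_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tss = [GenomicInterval("chr1", int(p), int(p))
                   for p in rng.integers(1000, 50_000, size=8)]
            tracks = [[GenomicInterval("chr1", int(s), int(s) + 30)
                       for s in rng.integers(1000, 50_000, size=15)]
                      for _ in range(3)]
            window = int(rng.integers(50, 400))
            got = promoters_with_peaks(tss, tracks, window=window)
            brute = _brute_force_qualifying(tss, tracks, window)
            assert sorted(p.tss.start for p in got) == sorted(brute)


class TestMethylationIntersection:
    def test_no_sites_counts_zero(self):
        p = Promoter(tss=GenomicInterval("chr1", 5000, 5000),
                     window=GenomicInterval("chr1", 4800, 5200))
        out = intersect_methylation([p], [])
        assert out[0].cpg_count == 0

    def test_fourteen_sites_in_promoter_window(self, tmp_path):
        truth = ndufa13_region_fixture(tmp_path)
        tss = GenomicInterval("chr19", truth["tss"], truth["tss"])
        p = Promoter(tss=tss, window=GenomicInterval(
            "chr19", tss.start - 500, tss.end + 500))
        sites = read_bed(truth["paths"]["methylation"])
        out = intersect_methylation([p], sites, window=500)
        assert out[0].cpg_count == 14
        assert out[0].mean_methylation == pytest.approx(75.0)

    def test_window_boundaries_inclusive(self):
        tss = GenomicInterval("chr1", 10_000, 10_000)
        p = Promoter(tss=tss, window=GenomicInterval("chr1", 9800, 10_200))
        sites = [GenomicInterval("chr1", 9800, 9800),   # exactly on edge
                 GenomicInterval("chr1", 10_200, 10_200),
                 GenomicInterval("chr1", 9799, 9799),   # just outside
                 GenomicInterval("chr1", 10_201, 10_201)]
        out = intersect_methylation([p], sites)
        # brute-force inclusive-boundary count
        expected = sum(1 for s in sites
                       if p.window.start <= s.start <= p.window.end)
        assert out[0].cpg_count == expected == 2


class TestModelRegion:
    RES = [("E2F1DP1", 19_626_904, 19_626_911),
           ("CEBPB", 19_626_924, 19_626_931)]

    def test_studied_interval_assembles_to_49_bp(self):
        chrom, start, end = NDUFA13_REGION
        region = assemble_model_region(GenomicInterval(chrom, start, end),
                                       self.RES, flank=0)
        assert region.length == 49
        assert region.re_positions["E2F1DP1"] == (7, 14)

    def test_six_methylcytosines_from_marks(self):
        chrom, start, end = NDUFA13_REGION
        sites = [start + off - 1 for off in (12, 14, 20, 24, 35, 36)]
        region = assemble_model_region(GenomicInterval(chrom, start, end),
                                       self.RES, flank=0,
                                       methylation_sites=sites)
        kinds = [k for _, k in region.methylation]
        assert kinds.count("single") == 4
        assert kinds.count("double") == 1
        assert region.n_methylcytosines == 6

    def test_zero_flank_degenerate_length_is_re_span(self):
        iv = GenomicInterval("chr19", 19_626_904, 19_626_911)
        region = assemble_model_region(iv, [self.RES[0]], flank=0)
        assert region.length == 8

    def test_re_outside_interval_rejected(self):
        iv = GenomicInterval("chr19", 19_626_910, 19_626_940)
        with pytest.raises(ValueError, match="outside"):
            assemble_model_region(iv, self.RES, flank=0)

    def test_fasta_export(self, tmp_path):
        iv = GenomicInterval("chr1", 1, 8)
        region = assemble_model_region(iv, [("RE", 2, 5)], flank=0,
                                       sequence="ACGTACGT")
        path = tmp_path / "region.fa"
        region.to_fasta(path)
        from Bio import SeqIO
        rec = next(SeqIO.parse(str(path), "fasta"))
        assert str(rec.seq) == "ACGTACGT"


class TestBedConvention:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        ivs = [GenomicInterval("chr19", 19_626_898, 19_626_946, strand="+",
                               score=75.0, name="region")]
        path = tmp_path / "x.bed"
        write_bed(ivs, path, scores=True)
        back = read_bed(path)
        assert back[0].start == 19_626_898
        assert back[0].end == 19_626_946
        assert back[0].length == 49
        assert back[0].score == 75.0
        # on disk: 0-based half-open
        cols = path.read_text().split()
        assert cols[1] == "19626897" and cols[2] == "19626946"

    def test_malformed_line_reports_line_number(self, tmp_path):
        from dnamech import FormatError
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\nchr1\tten\t30\n")
        with pytest.raises(FormatError, match=":2:"):
            read_bed(path)
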