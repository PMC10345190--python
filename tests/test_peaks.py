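"""IP/input normalization, window Fisher tests, BH FDR and peak calling."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from boundary_m6a.peaks import (
    CoverageTrack,
    ExpressionRecord,
    WindowTest,
    attach_fdr,
    bh_fdr,
    call_peaks,
    enrichment_track,
    exon_methylation_census,
    fpkm_filter,
    peaks_bed,
    read_bedgraph,
    scan_windows,
    write_bedgraph,
)
from boundary_m6a.simulate import generate_ip_coverage


class TestEnrichment:
    def test_identical_tracks_unity(self):
        t = CoverageTrack(np.full(100, 5.0))
        assert np.allclose(enrichment_track(t, t), 1.0)

    def test_fourfold(self):
        ip = CoverageTrack(np.full(50, 8.0), library_size=1000)
        inp = CoverageTrack(np.full(50, 2.0), library_size=1000)
        assert np.allclose(enrichment_track(ip, inp), 4.0)

    def test_library_normalization(self):
        ip = CoverageTrack(np.full(50, 2.0), library_size=500)
        inp = CoverageTrack(np.full(50, 2.0), library_size=1000)
        assert np.allclose(enrichment_track(ip, inp), 2.0)

    def test_zero_input_is_nan(self):
        ip = CoverageTrack(np.array([1.0, 1.0]), library_size=10)
        inp = CoverageTrack(np.array([1.0, 0.0]), library_size=10)
        e = enrichment_track(ip, inp)
        assert e[0] == 1.0 and np.isnan(e[1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            enrichment_track(CoverageTrack(np.ones(5)), CoverageTrack(np.ones(6)))


class TestScanWindows:
    def test_enriched_window_detected(self):
        """100 IP reads vs 10 input reads in one window at equal library
        sizes 1000: odds ratio about 11, p far below 0.001."""
        ip_cov = np.zeros(40)
        in_cov = np.zeros(40)
        ip_cov[:20] = 5.0          # 100 reads in window 1
        in_cov[:20] = 0.5          # 10 reads
        ip = CoverageTrack(ip_cov, library_size=1000)
        inp = CoverageTrack(in_cov, library_size=1000)
        tests = scan_windows(ip, inp)
        w = tests[0]
        assert (w.ip_count, w.input_count) == (100, 10)
        assert w.enrichment == pytest.approx(10.0)
        assert w.p_value < 1e-3

    def test_symmetric_counts_null(self):
        ip = CoverageTrack(np.full(20, 2.0), library_size=500)
        inp = CoverageTrack(np.full(20, 2.0), library_size=500)
        (w,) = scan_windows(ip, inp)
        assert w.p_value == pytest.approx(1.0)
        assert w.enrichment == pytest.approx(1.0)

    def test_empty_window_contract(self):
        ip = CoverageTrack(np.zeros(20), library_size=100)
        inp = CoverageTrack(np.zeros(20), library_size=100)
        (w,) = scan_windows(ip, inp)
        assert w.p_value == 1.0 and np.isnan(w.enrichment)

    def test_tiling_is_non_overlapping(self):
        ip = CoverageTrack(np.ones(95))
        tests = scan_windows(ip, CoverageTrack(np.ones(95)))
        assert [t.start for t in tests] == [0, 20, 40, 60]
        assert all(t.end - t.start == 20 for t in tests)


def brute_force_bh(p):
    """Direct step-up definition: q_i = min over j with p_(j) >= p_(i) of
    p_(j) * m / rank(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = min(running, 1.0)
    return q


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_order_stability(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        q = bh_fdr(p)
        assert np.allclose(q, brute_force_bh(p))
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _window(start, fold, q):
    return WindowTest(start, start + 20, 10, 5, fold, 0.001, q)


class TestCallPeaks:
    def test_three_windows_merge_to_60nt(self):
        tests = [_window(s, 4.0, 0.01) for s in (0, 20, 40)]
        (peak,) = call_peaks(tests)
        assert (peak.start, peak.end) == (0, 60)
        assert len(peak.windows) == 3

    def test_isolated_window_below_min_length(self):
        assert call_peaks([_window(0, 4.0, 0.01)]) == []

    def test_no_significant_windows(self):
        tests = [_window(s, 1.5, 0.5) for s in (0, 20, 40)]
        assert call_peaks(tests) == []

    def test_strict_thresholds(self):
        """fold == 2 and q == 0.05 are both excluded (strict inequalities)."""
        tests = [
            _window(0, 2.0, 0.01), _window(20, 4.0, 0.05),
            _window(40, 4.0, 0.01), _window(60, 4.0, 0.01),
        ]
        (peak,) = call_peaks(tests)
        assert (peak.start, peak.end) == (40, 80)

    def test_gap_splits_runs(self):
        tests = [_window(s, 4.0, 0.01) for s in (0, 20, 60, 80, 100)]
        peaks = call_peaks(tests)
        assert [(p.start, p.end) for p in peaks] == [(0, 40), (60, 120)]

    def test_summit_is_max_enrichment_window(self):
        tests = [_window(0, 3.0, 0.01), _window(20, 9.0, 0.01), _window(40, 4.0, 0.01)]
        (peak,) = call_peaks(tests)
        assert peak.summit == 30

    def test_peaks_never_overlap_and_cover_significant_windows(self, rng):
        tests = []
        for s in range(0, 4000, 20):
            sig = rng.random() < 0.3
            tests.append(_window(s, 5.0 if sig else 1.0, 0.01 if sig else 0.9))
        peaks = call_peaks(tests)
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start
        for p in peaks:
            assert all(w.enrichment > 2 and w.q_value < 0.05 for w in p.windows)
            assert p.end - p.start >= 40


class TestFpkm:
    def test_inclusive_threshold(self):
        recs = [
            ExpressionRecord("hi", 100, 1.0),      # FPKM 100 at 1e6 reads
            ExpressionRecord("edge", 1, 1.0),      # FPKM exactly 1
            ExpressionRecord("low", 0.99, 1.0),    # FPKM 0.99
            ExpressionRecord("zero", 0, 1.0),
        ]
        kept = {r.transcript_id for r in fpkm_filter(recs, mapped_millions=1.0)}
        assert kept == {"hi", "edge"}

    def test_fpkm_formula(self):
        assert ExpressionRecord("t", 100, 1.0).fpkm(1.0) == pytest.approx(100.0)

    def test_zero_length_error(self):
        with pytest.raises(ValueError):
            ExpressionRecord("t", 10, 0.0).fpkm(1.0)


class TestCensus:
    def test_no_peaks_all_unmethylated(self):
        c = exon_methylation_census([], [(0, 100), (200, 300)])
        assert c["with_m6a"] == 0 and c["without_m6a"] == 2

    def test_peak_inside_exon_counts_once(self):
        from boundary_m6a.peaks import Peak
        peak = Peak(120, 180, [_window(120, 4.0, 0.01)])
        c = exon_methylation_census([peak], [(100, 200), (300, 400)])
        assert c["with_m6a"] == 1 and c["without_m6a"] == 1

    def test_one_base_overlap_counts(self):
        from boundary_m6a.peaks import Peak
        peak = Peak(99, 140, [])
        c = exon_methylation_census([peak], [(0, 100)])
        assert c["with_m6a"] == 1

    def test_long_exons_excluded(self):
        c = exon_methylation_census([], [(0, 500)], max_len=200)
        assert c["with_m6a"] + c["without_m6a"] == 0

    def test_rac_census(self):
        c = exon_methylation_census([], [(0, 10), (10, 20)], ["GGACG" * 2, "TTTTT" * 2])
        assert c["with_rac"] == 1 and c["without_rac"] == 1

    def test_planted_fixture_recovered(self, rng):
        """The methylated-exon census equals the planted methylated set."""
        exons = [(i * 300, i * 300 + 150) for i in range(20)]
        methylated = {2, 7, 11}
        intervals = [(exons[i][0] + 40, exons[i][0] + 100) for i in sorted(methylated)]
        ip, inp = generate_ip_coverage(6000, intervals, 30, 6, seed=1)
        tests = scan_windows(ip, inp)
        attach_fdr(tests)
        called = call_peaks(tests)
        c = exon_methylation_census(called, exons, max_len=200)
        assert c["with_m6a"] == len(methylated)
        assert c["without_m6a"] == 20 - len(methylated)


class TestBedgraphIO:
    def test_round_trip(self, tmp_path, rng):
        cov = rng.poisson(3, 500).astype(float)
        track = CoverageTrack(cov)
        path = str(tmp_path / "t.bedGraph")
        write_bedgraph(track, path)
        back = read_bedgraph(path, 500)
        assert np.allclose(back.coverage, cov)
        assert back.library_size == pytest.approx(track.library_size)

    def test_bed_export(self):
        tests = [_window(s, 4.0, 0.001) for s in (0, 20)]
        (peak,) = call_peaks(tests)
        bed = peaks_bed([peak], "chr2")
        assert bed.iloc[0]["chrom"] == "chr2"
        assert bed.iloc[0]["end"] - bed.iloc[0]["start"] == 40
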