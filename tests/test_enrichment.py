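"""Window geometry, enrichment normalization, site classification,
peak calling and meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from splicemark.enrichment import (
    build_windows,
    call_peaks_simple,
    classify_site,
    classify_sites,
    control_rate,
    enrichment_per_kb,
    merge_regions,
    meta_profile,
    peak_overlap_fraction,
    sample_controls,
    summarize_classes,
    window_read_counts,
)
from splicemark.types import ASEvent, CoverageTrack, Gene, GenomeAnnotation


def _event(strand="+", alt=(1000, 1100), up=(800, 900), down=(1200, 1300)):
    if strand == "-":
        up, down = down, up
    return ASEvent("ev1", "SE", "chrS1", strand, alt[0], alt[1], up, down, "g1")


def _uniform_track(value=2, length=4000, celltype="ct"):
    counts = np.full(length, value, dtype=np.int64)
    return CoverageTrack(celltype, {"chrS1": counts}, int(counts.sum()))


class TestWindows:
    def test_plus_strand_arithmetic(self):
        ws = build_windows(_event())
        assert ws.w_alt5 == (975, 1025)
        assert ws.w_alt3 == (1075, 1125)
        assert ws.w_up3 == (875, 925)
        assert ws.w_down5 == (1175, 1225)

    def test_minus_strand_mirrors_plus(self):
        ws = build_windows(_event(strand="-"))
        # 5'/3' swap under reflection: alt5 sits on the genomic right edge
        assert ws.w_alt5 == (1075, 1125)
        assert ws.w_alt3 == (975, 1025)
        assert ws.w_up3 == (1175, 1225)
        assert ws.w_down5 == (875, 925)

    def test_length_50_alt_element_windows_touch_exactly(self):
        ws = build_windows(_event(alt=(1000, 1050), down=(1150, 1250)))
        assert ws.w_alt5[1] == ws.w_alt3[0] == 1025

    def test_contig_edge_clipping_flagged(self):
        ev = _event(alt=(30, 130), up=(0, 20), down=(200, 300))
        ws = build_windows(ev, contig_length=315)
        assert ws.clipped
        assert ws.w_up3[0] == 0  # upstream 3' boundary at 20, left edge clipped
        assert ws.w_down5 == (175, 225)  # interior window untouched
        ws2 = build_windows(ev, contig_length=210)
        assert ws2.w_down5 == (175, 210)  # right edge clipped at the contig

    def test_counts_match_per_base_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.0, size=4000).astype(np.int64)
        track = CoverageTrack("ct", {"chrS1": counts}, int(counts.sum()))
        for strand in "+-":
            ws = build_windows(_event(strand=strand))
            got = window_read_counts(track, ws)
            for name, (s, t) in ws.windows():
                naive = sum(int(counts[i]) for i in range(s, t))
                assert got[name] == naive


class TestEnrichmentPerKb:
    def test_uniform_coverage_closed_form(self):
        track = _uniform_track(value=3)
        regions = [("chrS1", 100, 600), ("chrS1", 1000, 1250)]
        expected = 3 * 1000 * 1e7 / track.library_size
        assert enrichment_per_kb(track, regions) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_count_and_library_rescale(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=3000).astype(np.int64)
        t1 = CoverageTrack("a", {"chrS1": counts}, int(counts.sum()))
        t2 = CoverageTrack("a", {"chrS1": counts * 2}, int(counts.sum() * 2))
        regions = [("chrS1", 50, 800)]
        assert enrichment_per_kb(t1, regions) == pytest.approx(
            enrichment_per_kb(t2, regions), rel=1e-12
        )

    def test_empty_track_is_zero(self):
        track = CoverageTrack("a", {"chrS1": np.zeros(100, dtype=np.int64)}, 0)
        assert enrichment_per_kb(track, [("chrS1", 0, 100)]) == 0.0

    def test_zero_length_region_set_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            enrichment_per_kb(_uniform_track(), [])

    def test_overlapping_regions_merged_not_double_counted(self):
        track = _uniform_track(value=1)
        a = enrichment_per_kb(track, [("chrS1", 0, 100), ("chrS1", 50, 150)])
        b = enrichment_per_kb(track, [("chrS1", 0, 150)])
        assert a == b
        assert merge_regions([("chrS1", 0, 100), ("chrS1", 50, 150)]) == [("chrS1", 0, 150)]


class TestControls:
    def test_zero_request_empty(self, small_sim):
        annotation, events, _ = small_sim
        cs = sample_controls(annotation, events, 0, seed=7)
        assert cs.windows == []

    def test_seeded_reproducibility(self, small_sim):
        annotation, events, _ = small_sim
        a = sample_controls(annotation, events, 20, seed=7)
        b = sample_controls(annotation, events, 20, seed=7)
        assert [w.windows() for w in a.windows] == [w.windows() for w in b.windows]
        c = sample_controls(annotation, events, 20, seed=8)
        assert [w.windows() for w in a.windows] != [w.windows() for w in c.windows]

    def test_controls_only_from_as_free_genes(self, small_sim):
        annotation, events, _ = small_sim
        as_genes = {e.gene_id for e in events}
        cs = sample_controls(annotation, events, 25, seed=1)
        assert not set(cs.source_genes) & as_genes

    def test_shortfall_is_named(self, small_sim):
        annotation, events, _ = small_sim
        with pytest.raises(ValueError, match="short by"):
            sample_controls(annotation, events, 10**6, seed=1)

    def test_all_genes_as_raises(self):
        gene = Gene("g1", "chrS1", "+", [(0, 100), (200, 300), (400, 500)])
        ann = GenomeAnnotation({"chrS1": 600}, [gene])
        ev = ASEvent("e1", "SE", "chrS1", "+", 200, 300, (0, 100), (400, 500), "g1")
        with pytest.raises(ValueError, match="short by"):
            sample_controls(ann, [ev], 1, seed=0)


class TestClassify:
    def test_count_at_expectation_is_same(self):
        assert classify_site(50, 100, rate=0.5) == "same"

    def test_zero_count_at_expectation_fifty_is_lower(self):
        # exact Poisson tail: P(X=0 | mu=50) = e^-50 << 0.05
        assert classify_site(0, 100, rate=0.5) == "lower"

    def test_zero_rate_edge_cases(self):
        assert classify_site(0, 100, rate=0.0) == "same"
        assert classify_site(5, 100, rate=0.0) == "higher"

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20, size=200)
        vec = classify_sites(x, np.full(200, 200), rate=0.1)
        scal = [classify_site(int(v), 200, rate=0.1) for v in x]
        assert list(vec) == scal


class TestSummary:
    def test_genome_scale_worked_example_se(self):
        # 33,765 higher / 4,310 same / 3,765 lower of 41,840 sites
        classes = ["higher"] * 33765 + ["same"] * 4310 + ["lower"] * 3765
        s = summarize_classes(classes).set_index("class")
        assert s.loc["higher", "percent"] == 80.7
        assert s.loc["same", "percent"] == 10.3
        assert s.loc["lower", "percent"] == 9.0

    def test_genome_scale_worked_example_a3ss(self):
        classes = ["higher"] * 4141 + ["same"] * 2410 + ["lower"] * 752
        s = summarize_classes(classes).set_index("class")
        assert s.loc["higher", "percent"] == 56.7

    def test_single_class_is_100(self):
        s = summarize_classes(["higher"] * 5).set_index("class")
        assert s.loc["higher", "percent"] == 100.0
        assert s.loc["same", "percent"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_classes([])


class TestPeaks:
    def test_flat_poisson_track_no_peaks(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(0.1, size=60_000).astype(np.int64)
        track = CoverageTrack("ct", {"chrS1": counts}, int(counts.sum()))
        assert call_peaks_simple(track, qmax=0.01) == []

    def test_planted_bump_recovered_as_one_peak(self):
        rng = np.random.default_rng(13)
        rate = np.full(60_000, 0.1)
        rate[30_000:30_500] = 1.0  # 10x bump over 500 bp
        counts = rng.poisson(rate).astype(np.int64)
        track = CoverageTrack("ct", {"chrS1": counts}, int(counts.sum()))
        peaks = call_peaks_simple(track, qmax=0.01)
        assert len(peaks) == 1
        chrom, s, e = peaks[0]
        overlap = min(e, 30_500) - max(s, 30_000)
        assert overlap >= 0.8 * 500

    def test_qmax_zero_no_peaks(self):
        assert call_peaks_simple(_uniform_track(), qmax=0.0) == []


class TestPeakOverlap:
    def test_no_peaks_zero(self):
        ws = [build_windows(_event())]
        assert peak_overlap_fraction(ws, []) == 0.0

    def test_contig_wide_peak_one(self):
        ws = [build_windows(_event())]
        assert peak_overlap_fraction(ws, [("chrS1", 0, 10_000)]) == 1.0

    def test_half_covered_fixture_exactly_half(self):
        events = [
            _event(),
            ASEvent("ev2", "SE", "chrS1", "+", 3000, 3100, (2800, 2900), (3200, 3300), "g2"),
        ]
        ws = [build_windows(e) for e in events]
        peaks = [("chrS1", 970, 1030)]  # hits only ev1's alt5 window
        assert peak_overlap_fraction(ws, peaks) == 0.5


class TestMetaProfile:
    def test_triangular_bump_peaks_at_anchor(self):
        counts = np.zeros(3000, dtype=np.int64)
        anchor = 1500
        for off in range(-30, 31):
            counts[anchor + off] = 30 - abs(off)
        track = CoverageTrack("ct", {"chrS1": counts}, int(counts.sum()))
        ev = ASEvent("e", "SE", "chrS1", "+", anchor, anchor + 100, (1300, 1400), (1700, 1800), "g")
        profile = meta_profile(track, [ev])
        assert profile.positions[np.argmax(profile.mean_z)] == 0

    def test_minus_strand_reflected(self):
        counts = np.zeros(3000, dtype=np.int64)
        anchor = 1500  # minus-strand anchor = alt_end; +100 downstream = genomic 1400
        counts[1395:1405] = 50
        track = CoverageTrack("ct", {"chrS1": counts}, int(counts.sum()))
        ev = ASEvent("e", "SE", "chrS1", "-", 1400, anchor, (1700, 1800), (1200, 1300), "g")
        profile = meta_profile(track, [ev])
        peak_pos = profile.positions[np.argmax(profile.mean_z)]
        assert 90 <= peak_pos <= 110

    def test_constant_density_excluded(self):
        track = _uniform_track(value=1, length=3000)
        ev = ASEvent("e", "SE", "chrS1", "+", 1500, 1600, (1300, 1400), (1700, 1800), "g")
        with pytest.raises(ValueError, match="non-constant"):
            meta_profile(track, [ev])

    def test_constant_events_counted_when_others_remain(self):
        counts = np.zeros(3000, dtype=np.int64)
        counts[1495:1505] = 9
        track = CoverageTrack("ct", {"chrS1": counts}, int(counts.sum()))
        bumpy = ASEvent("e1", "SE", "chrS1", "+", 1500, 1600, (1300, 1400), (1700, 1800), "g")
        flat = ASEvent("e2", "SE", "chrS1", "+", 700, 800, (500, 600), (900, 1000), "g2")
        profile = meta_profile(track, [bumpy, flat])
        assert profile.n_events == 1
        assert profile.n_excluded_constant == 1
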