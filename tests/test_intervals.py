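import pytest

from _oracles import greedy_center_clusters, transitive_stitch
from tscreg.intervals import (
    BedParseError,
    CoboundSite,
    Peak,
    PeakSet,
    cluster_cobound,
    read_bed,
    stitch,
)


def _bed(tmp_path, text, name="peaks.bed"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadBed:
    def test_bed5_fields_mapped(self, tmp_path):
        ps = read_bed(_bed(tmp_path, "chr1\t100\t600\tp1\t25\n"), factor="TF")
        assert len(ps) == 1
        p = ps.peaks[0]
        assert (p.chrom, p.start, p.end, p.score, p.factor) == ("chr1", 100, 600, 25.0, "TF")

    def test_empty_file_gives_empty_set(self, tmp_path):
        assert len(read_bed(_bed(tmp_path, ""))) == 0

    def test_bed3_scores_default_to_zero(self, tmp_path):
        ps = read_bed(_bed(tmp_path, "chr1\t5\t10\n"))
        assert ps.peaks[0].score == 0.0

    def test_comments_and_track_lines_ignored(self, tmp_path):
        ps = read_bed(_bed(tmp_path, "# c\ntrack name=x\nchr1\t1\t2\n"))
        assert len(ps) == 1

    @pytest.mark.parametrize(
        "line", ["chr1\t600\t100\n", "chr1\tabc\t100\n", "chr1\t100\n"]
    )
    def test_malformed_line_reports_line_number(self, tmp_path, line):
        with pytest.raises(BedParseError, match=":1:"):
            read_bed(_bed(tmp_path, line))


def _peaks(centers, factor, width=100, chrom="chr1"):
    return PeakSet(
        factor,
        [Peak(chrom, c - width // 2, c + width // 2, factor=factor) for c in centers],
    )


class TestClusterCobound:
    def test_three_centers_within_window_form_one_site(self):
        sets = [_peaks([1000], "A"), _peaks([1200], "B"), _peaks([1450], "C")]
        sites = cluster_cobound(sets, window=500)
        assert len(sites) == 1
        assert sites[0].n_factors == 3
        assert sites[0].span_end - sites[0].span_start == 450

    def test_centers_beyond_window_split(self):
        sites = cluster_cobound([_peaks([1000], "A"), _peaks([1600], "B")], window=500)
        assert [s.n_factors for s in sites] == [1, 1]

    def test_duplicate_factor_counted_once_nearest_mean_kept(self):
        sites = cluster_cobound([_peaks([1000, 1400], "A"), _peaks([1100], "B")], window=500)
        assert len(sites) == 1
        assert sites[0].n_factors == 2
        # cluster mean ~1166: the 1100-adjacent duplicate of A wins
        assert sites[0].members["A"].center == 1000

    def test_empty_input(self):
        assert cluster_cobound([], window=500) == []

    def test_matches_exhaustive_oracle_on_random_peaks(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 200))
            centers = sorted(int(c) for c in rng.integers(0, 50_000, size=n))
            factors = rng.integers(0, 5, size=n)
            sets = {}
            for c, f in zip(centers, factors):
                sets.setdefault(f"TF{f}", []).append(c)
            peaksets = [_peaks(cs, f) for f, cs in sets.items()]
            sites = cluster_cobound(peaksets, window=500)
            oracle = greedy_center_clusters(centers, window=500)
            assert len(sites) == len(oracle)
            for site, idxs in zip(sites, sorted(oracle, key=lambda ix: centers[ix[0]])):
                span = [centers[i] for i in idxs]
                assert site.span_start == min(span)
                assert site.span_end == max(span)
                assert site.n_factors == len({f"TF{factors[i]}" for i in idxs})

    def test_partition_conserves_total_span_membership(self, rng):
        centers = sorted(int(c) for c in rng.integers(0, 100_000, size=300))
        sites = cluster_cobound([_peaks(centers, "A")], window=500)
        # every center falls in exactly one site span
        covered = sum(
            sum(1 for c in centers if s.span_start <= c <= s.span_end) for s in sites
        )
        assert covered >= len(centers)
        for s in sites:
            assert s.span_end - s.span_start <= 500

    def test_invariant_under_input_order(self, rng):
        centers = [int(c) for c in rng.integers(0, 20_000, size=100)]
        a = cluster_cobound([_peaks(sorted(centers), "A")], window=500)
        b = cluster_cobound([_peaks(centers[::-1], "A")], window=500)
        assert [(s.span_start, s.span_end) for s in a] == [
            (s.span_start, s.span_end) for s in b
        ]


class TestStitch:
    def test_gap_within_limit_merges(self):
        ps = _peaks([150, 5050], "E")
        regions = stitch(ps, gap=12_500)
        assert len(regions) == 1
        assert len(regions[0].constituents) == 2

    def test_exclusion_zone_blocks_merge(self):
        ps = PeakSet("E", [Peak("chr1", 100, 200), Peak("chr1", 5000, 5100)])
        regions = stitch(ps, gap=12_500, exclusion=[("chr1", 2000, 3000)])
        assert len(regions) == 2

    def test_peak_inside_zone_removed(self):
        ps = PeakSet("E", [Peak("chr1", 2100, 2300), Peak("chr1", 5000, 5100)])
        regions = stitch(ps, gap=12_500, exclusion=[("chr1", 2000, 3000)])
        assert len(regions) == 1
        assert regions[0].start == 5000

    def test_matches_transitive_oracle_on_random_peaks(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 100))
            starts = rng.integers(0, 200_000, size=n)
            widths = rng.integers(50, 500, size=n)
            peaks = [Peak("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)]
            gap = int(rng.integers(0, 5000))
            regions = stitch(PeakSet("E", peaks), gap=gap)
            oracle = transitive_stitch([(p.start, p.end) for p in peaks], gap)
            assert [(r.start, r.end) for r in regions] == oracle

    def test_constituents_conserved_and_disjoint(self, rng):
        starts = rng.integers(0, 100_000, size=200)
        peaks = [Peak("chr1", int(s), int(s) + 100) for s in starts]
        regions = stitch(PeakSet("E", peaks), gap=1000)
        assert sum(len(r.constituents) for r in regions) == len(peaks)
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start or a.chrom != b.chrom

    def test_zero_gap_merges_only_abutting(self):
        ps = PeakSet("E", [Peak("chr1", 0, 100), Peak("chr1", 100, 200), Peak("chr1", 201, 300)])
        regions = stitch(ps, gap=0)
        assert [(r.start, r.end) for r in regions] == [(0, 200), (201, 300)]

    def test_huge_gap_one_region_per_chromosome(self):
        peaks = [Peak("chr1", 0, 10), Peak("chr1", 9_000_000, 9_000_010), Peak("chr2", 5, 20)]
        regions = stitch(PeakSet("E", peaks), gap=10_000_000)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"chr1", "chr2"}


class TestInvariants:
    def test_peak_validation(self):
        with pytest.raises(ValueError):
            Peak("chr1", 10, 10)
        with pytest.raises(ValueError):
            Peak("", 0, 10)

    def test_center_within_interval(self, rng):
        for _ in range(100):
            s = int(rng.integers(0, 1000))
            e = s + int(rng.integers(1, 1000))
            p = Peak("chr1", s, e)
            assert s <= p.center < e
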