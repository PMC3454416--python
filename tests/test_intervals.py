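import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bivenrich import (
    GenomeAssembly,
    Interval,
    IntervalTrack,
    PointSet,
    TrackError,
    enrichment_ratio,
    extend_and_clamp,
    merge_track,
    points_in_track,
    randomize_track,
    read_bed,
    track_coverage_bp,
    write_bed,
)
from bivenrich.intervals import BedParseError

from conftest import brute_force_points_in_track, random_instance


@pytest.mark.parametrize(
    "raw, expected",
    [
        # overlapping pair coalesces
        ([("c1", 100, 200), ("c1", 150, 300)], [("c1", 100, 300)]),
        # adjacent half-open intervals coalesce
        ([("c1", 100, 200), ("c1", 200, 300)], [("c1", 100, 300)]),
        # different chromosomes stay apart
        ([("c1", 100, 200), ("c2", 100, 200)], [("c1", 100, 200), ("c2", 100, 200)]),
        # nested interval absorbed
        ([("c1", 100, 400), ("c1", 150, 200)], [("c1", 100, 400)]),
    ],
)
def test_merge_examples(raw, expected):
    merged = merge_track(IntervalTrack([Interval(*t) for t in raw]))
    assert merged.merged
    assert [tuple(iv) for iv in merged.intervals] == expected


@st.composite
def tracks(draw):
    n = draw(st.integers(1, 20))
    ivs = []
    for _ in range(n):
        chrom = draw(st.sampled_from(["c1", "c2"]))
        start = draw(st.integers(0, 500))
        end = draw(st.integers(start + 1, 501))
        ivs.append(Interval(chrom, start, end))
    return IntervalTrack(ivs)


@settings(derandomize=True, max_examples=100)
@given(tracks())
def test_merge_is_idempotent_and_preserves_union(track):
    merged = merge_track(track)
    again = merge_track(merged)
    assert again.intervals == merged.intervals
    # union of base pairs unchanged; covered bp never increases
    covered = {
        (iv.chrom, p) for iv in track.intervals for p in range(iv.start, iv.end)
    }
    assert track_coverage_bp(merged) == len(covered)
    assert track_coverage_bp(merged) <= sum(iv.length for iv in track.intervals)
    # merged contract: sorted, disjoint, non-adjacent per chromosome
    for chrom, (starts, ends) in merged.by_chrom().items():
        assert np.all(ends[:-1] < starts[1:])


def test_extend_and_clamp(toy_genome):
    g10k = GenomeAssembly("g", {"c1": 10_000})
    t = IntervalTrack([Interval("c1", 1000, 2000)])
    assert extend_and_clamp(t, g10k, 2000).intervals == [Interval("c1", 0, 4000)]
    t = IntervalTrack([Interval("c1", 9000, 9500)])
    assert extend_and_clamp(t, g10k, 2000).intervals == [Interval("c1", 7000, 10_000)]
    t = IntervalTrack([Interval("c1", 100, 200)])
    assert extend_and_clamp(t, g10k, 0).intervals == t.intervals
    with pytest.raises(ValueError):
        extend_and_clamp(t, g10k, -1)


def test_points_in_track_boundaries(toy_track):
    assert points_in_track(PointSet([("c1", 150), ("c1", 500)]), toy_track) == 1
    # half-open right boundary excluded, closed left boundary included
    assert points_in_track(PointSet([("c1", 200)]), toy_track) == 0
    assert points_in_track(PointSet([("c1", 100)]), toy_track) == 1
    # unknown chromosome in track index simply contributes nothing
    assert points_in_track(PointSet([("c9", 150)]), toy_track) == 0


def test_points_in_track_requires_merged():
    unmerged = IntervalTrack([Interval("c1", 0, 10)])
    with pytest.raises(TrackError):
        points_in_track(PointSet([("c1", 5)]), unmerged)


def test_points_in_track_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(200):
        points, track = random_instance(rng)
        assert points_in_track(points, track) == brute_force_points_in_track(
            points, track
        )


def test_track_coverage(toy_track):
    assert track_coverage_bp(toy_track) == 100
    empty = IntervalTrack([], merged=True)
    assert track_coverage_bp(empty) == 0
    two = merge_track(IntervalTrack([Interval("c1", 0, 10), Interval("c2", 0, 10)]))
    assert track_coverage_bp(two) == 20


class TestEnrichmentRatio:
    def test_hand_evaluated_values(self, toy_genome, toy_track):
        pts = PointSet([("c1", 150), ("c1", 500), ("c1", 700)])
        # (1/3) / (99/997)
        assert enrichment_ratio(pts, toy_track, toy_genome) == pytest.approx(997 / 297)
        pts = PointSet([("c1", 110), ("c1", 120), ("c1", 130)])
        # (3/3) / (97/997)
        assert enrichment_ratio(pts, toy_track, toy_genome) == pytest.approx(997 / 97)

    def test_no_overlap_gives_zero(self, toy_genome, toy_track):
        pts = PointSet([("c1", 500), ("c1", 700)])
        assert enrichment_ratio(pts, toy_track, toy_genome) == 0.0

    def test_track_all_probes_gives_inf(self):
        genome = GenomeAssembly("g", {"c1": 1000})
        track = merge_track(IntervalTrack([Interval("c1", 10, 12)]))
        pts = PointSet([("c1", 10), ("c1", 11)])
        assert enrichment_ratio(pts, track, genome) == float("inf")

    def test_unit_expectation_under_uniform_points(self):
        # uniform points independent of the track: mean ratio ~ 1 (CLT bound)
        rng = np.random.default_rng(7)
        genome = GenomeAssembly("g", {"c1": 100_000})
        track = merge_track(
            IntervalTrack([Interval("c1", s, s + 1000) for s in range(0, 100_000, 5000)])
        )
        n, reps = 400, 200
        ratios = []
        for _ in range(reps):
            pos = rng.choice(100_000, size=n, replace=False)
            ratios.append(
                enrichment_ratio(PointSet([("c1", int(p)) for p in pos]), track, genome)
            )
        mean, sem = np.mean(ratios), np.std(ratios, ddof=1) / np.sqrt(reps)
        assert abs(mean - 1.0) < 4 * sem + 0.01


class TestRandomizeTrack:
    def test_preserves_length_and_gap_multisets(self):
        genome = GenomeAssembly("g", {"c1": 10_000, "c2": 5_000})
        track = merge_track(
            IntervalTrack(
                [
                    Interval("c1", 100, 110),
                    Interval("c1", 115, 135),
                    Interval("c1", 200, 230),
                    Interval("c2", 0, 50),
                ]
            )
        )
        rng = np.random.default_rng(0)
        for _ in range(100):
            null = randomize_track(track, genome, rng)
            assert null.merged
            for chrom in ("c1", "c2"):
                s0, e0 = track.by_chrom()[chrom]
                s1, e1 = null.by_chrom()[chrom]
                assert sorted(e1 - s1) == sorted(e0 - s0)
                assert sorted(s1[1:] - e1[:-1]) == sorted(s0[1:] - e0[:-1])
                assert s1[0] >= 0 and e1[-1] <= genome.length_of(chrom)

    def test_seed_determinism(self, toy_genome, toy_track):
        a = randomize_track(toy_track, toy_genome, 123)
        b = randomize_track(toy_track, toy_genome, 123)
        assert a.intervals == b.intervals

    def test_single_segment_start_uniform(self):
        # 100 bp segment on 1,000 bp chromosome: start uniform on [0, 900]
        genome = GenomeAssembly("g", {"c1": 1000})
        track = merge_track(IntervalTrack([Interval("c1", 0, 100)]))
        rng = np.random.default_rng(11)
        starts = [randomize_track(track, genome, rng).intervals[0].start for _ in range(1000)]
        obs, edges = np.histogram(starts, bins=10, range=(0, 901))
        widths = np.diff(edges)
        expected = 1000 * widths / 901
        p = stats.chisquare(obs, expected).pvalue
        assert p > 0.001

    def test_infeasible_layout(self):
        genome = GenomeAssembly("g", {"c1": 100})
        track = merge_track(
            IntervalTrack([Interval("c1", 0, 40), Interval("c1", 60, 100)])
        )
        tiny = GenomeAssembly("g", {"c1": 99})
        with pytest.raises(TrackError):
            randomize_track(track, tiny, 0)


class TestBedIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t100\t200\tGENE1\nchr2\t0\t50\tGENE2\n")
        track = read_bed(path)
        assert track.intervals == [Interval("chr1", 100, 200), Interval("chr2", 0, 50)]
        assert track.names == ["GENE1", "GENE2"]
        out = tmp_path / "y.bed"
        write_bed(track, out)
        assert out.read_text() == path.read_text()

    @pytest.mark.parametrize(
        "content", ["chr1\t200\t100\n", "chr1\t100\n", "chr1\tx\t200\n", "chr1\t-5\t10\n"]
    )
    def test_malformed_lines_rejected_with_line_number(self, tmp_path, content):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t1\t2\n" + content)
        with pytest.raises(BedParseError, match=":2"):
            read_bed(path)
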