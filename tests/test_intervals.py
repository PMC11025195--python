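"""Interval algebra: narrowPeak reading, merging, exclusion, recurrence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from re1scan.intervals import (
    ExperimentPeakSet,
    GenomicInterval,
    MergedPeak,
    filter_by_recurrence,
    merge_across_experiments,
    read_merged_peaks,
    read_narrowpeak,
    recurrence_histogram,
    subtract_any_overlap,
    write_merged_peaks,
)


def brute_force_merge(sets):
    """Per-base union oracle: covered runs + any-overlap support."""
    raw = [(p.chrom, p.start, p.end, s.experiment_id) for s in sets for p in s.peaks]
    chroms = sorted({r[0] for r in raw})
    out = []
    for chrom in chroms:
        ivs = [r for r in raw if r[0] == chrom]
        hi = max(r[2] for r in ivs)
        covered = np.zeros(hi + 1, dtype=bool)
        for _, a, b, _ in ivs:
            covered[a:b] = True
        pos = 0
        while pos <= hi:
            if not covered[pos]:
                pos += 1
                continue
            start = pos
            while pos <= hi and covered[pos]:
                pos += 1
            end = pos
            support = {e for _, a, b, e in ivs if a < end and start < b}
            out.append(MergedPeak(GenomicInterval(chrom, start, end), frozenset(support)))
    return out


def random_sets(rng, n_exp=5, n_iv=20, span=10_000):
    sets = []
    for i in range(n_exp):
        peaks = []
        for _ in range(n_iv):
            a = int(rng.integers(0, span - 1))
            b = a + int(rng.integers(1, 200))
            peaks.append(GenomicInterval("chrT", a, b))
        peaks.sort(key=lambda p: (p.start, p.end))
        sets.append(ExperimentPeakSet(f"e{i}", f"cl{i % 2}", peaks))
    return sets


class TestReadNarrowpeak:
    def test_ten_column_line(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\tpeak1\t0\t.\t5\t-1\t-1\t50\n")
        ps = read_narrowpeak(f, "expA", "K562")
        assert ps.peaks == [GenomicInterval("chr1", 100, 200)]
        assert (ps.experiment_id, ps.cell_line) == ("expA", "K562")

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.narrowPeak"
        f.write_text("")
        assert read_narrowpeak(f, "e", "c").peaks == []

    def test_overlapping_lines_not_merged_on_read(self, tmp_path):
        f = tmp_path / "ovl.bed"
        f.write_text("chr2\t10\t100\nchr2\t50\t150\nchr2\t90\t200\n")
        assert len(read_narrowpeak(f, "e", "c").peaks) == 3

    @pytest.mark.parametrize("line", ["chr1\t100", "chr1\tx\t200", "chr1\t200\t100"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        f = tmp_path / "bad.bed"
        f.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_narrowpeak(f, "e", "c")


class TestMerge:
    def test_overlap_union(self):
        sets = [
            ExperimentPeakSet("A", "c", [GenomicInterval("chr1", 100, 200)]),
            ExperimentPeakSet("B", "c", [GenomicInterval("chr1", 150, 250)]),
        ]
        (m,) = merge_across_experiments(sets)
        assert m.interval == GenomicInterval("chr1", 100, 250)
        assert m.support == {"A", "B"} and m.recurrence == 2

    def test_disjoint_stay_separate(self):
        sets = [
            ExperimentPeakSet("A", "c", [GenomicInterval("chr1", 100, 200)]),
            ExperimentPeakSet("B", "c", [GenomicInterval("chr1", 300, 400)]),
        ]
        merged = merge_across_experiments(sets)
        assert [m.recurrence for m in merged] == [1, 1]

    def test_bookended_intervals_merge(self):
        sets = [
            ExperimentPeakSet("A", "c", [GenomicInterval("chr1", 100, 200)]),
            ExperimentPeakSet("B", "c", [GenomicInterval("chr1", 200, 300)]),
        ]
        (m,) = merge_across_experiments(sets)
        assert m.interval == GenomicInterval("chr1", 100, 300)
        assert m.support == {"A", "B"}

    def test_matches_per_base_oracle(self, rng):
        for _ in range(20):
            sets = random_sets(rng)
            got = merge_across_experiments(sets)
            expected = brute_force_merge(sets)
            assert [(m.interval, m.support) for m in got] == [
                (m.interval, m.support) for m in expected
            ]

    def test_merge_idempotent(self, rng):
        sets = random_sets(rng)
        merged = merge_across_experiments(sets)
        pseudo = ExperimentPeakSet("pseudo", "c", [m.interval for m in merged])
        again = merge_across_experiments([pseudo])
        assert [m.interval for m in again] == [m.interval for m in merged]

    def test_duplicate_experiment_id_rejected(self):
        s = ExperimentPeakSet("A", "c", [GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="duplicate"):
            merge_across_experiments([s, s])


class TestSubtract:
    def test_one_bp_overlap_removes_whole_peak(self):
        pk = MergedPeak(GenomicInterval("chr1", 100, 200), frozenset({"A"}))
        assert subtract_any_overlap([pk], [GenomicInterval("chr1", 199, 300)]) == []

    def test_bookended_exclusion_keeps_peak(self):
        pk = MergedPeak(GenomicInterval("chr1", 100, 200), frozenset({"A"}))
        out = subtract_any_overlap([pk], [GenomicInterval("chr1", 200, 300)])
        assert out == [pk]

    def test_matches_brute_force(self, rng):
        peaks = [
            MergedPeak(GenomicInterval("chrT", a := int(rng.integers(0, 9000)),
                                       a + int(rng.integers(1, 300))), frozenset({"A"}))
            for _ in range(100)
        ]
        excl = [
            GenomicInterval("chrT", a := int(rng.integers(0, 9000)),
                            a + int(rng.integers(1, 300)))
            for _ in range(10)
        ]
        got = subtract_any_overlap(peaks, excl)
        expected = [p for p in peaks if not any(p.interval.overlaps(e) for e in excl)]
        assert got == expected

    def test_monotone_in_exclusions(self, rng):
        peaks = [
            MergedPeak(GenomicInterval("chrT", i * 100, i * 100 + 50), frozenset({"A"}))
            for i in range(30)
        ]
        excl = [GenomicInterval("chrT", a := int(rng.integers(0, 3000)), a + 40)
                for _ in range(10)]
        prev = len(peaks)
        for k in range(len(excl) + 1):
            n = len(subtract_any_overlap(peaks, excl[:k]))
            assert n <= prev
            prev = n


class TestRecurrence:
    def test_histogram_counts(self):
        peaks = [
            make(1, "A"), make(2, "A", "B"), make(3, "C"),
        ]
        assert recurrence_histogram(peaks) == {1: 2, 2: 1}

    def test_empty(self):
        assert recurrence_histogram([]) == {}

    def test_histogram_sums_to_input_size(self, rng):
        peaks = [make(i, *(f"e{j}" for j in range(int(rng.integers(1, 6)))))
                 for i in range(40)]
        assert sum(recurrence_histogram(peaks).values()) == 40

    def test_filter_by_recurrence(self):
        peaks = [make(1, "A"), make(2, "A", "B"), make(3, "A", "B", "C")]
        assert [p.recurrence for p in filter_by_recurrence(peaks, 2)] == [2, 3]
        assert filter_by_recurrence(peaks, 1) == peaks

    def test_min_recurrence_validated(self):
        with pytest.raises(ValueError):
            filter_by_recurrence([], 0)


def make(i, *support):
    return MergedPeak(GenomicInterval("chr1", i * 1000, i * 1000 + 100), frozenset(support))


@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=30
    )
)
def test_merged_output_is_nonoverlapping_and_sorted(pairs):
    peaks = [GenomicInterval("chr1", a, a + w) for a, w in pairs]
    merged = merge_across_experiments([ExperimentPeakSet("A", "c", peaks)])
    for prev, nxt in zip(merged, merged[1:]):
        assert prev.interval.end < nxt.interval.start  # non-abutting, non-overlapping


def test_bed_round_trip(tmp_path, rng):
    peaks = [make(i, *(f"e{j}" for j in range(1 + i % 3))) for i in range(10)]
    path = tmp_path / "merged.bed"
    write_merged_peaks(peaks, path)
    assert read_merged_peaks(path) == peaks
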