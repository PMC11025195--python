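"""Composite site calling: pairing, geometry classification, half-only
filters and peak category assignment."""

import itertools

import pytest

from conftest import make_hit, make_peak
from re1scan.composite import (
    ALTERED_GAP,
    CANONICAL,
    CONVERGENT,
    DIVERGENT,
    FLIPPED,
    LEFT_ONLY,
    PEAK_CANONICAL,
    PEAK_NO_MOTIF,
    RIGHT_ONLY,
    Thresholds,
    assign_peak_category,
    call_canonical,
    call_sites_in_peak,
    classify_pair,
    filter_half_only,
    pair_half_hits,
)

L, R = 9, 10  # RE1 half-segment widths


def pair_at(u_kind, u_strand, d_kind, d_strand, gap, start=100):
    """Build a (left_hit, right_hit) pair with the given genomic geometry."""
    wu = L if u_kind == "left" else R
    wd = L if d_kind == "left" else R
    u = make_hit(start, wu, u_strand, u_kind)
    d = make_hit(start + wu + gap, wd, d_strand, d_kind)
    left = u if u_kind == "left" else d
    right = d if u_kind == "left" else u
    return left, right


# the 8 strand/order geometries and their expected categories
GEOMETRIES = [
    ("left", "+", "right", "+", "regular"),
    ("right", "-", "left", "-", "regular"),
    ("right", "+", "left", "+", FLIPPED),
    ("left", "-", "right", "-", FLIPPED),
    ("left", "+", "right", "-", CONVERGENT),
    ("right", "+", "left", "-", CONVERGENT),
    ("left", "-", "right", "+", DIVERGENT),
    ("right", "-", "left", "+", DIVERGENT),
]


class TestClassifyPair:
    @pytest.mark.parametrize("geom", GEOMETRIES, ids=lambda g: f"{g[0]}{g[1]}_{g[2]}{g[3]}")
    @pytest.mark.parametrize("gap", [0, 2, 10, 49])
    def test_geometry_truth_table(self, geom, gap):
        u_kind, u_strand, d_kind, d_strand, expected = geom
        left, right = pair_at(u_kind, u_strand, d_kind, d_strand, gap)
        site = classify_pair(left, right)
        if expected == "regular":
            assert site.category == (CANONICAL if gap == 2 else ALTERED_GAP)
        else:
            assert site.category == expected
        assert site.gap == gap
        assert site.interval.end - site.interval.start == L + gap + R

    def test_altered_gap_example(self):
        left = make_hit(100, L, "+", "left")
        right = make_hit(115, R, "+", "right")
        site = classify_pair(left, right)
        assert site.category == ALTERED_GAP and site.gap == 6

    def test_flipped_example(self):
        right = make_hit(100, R, "+", "right")
        left = make_hit(114, L, "+", "left")
        site = classify_pair(left, right)
        assert site.category == FLIPPED and site.gap == 4

    def test_overlapping_members_rejected(self):
        left = make_hit(100, L, "+", "left")
        right = make_hit(105, R, "+", "right")
        with pytest.raises(ValueError, match="overlap"):
            classify_pair(left, right)

    def test_combined_score_is_member_sum(self):
        left, right = pair_at("left", "+", "right", "+", 2)
        assert classify_pair(left, right).combined_score == pytest.approx(
            left.score + right.score
        )


class TestPairing:
    def test_canonical_geometry_pairs_gap2(self):
        left = make_hit(100, L, "+", "left")
        right = make_hit(111, R, "+", "right")
        pairs, leftovers = pair_half_hits([left], [right])
        assert pairs == [(left, right)] and leftovers == []
        assert classify_pair(*pairs[0]).gap == 2

    def test_gap_52_rejected(self):
        left = make_hit(100, L, "+", "left")
        right = make_hit(161, R, "+", "right")
        pairs, leftovers = pair_half_hits([left], [right])
        assert pairs == [] and set(leftovers) == {left, right}

    @pytest.mark.parametrize("gap,ok", [(0, True), (49, True), (50, False), (-1, False)])
    def test_gap_boundaries(self, gap, ok):
        left = make_hit(100, L, "+", "left")
        right = make_hit(100 + L + gap, R, "+", "right")
        pairs, _ = pair_half_hits([left], [right])
        assert bool(pairs) is ok

    def test_each_hit_in_at_most_one_pair(self, rng):
        peak = make_peak(end=10_000)
        for _ in range(20):
            lefts = [make_hit(int(rng.integers(0, 900)), L, "+", "left",
                              score=float(rng.uniform(10, 20)), peak=peak)
                     for _ in range(5)]
            rights = [make_hit(int(rng.integers(0, 900)), R, "+", "right",
                               score=float(rng.uniform(10, 20)), peak=peak)
                      for _ in range(5)]
            pairs, leftovers = pair_half_hits(lefts, rights)
            used = [h for p in pairs for h in p]
            assert len(used) == len(set(map(id, used)))
            assert len(used) + len(leftovers) == 10
            for lh, rh in pairs:
                u, d = sorted((lh, rh), key=lambda h: h.interval.start)
                assert 0 <= d.interval.start - u.interval.end <= 49

    def test_greedy_matches_exhaustive_on_small_instances(self, rng):
        """Where the greedy and the max-weight matchings agree on total
        score, they select the same pairs (deterministic tie-breaks)."""
        th = Thresholds()
        for _ in range(30):
            lefts = [make_hit(int(rng.integers(0, 300)), L, "+", "left",
                              score=float(rng.uniform(10, 20))) for _ in range(3)]
            rights = [make_hit(int(rng.integers(0, 300)), R, "+", "right",
                               score=float(rng.uniform(10, 20))) for _ in range(3)]
            pairs, _ = pair_half_hits(lefts, rights, th)
            greedy_total = sum(lh.score + rh.score for lh, rh in pairs)

            def feasible(lh, rh):
                u, d = sorted((lh, rh), key=lambda h: h.interval.start)
                return 0 <= d.interval.start - u.interval.end <= 49

            best = 0.0
            for k in range(min(3, 3), -1, -1):
                for lsub in itertools.permutations(range(3), k):
                    for rsub in itertools.combinations(range(3), k):
                        if all(feasible(lefts[i], rights[j])
                               for i, j in zip(lsub, rsub)):
                            tot = sum(lefts[i].score + rights[j].score
                                      for i, j in zip(lsub, rsub))
                            best = max(best, tot)
            assert greedy_total <= best + 1e-9
            # greedy never leaves an addable feasible pair on the table
            unused_l = [h for h in lefts if h not in {p[0] for p in pairs}]
            unused_r = [h for h in rights if h not in {p[1] for p in pairs}]
            assert not any(feasible(a, b) for a in unused_l for b in unused_r)


class TestHalfOnly:
    @pytest.mark.parametrize(
        "kind,score,kept",
        [
            ("left", 15.0, True),
            ("left", 14.99, False),
            ("right", 16.0, True),
            ("right", 15.5, False),
            ("right", 15.99, False),
        ],
    )
    def test_score_floors(self, kind, score, kept):
        w = L if kind == "left" else R
        sites = filter_half_only([make_hit(100, w, "+", kind, score=score)])
        assert (len(sites) == 1) is kept
        if kept:
            assert sites[0].category == (LEFT_ONLY if kind == "left" else RIGHT_ONLY)

    def test_predicate_oracle_on_random_scores(self, rng):
        hits = [
            make_hit(i * 100, L if i % 2 else R, "+", "left" if i % 2 else "right",
                     score=float(rng.uniform(10, 22)))
            for i in range(40)
        ]
        sites = filter_half_only(hits)
        expected = [
            h for h in hits
            if (h.segment_kind == "left" and h.score >= 15)
            or (h.segment_kind == "right" and h.score >= 16)
        ]
        assert [s.member_hits[0] for s in sites] == expected


class TestPeakCategory:
    def test_canonical_precedence(self):
        peak = make_peak()
        full = make_hit(100, 21, "+", "full", score=30, peak=peak)
        half = make_hit(400, L, "+", "left", score=18, peak=peak)
        sites = call_canonical([full]) + filter_half_only([half])
        assert assign_peak_category(peak, sites) == PEAK_CANONICAL

    def test_no_sites_means_no_motif(self):
        assert assign_peak_category(make_peak(), []) == PEAK_NO_MOTIF

    def test_highest_scoring_noncanonical_sets_subtype(self):
        peak = make_peak()
        weak = filter_half_only([make_hit(100, L, "+", "left", score=15.5, peak=peak)])
        strong = filter_half_only([make_hit(500, R, "+", "right", score=17.5, peak=peak)])
        label = assign_peak_category(peak, weak + strong)
        assert label == "Peak_ncRE1:right_only"


class TestCallSitesInPeak:
    def test_whole_motif_call_suppresses_gap2_pair(self):
        peak = make_peak()
        full = make_hit(100, 21, "+", "full", score=30, peak=peak)
        left = make_hit(100, L, "+", "left", score=14, peak=peak)
        right = make_hit(111, R, "+", "right", score=15, peak=peak)
        sites = call_sites_in_peak(peak, [full], [left], [right])
        canon = [s for s in sites if s.category == CANONICAL]
        assert len(canon) == 1 and canon[0].member_hits == (full,)

    def test_no_hit_used_twice(self):
        peak = make_peak()
        left = make_hit(100, L, "+", "left", score=16, peak=peak)
        r1 = make_hit(111, R, "+", "right", score=17, peak=peak)
        r2 = make_hit(140, R, "+", "right", score=17, peak=peak)
        sites = call_sites_in_peak(peak, [], [left], [r1, r2])
        members = [h for s in sites for h in s.member_hits]
        assert len(members) == len(set(map(id, members)))

    def test_span_lengths(self):
        peak = make_peak()
        left = make_hit(100, L, "+", "left", score=16, peak=peak)
        right = make_hit(120, R, "+", "right", score=17, peak=peak)
        (site,) = [s for s in call_sites_in_peak(peak, [], [left], [right])]
        assert len(site.interval) == L + site.gap + R


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(score_fraction=0)
    with pytest.raises(ValueError):
        Thresholds(canonical_gap=60)
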