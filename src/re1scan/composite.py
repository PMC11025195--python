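"""Composite RE1 site calling: pair half-segment hits within a peak, classify
their geometry, and assign each peak a single occupancy category.

Categories
----------
A full-length RE1 site is built either from one whole-motif hit (canonical)
or from a left-segment hit paired with a right-segment hit whose gap lies in
[0, 49] bp.  Paired sites are classified from the strands and the genomic
order of the two members:

* same strand, segments in reading order (left then right on '+', right then
  left on '-') -> regular: canonical when the gap is exactly 2 bp, otherwise
  altered_gap;
* same strand, segments in the opposite order -> flipped;
* opposite strands, upstream member on '+' -> convergent (segments point
  toward each other);
* opposite strands, upstream member on '-' -> divergent.

Unpaired half hits become left_only / right_only provided their score clears
the absolute half-motif thresholds (15 bits for left, 16 for right; lower
scoring half hits are discarded as likely false positives of the short
segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import GenomicInterval, MergedPeak
from .scanner import MotifHit

CANONICAL = "canonical"
ALTERED_GAP = "altered_gap"
CONVERGENT = "convergent"
DIVERGENT = "divergent"
FLIPPED = "flipped"
LEFT_ONLY = "left_only"
RIGHT_ONLY = "right_only"

CATEGORIES = (CANONICAL, ALTERED_GAP, CONVERGENT, DIVERGENT, FLIPPED, LEFT_ONLY, RIGHT_ONLY)
FULL_LENGTH_CATEGORIES = (CANONICAL, ALTERED_GAP, CONVERGENT, DIVERGENT, FLIPPED)

# tie-break order for the peak label when several non-canonical sites tie on score
_SUBTYPE_PRECEDENCE = (ALTERED_GAP, CONVERGENT, DIVERGENT, FLIPPED, LEFT_ONLY, RIGHT_ONLY)

PEAK_CANONICAL = "Peak_cRE1"
PEAK_NONCANONICAL_PREFIX = "Peak_ncRE1"
PEAK_NO_MOTIF = "Peak_NoRE1"
NO_PEAK = "NoPeak"

__all__ = [
    "Thresholds",
    "CompositeSite",
    "call_canonical",
    "pair_half_hits",
    "classify_pair",
    "filter_half_only",
    "assign_peak_category",
    "call_sites_in_peak",
    "write_sites",
    "CATEGORIES",
    "FULL_LENGTH_CATEGORIES",
]


@dataclass
class Thresholds:
    """All numeric filter constants of the analysis, with field defaults."""

    score_fraction: float = 0.84       # fraction-of-maximum score filter
    max_pair_gap: int = 49             # bp, inclusive
    min_pair_gap: int = 0              # bp
    canonical_gap: int = 2             # bp between the two segments
    l_only_min_score: float = 15.0     # bits
    r_only_min_score: float = 16.0     # bits
    min_recurrence: int = 2            # singleton peaks excluded
    upstream_window: int = 1000        # bp 5' of a TSS

    def __post_init__(self) -> None:
        if not (0 < self.score_fraction <= 1):
            raise ValueError("score_fraction must be in (0, 1]")
        if not (self.min_pair_gap <= self.canonical_gap <= self.max_pair_gap):
            raise ValueError("need min_pair_gap <= canonical_gap <= max_pair_gap")


@dataclass
class CompositeSite:
    """A classified RE1 occurrence within one merged peak."""

    category: str
    interval: GenomicInterval        # span of all member hits
    member_hits: tuple[MotifHit, ...]
    source_peak: MergedPeak
    gap: int | None = None           # None for half-only sites

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        n = len(self.member_hits)
        if self.category in (LEFT_ONLY, RIGHT_ONLY):
            if n != 1:
                raise ValueError("half-only sites have exactly one member hit")
        elif self.category == CANONICAL:
            if n not in (1, 2):  # whole-motif hit, or a gap-2 regular pair
                raise ValueError("canonical sites have one or two member hits")
        elif n != 2:
            raise ValueError(f"{self.category} sites have exactly two member hits")

    @property
    def combined_score(self) -> float:
        return sum(h.score for h in self.member_hits)

    @property
    def strand(self) -> str:
        """Strand of the genomically upstream member."""
        return min(self.member_hits, key=lambda h: h.interval.start).strand


def call_canonical(full_hits: Iterable[MotifHit]) -> list[CompositeSite]:
    """Each surviving whole-motif hit becomes a canonical site (gap 2)."""
    return [
        CompositeSite(
            category=CANONICAL,
            interval=h.interval,
            member_hits=(h,),
            source_peak=h.source_peak,
            gap=2,
        )
        for h in full_hits
    ]


def _gap(a: MotifHit, b: MotifHit) -> int:
    """Gap in bp between two hits, ordered genomically (negative = overlap)."""
    u, d = sorted((a, b), key=lambda h: h.interval.start)
    return d.interval.start - u.interval.end


def pair_half_hits(
    left_hits: Sequence[MotifHit],
    right_hits: Sequence[MotifHit],
    th: Thresholds | None = None,
) -> tuple[list[tuple[MotifHit, MotifHit]], list[MotifHit]]:
    """Greedily pair left- with right-segment hits whose gap lies in range.

    Candidate pairs are ranked by descending combined score, then smaller
    gap, then leftmost coordinate; each hit joins at most one pair.  Unpaired
    hits are returned as leftovers.
    """
    th = th or Thresholds()
    candidates: list[tuple[float, int, int, int, int, MotifHit, MotifHit]] = []
    for i, lh in enumerate(left_hits):
        for j, rh in enumerate(right_hits):
            if lh.interval.chrom != rh.interval.chrom:
                continue
            g = _gap(lh, rh)
            if th.min_pair_gap <= g <= th.max_pair_gap:
                start = min(lh.interval.start, rh.interval.start)
                candidates.append((-(lh.score + rh.score), g, start, i, j, lh, rh))
    candidates.sort(key=lambda c: c[:5])

    used_left: set[int] = set()
    used_right: set[int] = set()
    pairs: list[tuple[MotifHit, MotifHit]] = []
    for _, _, _, i, j, lh, rh in candidates:
        if i in used_left or j in used_right:
            continue
        used_left.add(i)
        used_right.add(j)
        pairs.append((lh, rh))
    leftovers = [h for i, h in enumerate(left_hits) if i not in used_left]
    leftovers += [h for j, h in enumerate(right_hits) if j not in used_right]
    return pairs, leftovers


def classify_pair(left: MotifHit, right: MotifHit, th: Thresholds | None = None) -> CompositeSite:
    """Classify a (left-segment, right-segment) pair by orientation and order."""
    th = th or Thresholds()
    u, d = sorted((left, right), key=lambda h: h.interval.start)
    gap = d.interval.start - u.interval.end
    if gap < 0:
        raise ValueError("member hits overlap; pairing must prevent this")

    if u.strand == d.strand:
        reading_order = (
            (u.strand == "+" and u.segment_kind == "left" and d.segment_kind == "right")
            or (u.strand == "-" and u.segment_kind == "right" and d.segment_kind == "left")
        )
        if reading_order:
            category = CANONICAL if gap == th.canonical_gap else ALTERED_GAP
        else:
            category = FLIPPED
    else:
        category = CONVERGENT if u.strand == "+" else DIVERGENT

    interval = GenomicInterval(u.interval.chrom, u.interval.start, d.interval.end)
    return CompositeSite(
        category=category,
        interval=interval,
        member_hits=(left, right),
        source_peak=left.source_peak,
        gap=gap,
    )


def filter_half_only(
    leftovers: Iterable[MotifHit], th: Thresholds | None = None
) -> list[CompositeSite]:
    """Turn unpaired half hits into half-only sites, applying score floors.

    Left hits below 15 bits and right hits below 16 bits are dropped;
    boundary scores are kept (the filter removes scores strictly below the
    threshold).
    """
    th = th or Thresholds()
    sites: list[CompositeSite] = []
    for h in leftovers:
        if h.segment_kind == "left":
            if h.score < th.l_only_min_score - 1e-9:
                continue
            category = LEFT_ONLY
        elif h.segment_kind == "right":
            if h.score < th.r_only_min_score - 1e-9:
                continue
            category = RIGHT_ONLY
        else:
            raise ValueError(f"unexpected segment kind {h.segment_kind!r}")
        sites.append(
            CompositeSite(
                category=category,
                interval=h.interval,
                member_hits=(h,),
                source_peak=h.source_peak,
            )
        )
    return sites


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / len(a), inter / len(b))


def call_sites_in_peak(
    peak: MergedPeak,
    full_hits: Sequence[MotifHit],
    left_hits: Sequence[MotifHit],
    right_hits: Sequence[MotifHit],
    th: Thresholds | None = None,
) -> list[CompositeSite]:
    """All composite sites of one peak from its thresholded hits.

    Canonical sites are found both by the whole-motif scan and as gap-2
    regular pairs; when both fire on the same locus (>= 50% reciprocal
    overlap) the whole-motif call wins and the pair is suppressed.
    """
    th = th or Thresholds()
    canonical = call_canonical(full_hits)
    pairs, leftovers = pair_half_hits(left_hits, right_hits, th)
    paired_sites = [classify_pair(lh, rh, th) for lh, rh in pairs]
    deduped: list[CompositeSite] = []
    for s in paired_sites:
        if s.category == CANONICAL and any(
            _reciprocal_overlap(s.interval, c.interval) >= 0.5 for c in canonical
        ):
            continue
        deduped.append(s)
    return canonical + deduped + filter_half_only(leftovers, th)


def assign_peak_category(peak: MergedPeak, sites: Sequence[CompositeSite]) -> str:
    """One occupancy label per peak.

    Canonical sites take precedence; otherwise the highest-scoring
    non-canonical site sets the subtype (ties broken by a fixed subtype
    order, then leftmost site); a peak without sites is Peak_NoRE1.
    """
    if any(s.category == CANONICAL for s in sites):
        return PEAK_CANONICAL
    noncanon = [s for s in sites if s.category != CANONICAL]
    if not noncanon:
        return PEAK_NO_MOTIF
    best = min(
        noncanon,
        key=lambda s: (
            -s.combined_score,
            _SUBTYPE_PRECEDENCE.index(s.category),
            s.interval.start,
        ),
    )
    return f"{PEAK_NONCANONICAL_PREFIX}:{best.category}"


def write_sites(sites: Iterable[CompositeSite], path) -> None:
    """Write composite sites as extended BED.

    Columns: chrom, start, end, category, combined_score, upstream-member
    strand, gap, member coordinates (semicolon-joined start-end/strand).
    """
    with open(path, "w") as fh:
        for s in sites:
            members = ";".join(
                f"{h.interval.start}-{h.interval.end}/{h.strand}"
                for h in sorted(s.member_hits, key=lambda h: h.interval.start)
            )
            gap = "." if s.gap is None else str(s.gap)
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.category}\t{s.combined_score:.6f}\t{s.strand}\t{gap}\t{members}\n"
            )
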