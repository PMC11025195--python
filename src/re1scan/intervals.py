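"""Peak interval algebra: narrowPeak I/O, cross-experiment merging, exclusion
subtraction and recurrence accounting.

All coordinates are 0-based half-open (BED native).  Merging follows
``bedtools multiinter`` + ``merge`` semantics: intervals that overlap or abut
(gap 0) collapse into one region, and an experiment supports a merged region
iff at least one of its raw peaks overlaps it by >= 1 bp.  Exclusion follows
``bedtools subtract -A``: any >= 1 bp overlap with an exclusion interval
removes the whole peak; book-ended peak/exclusion pairs do *not* overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "ExperimentPeakSet",
    "MergedPeak",
    "read_narrowpeak",
    "merge_across_experiments",
    "subtract_any_overlap",
    "recurrence_histogram",
    "filter_by_recurrence",
    "write_merged_peaks",
    "read_merged_peaks",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp overlap; book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ExperimentPeakSet:
    """Peak calls of one ChIP-seq experiment (one narrowPeak file)."""

    experiment_id: str
    cell_line: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def sorted_peaks(self) -> list[GenomicInterval]:
        return sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))


@dataclass(frozen=True)
class MergedPeak:
    """A merged peak region with the set of experiments supporting it."""

    interval: GenomicInterval
    support: frozenset[str]

    @property
    def recurrence(self) -> int:
        """Number of experiments whose peaks overlap this region."""
        return len(self.support)


def read_narrowpeak(path: str | Path, experiment_id: str, cell_line: str) -> ExperimentPeakSet:
    """Read a narrowPeak/BED3+ file into an :class:`ExperimentPeakSet`.

    Only the first three columns are used; extra columns (name, score,
    strand, signalValue, pValue, qValue, summit) are ignored.  Raises
    ``ValueError`` naming the offending line on malformed input.
    """
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start},{end})"
                )
            peaks.append(GenomicInterval(chrom, start, end))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return ExperimentPeakSet(experiment_id=experiment_id, cell_line=cell_line, peaks=peaks)


def merge_across_experiments(sets: Iterable[ExperimentPeakSet]) -> list[MergedPeak]:
    """Merge peaks of several experiments into maximal non-overlapping regions.

    Overlapping or book-ended intervals are unioned (bedtools merge default,
    distance 0).  Each merged region records every experiment contributing at
    least one base to it.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one experiment peak set")
    seen_ids = set()
    for s in sets:
        if s.experiment_id in seen_ids:
            raise ValueError(f"duplicate experiment_id {s.experiment_id!r}")
        seen_ids.add(s.experiment_id)

    tagged: list[tuple[str, int, int, str]] = []
    for s in sets:
        for p in s.peaks:
            tagged.append((p.chrom, p.start, p.end, s.experiment_id))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    merged: list[MergedPeak] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_support: set[str] = set()
    for chrom, start, end, exp in tagged:
        if chrom == cur_chrom and start <= cur_end:  # overlap or abut
            cur_end = max(cur_end, end)
            cur_support.add(exp)
        else:
            if cur_chrom is not None:
                merged.append(
                    MergedPeak(GenomicInterval(cur_chrom, cur_start, cur_end), frozenset(cur_support))
                )
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_support = {exp}
    if cur_chrom is not None:
        merged.append(
            MergedPeak(GenomicInterval(cur_chrom, cur_start, cur_end), frozenset(cur_support))
        )
    return merged


def _exclusion_trees(exclusions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ex in exclusions:
        trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end)
    return trees


def subtract_any_overlap(
    peaks: Iterable[MergedPeak], exclusions: Iterable[GenomicInterval]
) -> list[MergedPeak]:
    """Remove every peak that overlaps any exclusion region by >= 1 bp.

    Survivors pass through unmodified (``bedtools subtract -A`` semantics).
    """
    trees = _exclusion_trees(exclusions)
    out: list[MergedPeak] = []
    for pk in peaks:
        tree = trees.get(pk.interval.chrom)
        if tree is not None and tree.overlap(pk.interval.start, pk.interval.end):
            continue
        out.append(pk)
    return out


def recurrence_histogram(peaks: Iterable[MergedPeak]) -> dict[int, int]:
    """Tally peaks by recurrence (number of supporting experiments)."""
    hist: dict[int, int] = {}
    for pk in peaks:
        hist[pk.recurrence] = hist.get(pk.recurrence, 0) + 1
    return dict(sorted(hist.items()))


def filter_by_recurrence(peaks: Iterable[MergedPeak], min_recurrence: int) -> list[MergedPeak]:
    """Keep peaks supported by at least ``min_recurrence`` experiments."""
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")
    return [pk for pk in peaks if pk.recurrence >= min_recurrence]


def write_merged_peaks(peaks: Iterable[MergedPeak], path: str | Path) -> None:
    """Write merged peaks as BED: chrom, start, end, support count, ids."""
    with open(path, "w") as fh:
        for pk in peaks:
            ids = ",".join(sorted(pk.support))
            fh.write(
                f"{pk.interval.chrom}\t{pk.interval.start}\t{pk.interval.end}"
                f"\t{pk.recurrence}\t{ids}\n"
            )


def read_merged_peaks(path: str | Path) -> list[MergedPeak]:
    """Read peaks written by :func:`write_merged_peaks`."""
    out: list[MergedPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            support = frozenset(fields[4].split(","))
            if len(support) != int(fields[3]):
                raise ValueError(f"{path}:{lineno}: support count mismatch")
            out.append(MergedPeak(interval, support))
    return out
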