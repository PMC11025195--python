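"""Scoring a pipeline run against simulator ground truth.

Used by the test suite and the reproduction script to measure how many
planted sites receive their planted occupancy category, whether blacklisted
sites leak into downstream outputs, and whether the recurrence histogram
matches the truth tally.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composite import PEAK_CANONICAL, PEAK_NO_MOTIF, PEAK_NONCANONICAL_PREFIX
from .intervals import GenomicInterval, MergedPeak, recurrence_histogram
from .pipeline import PipelineResult
from .synthetic_data import CATEGORY_NONE, TruthRecord

__all__ = ["RecoveryReport", "expected_peak_label", "evaluate_run", "truth_recurrence_tally"]


def expected_peak_label(category: str) -> str:
    """Peak occupancy label implied by a planted site category."""
    if category == "canonical":
        return PEAK_CANONICAL
    if category == CATEGORY_NONE:
        return PEAK_NO_MOTIF
    return f"{PEAK_NONCANONICAL_PREFIX}:{category}"


@dataclass
class RecoveryReport:
    n_evaluated: int            # non-blacklisted, non-singleton planted sites
    n_recovered: int            # of those, peak label == planted label
    blacklisted_leaks: int      # blacklisted sites overlapping any kept peak
    singleton_leaks: int        # singleton-only sites surviving the filter
    histogram_matches: bool     # pipeline recurrence tally == truth tally

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_evaluated if self.n_evaluated else float("nan")


def truth_recurrence_tally(truth: list[TruthRecord]) -> dict[int, int]:
    """Expected recurrence histogram over non-blacklisted truth sites."""
    tally: dict[int, int] = {}
    for rec in truth:
        if rec.blacklisted or rec.recurrence == 0:
            continue
        tally[rec.recurrence] = tally.get(rec.recurrence, 0) + 1
    return dict(sorted(tally.items()))


def _overlapping_peak(rec: TruthRecord, peaks: list[MergedPeak]) -> MergedPeak | None:
    iv = GenomicInterval(rec.chrom, rec.start, max(rec.end, rec.start + 1))
    for pk in peaks:
        if pk.interval.overlaps(iv):
            return pk
    return None


def evaluate_run(truth: list[TruthRecord], result: PipelineResult) -> RecoveryReport:
    """Compare one pipeline run against the simulator's ground truth."""
    n_eval = n_rec = black_leaks = singleton_leaks = 0
    for rec in truth:
        is_singleton = rec.sharing_class.startswith("singleton:")
        pk = _overlapping_peak(rec, result.kept)
        if rec.blacklisted:
            if pk is not None:
                black_leaks += 1
            continue
        if is_singleton:
            if pk is not None and pk.recurrence <= 1:
                singleton_leaks += 1
            continue
        n_eval += 1
        if pk is not None and result.peak_categories.get(pk) == expected_peak_label(rec.category):
            n_rec += 1

    hist_ok = recurrence_histogram(result.filtered) == truth_recurrence_tally(truth)
    return RecoveryReport(
        n_evaluated=n_eval,
        n_recovered=n_rec,
        blacklisted_leaks=black_leaks,
        singleton_leaks=singleton_leaks,
        histogram_matches=hist_ok,
    )
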