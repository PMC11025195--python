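"""Strand-aware PWM scanning of peak sequences.

Every window of motif width on both strands of each peak sequence is scored;
minus-strand hits come from scanning the forward sequence with the
reverse-complement matrix, so reported intervals are always forward-strand
genomic coordinates.  Windows containing non-ACGT characters are skipped.
The fraction-of-maximum filter keeps hits scoring at least
``fraction * max_score`` (the primary filter of the analysis, default 0.84:
hits scoring *less than* 84% of the maximum are discarded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

from .intervals import GenomicInterval, MergedPeak
from .motif_model import LogOddsMatrix, reverse_complement

__all__ = [
    "MotifHit",
    "extract_peak_sequences",
    "scan",
    "threshold_by_fraction",
    "write_hits",
    "read_hits",
]

_ENCODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i
    _ENCODE[ord(b.lower())] = i


@dataclass(frozen=True)
class MotifHit:
    """A scored match of the full motif or one half segment.

    ``interval`` is in forward-strand genomic coordinates; ``matched_seq`` is
    the forward-strand genome slice regardless of ``strand``.
    """

    interval: GenomicInterval
    strand: str                 # '+' or '-'
    segment_kind: str           # 'full' | 'left' | 'right'
    score: float                # bits
    matched_seq: str
    source_peak: MergedPeak


def extract_peak_sequences(
    genome: str | Path, peaks: Sequence[MergedPeak]
) -> list[tuple[MergedPeak, str]]:
    """Fetch the uppercase forward-strand sequence of each peak from a FASTA."""
    fasta = Fasta(str(genome), as_raw=True, rebuild=True)
    out: list[tuple[MergedPeak, str]] = []
    for pk in peaks:
        iv = pk.interval
        if iv.chrom not in fasta:
            raise KeyError(f"chromosome {iv.chrom!r} not present in {genome}")
        contig = fasta[iv.chrom]
        if iv.end > len(contig):
            raise ValueError(
                f"peak {iv.chrom}:[{iv.start},{iv.end}) extends past contig end {len(contig)}"
            )
        seq = str(contig[iv.start: iv.end]).upper()
        out.append((pk, seq))
    return out


def _window_scores(codes: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all length-w windows; boolean validity (no non-ACGT base)."""
    w = scores.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)  # n x w
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    vals = scores[np.arange(w)[None, :], safe].sum(axis=1)
    return vals, valid


def scan(
    lom: LogOddsMatrix, segment_kind: str, peak: MergedPeak, sequence: str
) -> list[MotifHit]:
    """Score every window of ``sequence`` on both strands with ``lom``.

    Returns one hit per valid window per strand, in genomic coordinates.
    No thresholding is applied here; see :func:`threshold_by_fraction`.
    """
    w = lom.width
    if len(sequence) < w:
        return []
    codes = _ENCODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    fwd, valid = _window_scores(codes, lom.scores)
    rev, _ = _window_scores(codes, reverse_complement(lom).scores)

    hits: list[MotifHit] = []
    chrom, pstart = peak.interval.chrom, peak.interval.start
    for off in np.flatnonzero(valid):
        off = int(off)
        iv = GenomicInterval(chrom, pstart + off, pstart + off + w)
        mseq = sequence[off: off + w].upper()
        hits.append(MotifHit(iv, "+", segment_kind, float(fwd[off]), mseq, peak))
        hits.append(MotifHit(iv, "-", segment_kind, float(rev[off]), mseq, peak))
    return hits


def threshold_by_fraction(
    hits: Iterable[MotifHit], lom: LogOddsMatrix, fraction: float = 0.84
) -> list[MotifHit]:
    """Keep hits with score >= fraction * max_score (boundary kept)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    cutoff = fraction * lom.max_score
    return [h for h in hits if h.score >= cutoff - 1e-9]


def write_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write hits as TSV: chrom, start, end, strand, segment_kind, score, seq.

    Coordinates are 0-based half-open (BED convention, unlike FIMO's 1-based).
    """
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tsegment_kind\tscore\tmatched_seq\n")
        for h in hits:
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}"
                f"\t{h.strand}\t{h.segment_kind}\t{h.score:.6f}\t{h.matched_seq}\n"
            )


def read_hits(path: str | Path, peaks: Sequence[MergedPeak]) -> list[MotifHit]:
    """Read a hits TSV, re-attaching each hit to its enclosing peak."""
    by_chrom: dict[str, list[MergedPeak]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.interval.chrom, []).append(pk)
    hits: list[MotifHit] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: missing header line")
        for line in fh:
            chrom, start, end, strand, kind, score, seq = line.rstrip("\n").split("\t")
            iv = GenomicInterval(chrom, int(start), int(end))
            peak = next(
                (pk for pk in by_chrom.get(chrom, ())
                 if pk.interval.start <= iv.start and iv.end <= pk.interval.end),
                None,
            )
            if peak is None:
                raise ValueError(f"{path}: hit {chrom}:{start}-{end} outside every peak")
            hits.append(MotifHit(iv, strand, kind, float(score), seq, peak))
    return hits
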