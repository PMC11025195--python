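"""RE1 motif model: MEME-format parsing, log-odds scoring matrices for the
full 21-bp motif and its two half segments, and the exact score null
distribution under the background model.

The RE1 element recognised by REST/NRSF is 21 bp: a 9-nt left segment and a
10-nt right segment separated by a 2-bp non-conserved gap.  Scoring follows
the standard FIMO construction: position probabilities are regularised with a
total pseudocount of 0.1 apportioned by the background and weighted by the
number of source sites (``nsites``), then converted to log2 odds against the
background.  The score of a sequence window is the sum of per-position
log-odds values; the maximum score is attained by the consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G channel swap

# RE1-specific segment geometry: left 9 nt, 2-bp gap, right 10 nt.
LEFT_WIDTH = 9
RIGHT_WIDTH = 10
GAP_WIDTH = 2
FULL_WIDTH = LEFT_WIDTH + GAP_WIDTH + RIGHT_WIDTH

__all__ = [
    "PositionFrequencyMatrix",
    "LogOddsMatrix",
    "MotifSegments",
    "ScoreDistribution",
    "read_meme_motif",
    "write_meme",
    "to_log_odds",
    "split_segments",
    "reverse_complement",
    "score_distribution",
]


@dataclass
class PositionFrequencyMatrix:
    """Base probabilities per motif position, with background and nsites."""

    motif_id: str
    probs: np.ndarray  # width x 4, rows sum to 1
    nsites: int = 20
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a width x 4 matrix with width >= 1")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError("each position's probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


@dataclass
class LogOddsMatrix:
    """Log2-odds scoring form of a PFM (scores in bits)."""

    motif_id: str
    scores: np.ndarray  # width x 4

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.scores.argmax(axis=1))

    def score_sequence(self, seq: str) -> float:
        """Score a sequence of exactly the motif width (forward strand)."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != width {self.width}")
        idx = [_BASE_INDEX[b] for b in seq.upper()]
        return float(self.scores[np.arange(self.width), idx].sum())


@dataclass
class MotifSegments:
    """The two half segments of the full RE1 motif."""

    left: PositionFrequencyMatrix
    right: PositionFrequencyMatrix
    excluded_gap_positions: tuple[int, int]


def read_meme_motif(path: str | Path, motif_id: str | None = None) -> PositionFrequencyMatrix:
    """Parse one motif from a MEME minimal-format file.

    If ``motif_id`` is None the file must contain exactly one motif.  The
    background defaults to uniform 0.25 when the file lacks a
    "Background letter frequencies" section; ``nsites`` defaults to 20.
    """
    text = Path(path).read_text()
    alpha_m = re.search(r"^ALPHABET\s*=\s*(\S+)", text, re.M)
    if alpha_m and alpha_m.group(1).upper() != "ACGT":
        raise ValueError(f"unsupported alphabet {alpha_m.group(1)!r}; only ACGT")

    background = np.full(4, 0.25)
    bg_m = re.search(
        r"Background letter frequencies[^\n]*\n([ACGT0-9.eE+\-\s]+)", text
    )
    if bg_m:
        toks = bg_m.group(1).split()
        freq = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2) if toks[i] in _BASE_INDEX}
        if len(freq) == 4:
            background = np.array([freq[b] for b in ALPHABET])

    motif_blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
    if not motif_blocks:
        raise ValueError(f"no MOTIF entries in {path}")
    chosen = None
    for block in motif_blocks:
        header = block.splitlines()[0].split()
        mid = header[0]
        if motif_id is None or motif_id in header:
            chosen = (mid, block)
            if motif_id is not None:
                break
    if chosen is None:
        raise ValueError(f"motif {motif_id!r} not found in {path}")
    if motif_id is None and len(motif_blocks) > 1:
        raise ValueError(f"{path} contains {len(motif_blocks)} motifs; specify motif_id")

    mid, block = chosen
    lpm = re.search(r"letter-probability matrix:([^\n]*)\n", block)
    if not lpm:
        raise ValueError(f"motif {mid}: missing letter-probability matrix")
    attrs = dict(re.findall(r"(\w+)\s*=\s*(\S+)", lpm.group(1)))
    width = int(attrs["w"]) if "w" in attrs else None
    nsites = int(float(attrs["nsites"])) if "nsites" in attrs else 20

    rows: list[list[float]] = []
    for line in block[lpm.end():].splitlines():
        parts = line.split()
        if len(parts) == 4:
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                break
        elif rows:
            break
    if width is not None:
        rows = rows[:width]
    probs = np.array(rows)
    if width is not None and probs.shape[0] != width:
        raise ValueError(f"motif {mid}: expected {width} rows, got {probs.shape[0]}")
    return PositionFrequencyMatrix(motif_id=mid, probs=probs, nsites=nsites, background=background)


def write_meme(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Write a single motif in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, pfm.background)) + "\n\n")
        fh.write(f"MOTIF {pfm.motif_id}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pfm.width} "
            f"nsites= {pfm.nsites} E= 0\n"
        )
        for row in pfm.probs:
            fh.write(" ".join(f"{p:.9f}" for p in row) + "\n")


def to_log_odds(pfm: PositionFrequencyMatrix, pseudocount: float = 0.1) -> LogOddsMatrix:
    """Build the log2-odds scoring matrix with FIMO-style regularisation.

    p'[i,b] = (probs[i,b] * nsites + pseudocount * background[b]) / (nsites + pseudocount)
    scores[i,b] = log2(p'[i,b] / background[b])
    """
    if np.any(pfm.background <= 0):
        raise ValueError("background probabilities must be strictly positive")
    p = (pfm.probs * pfm.nsites + pseudocount * pfm.background) / (pfm.nsites + pseudocount)
    lom = LogOddsMatrix(motif_id=pfm.motif_id, scores=np.log2(p / pfm.background))
    if lom.max_score <= 0:
        raise ValueError(
            f"motif {pfm.motif_id}: non-positive maximum score; "
            "fraction-of-maximum thresholds would be meaningless"
        )
    return lom


def split_segments(
    pfm: PositionFrequencyMatrix,
    left_width: int = LEFT_WIDTH,
    gap_width: int = GAP_WIDTH,
    right_width: int = RIGHT_WIDTH,
) -> MotifSegments:
    """Split the full motif into left/right half segments, dropping the gap.

    Defaults encode the RE1 geometry (first 9 nt, middle 2 dropped, last
    10 nt) and require a 21-wide input.
    """
    expected = left_width + gap_width + right_width
    if pfm.width != expected:
        raise ValueError(
            f"motif width {pfm.width} != {expected} "
            f"(= {left_width} + {gap_width} + {right_width})"
        )
    left = PositionFrequencyMatrix(
        motif_id=f"{pfm.motif_id}_left",
        probs=pfm.probs[:left_width].copy(),
        nsites=pfm.nsites,
        background=pfm.background.copy(),
    )
    right = PositionFrequencyMatrix(
        motif_id=f"{pfm.motif_id}_right",
        probs=pfm.probs[left_width + gap_width:].copy(),
        nsites=pfm.nsites,
        background=pfm.background.copy(),
    )
    return MotifSegments(
        left=left, right=right,
        excluded_gap_positions=(left_width, left_width + gap_width - 1),
    )


def reverse_complement(lom: LogOddsMatrix) -> LogOddsMatrix:
    """Scoring matrix for the reverse-complement strand (involution)."""
    return LogOddsMatrix(
        motif_id=f"{lom.motif_id}_rc",
        scores=lom.scores[::-1, _COMPLEMENT_PERM].copy(),
    )


@dataclass
class ScoreDistribution:
    """Exact null distribution of the discretized window score.

    Scores are rounded per position to multiples of ``step`` (bits) and the
    per-position pmfs convolved under the background model; ``support`` is the
    full achievable integer grid expressed back in bits.
    """

    support: np.ndarray       # ascending achievable scores, bits
    pmf: np.ndarray           # matching probabilities
    step: float
    width: int
    _offset: int = 0          # support[0] / step, integer grid origin
    _sf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self._sf is None:
            self._sf = np.cumsum(self.pmf[::-1])[::-1]

    def p_value(self, score: float) -> float:
        """P(null score >= ``score``).

        A rounding slack of step/2 per position is applied so that a score
        computed in exact arithmetic (e.g. ``max_score``) maps onto the
        discretized grid conservatively; p_value is non-increasing in score.
        """
        slack = self.width * self.step / 2.0
        k = int(np.ceil((score - slack - self.support[0]) / self.step - 1e-12))
        if k <= 0:
            return 1.0
        if k >= len(self.support):
            return 0.0
        return float(self._sf[k])


def score_distribution(
    lom: LogOddsMatrix,
    background: np.ndarray | None = None,
    step: float = 0.001,
) -> ScoreDistribution:
    """Exact pmf of the window score of a random background sequence.

    Per-position scores are discretized to integer multiples of ``step`` and
    the position pmfs convolved (dynamic programming over positions); the
    result is exact on the discretized score.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    ints = np.rint(lom.scores / step).astype(np.int64)  # width x 4

    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # start with the first position, then convolve the rest in turn
    cur_lo = int(ints[0].min())
    cur = np.zeros(int(ints[0].max()) - cur_lo + 1)
    for b in range(4):
        cur[ints[0, b] - cur_lo] += bg[b]
    for pos in range(1, lom.width):
        p_lo = int(ints[pos].min())
        p = np.zeros(int(ints[pos].max()) - p_lo + 1)
        for b in range(4):
            p[ints[pos, b] - p_lo] += bg[b]
        cur = np.convolve(cur, p)
        cur_lo += p_lo
    pmf[cur_lo - lo: cur_lo - lo + len(cur)] = cur
    support = (np.arange(lo, hi + 1)) * step
    return ScoreDistribution(support=support, pmf=pmf, step=step, width=lom.width, _offset=lo)


def discretized_score(lom: LogOddsMatrix, seq: str, step: float = 0.001) -> float:
    """Window score on the same discretized grid as :func:`score_distribution`."""
    ints = np.rint(lom.scores / step).astype(np.int64)
    idx = [_BASE_INDEX[b] for b in seq.upper()]
    return float(ints[np.arange(lom.width), idx].sum() * step)
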