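"""Synthetic ChIP-seq study generator with planted RE1 motifs and ground truth.

Emulates the statistical structure the pipeline assumes: a random background
genome; experiments grouped into cell lines with replicates; merged-peak
sharing classes (universal sites supported by every experiment, cell-line
specific sites supported by one line's replicates, singleton peaks supported
by a single experiment); planted motif instances in each geometric
configuration (canonical 2-bp gap, altered gap, convergent, divergent,
flipped, left-only, right-only); motif-free peaks; and blacklist regions, a
fraction of which overlap planted peaks.

Planted motif text uses a per-base fidelity mixture: each position is the
consensus base with probability ``motif_fidelity`` and otherwise drawn from
the PFM row, so fidelity 1.0 plants exact consensus text.  All randomness
comes from one seeded generator in a fixed draw order, so identical configs
produce byte-identical outputs.

The module also ships :func:`synthetic_re1_pfm`, a programmatically built
stand-in for the JASPAR RE1 matrix: a synthetic 21-bp PFM on the published
RE1 consensus (TTCAGCACC + 2-bp gap + GGACAGCGCC) with near-uniform gap
columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .motif_model import (
    ALPHABET,
    FULL_WIDTH,
    GAP_WIDTH,
    LEFT_WIDTH,
    RIGHT_WIDTH,
    PositionFrequencyMatrix,
    split_segments,
    to_log_odds,
    write_meme,
)

# canonical-form RE1 consensus: left 9 nt + 2-bp non-conserved gap + right 10 nt
LEFT_CONSENSUS = "TTCAGCACC"
GAP_CONSENSUS = "AC"
RIGHT_CONSENSUS = "GGACAGCGCC"

CATEGORY_NONE = "none"  # motif-free truth sites

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def synthetic_re1_pfm(
    consensus_prob: float = 0.85, motif_id: str = "RE1_synthetic"
) -> PositionFrequencyMatrix:
    """Synthetic 21-bp RE1-like PFM (not the JASPAR matrix).

    Informative positions put ``consensus_prob`` on the consensus base and
    split the rest evenly; the two gap positions are uniform.
    """
    full = LEFT_CONSENSUS + GAP_CONSENSUS + RIGHT_CONSENSUS
    assert len(full) == FULL_WIDTH
    off = (1.0 - consensus_prob) / 3.0
    probs = np.full((FULL_WIDTH, 4), off)
    for i, base in enumerate(full):
        probs[i, ALPHABET.index(base)] = consensus_prob
    probs[LEFT_WIDTH: LEFT_WIDTH + GAP_WIDTH] = 0.25  # non-conserved gap
    return PositionFrequencyMatrix(motif_id=motif_id, probs=probs, nsites=20)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run (defaults = standard study)."""

    seed: int = 7
    genome_length: int = 2_000_000
    gc_content: float = 0.41
    chrom: str = "chrSim"
    n_cell_lines: int = 3
    replicates_per_line: int = 3
    n_universal_sites: int = 60
    n_line_specific_sites: int = 60
    n_singleton_peaks: int = 30
    n_motif_free_sites: int = 30
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.25,
            "altered_gap": 0.15,
            "convergent": 0.10,
            "divergent": 0.10,
            "flipped": 0.10,
            "left_only": 0.15,
            "right_only": 0.15,
        }
    )
    peak_halfwidth: int = 150
    peak_jitter: int = 15
    motif_fidelity: float = 0.95
    detection_rate: float = 1.0
    n_blacklist_regions: int = 8
    blacklist_overlap_fraction: float = 0.5
    blacklist_halfwidth: int = 400

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix proportions must sum to 1")
        for name in ("n_universal_sites", "n_line_specific_sites",
                     "n_singleton_peaks", "n_motif_free_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.motif_fidelity <= 1):
            raise ValueError("motif_fidelity must be in (0, 1]")

    @property
    def n_sites(self) -> int:
        return (self.n_universal_sites + self.n_line_specific_sites
                + self.n_singleton_peaks + self.n_motif_free_sites)

    @property
    def experiments(self) -> list[tuple[str, str]]:
        """(experiment_id, cell_line) pairs, lines x replicates."""
        return [
            (f"CL{i + 1}.rep{j + 1}", f"CL{i + 1}")
            for i in range(self.n_cell_lines)
            for j in range(self.replicates_per_line)
        ]


@dataclass
class TruthRecord:
    """Ground truth for one planted site."""

    site_id: str
    chrom: str
    start: int            # genomic span of the planted insert (peak center for motif-free)
    end: int
    category: str         # a motif category or "none"
    gap: int | None
    strand: str           # planted strand ('.' for motif-free)
    sharing_class: str    # "universal" | "line:<cell_line>" | "singleton:<exp>"
    experiments: tuple[str, ...]   # experiments that emitted a peak
    blacklisted: bool
    left_score: float | None = None
    right_score: float | None = None
    full_score: float | None = None

    @property
    def recurrence(self) -> int:
        return len(self.experiments)


@dataclass
class SimulationOutput:
    config: SimulationConfig
    genome_path: Path
    peak_files: list[tuple[str, str, Path]]   # (experiment_id, cell_line, path)
    blacklist_path: Path
    truth_path: Path
    motif_path: Path
    truth: list[TruthRecord]


def _sample_segment(rng: np.random.Generator, probs: np.ndarray,
                    consensus: str, fidelity: float) -> str:
    out = []
    for i, cbase in enumerate(consensus):
        if rng.random() < fidelity:
            out.append(cbase)
        else:
            out.append(ALPHABET[rng.choice(4, p=probs[i] / probs[i].sum())])
    return "".join(out)


def _bg_bases(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in rng.choice(4, size=n, p=p))


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulationOutput:
    """Generate genome FASTA, per-experiment narrowPeaks, blacklist and truth."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    pfm = synthetic_re1_pfm()
    segs = split_segments(pfm)
    full_lom = to_log_odds(pfm)
    left_lom = to_log_odds(segs.left)
    right_lom = to_log_odds(segs.right)

    gc = cfg.gc_content
    bg_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    # 1) background genome
    genome = np.array(list(_bg_bases(rng, cfg.genome_length, bg_p)))

    # 2) site placement on an evenly slotted grid (guarantees spacing)
    n_sites = cfg.n_sites
    centers: list[int] = []
    if n_sites > 0:
        slot = cfg.genome_length // (n_sites + 1)
        min_slot = 4 * cfg.peak_halfwidth + 2 * cfg.peak_jitter + 100
        if slot < min_slot:
            raise ValueError(
                f"genome too short: slot {slot} bp < {min_slot} bp needed for "
                f"{n_sites} sites at peak halfwidth {cfg.peak_halfwidth}"
            )
        jit = max(1, slot // 5)
        centers = [int(slot * (i + 1) + rng.integers(-jit, jit + 1)) for i in range(n_sites)]
        rng.shuffle(centers)

    # 3) sharing classes in a fixed order over the shuffled centers
    classes: list[str] = (
        ["universal"] * cfg.n_universal_sites
        + ["line"] * cfg.n_line_specific_sites
        + ["singleton"] * cfg.n_singleton_peaks
        + ["none"] * cfg.n_motif_free_sites
    )
    experiments = cfg.experiments
    lines = [f"CL{i + 1}" for i in range(cfg.n_cell_lines)]
    cat_names = list(cfg.category_mix)
    cat_probs = np.array([cfg.category_mix[c] for c in cat_names])
    altered_gaps = [g for g in range(50) if g != GAP_WIDTH]

    truth: list[TruthRecord] = []
    peak_calls: dict[str, list[tuple[int, int, str]]] = {e[0]: [] for e in experiments}

    for idx, (center, klass) in enumerate(zip(centers, classes)):
        site_id = f"site{idx:04d}"
        # sharing class -> designated supporting experiments
        if klass == "universal":
            sharing = "universal"
            support = [e[0] for e in experiments]
        elif klass == "line":
            line = lines[int(rng.integers(len(lines)))]
            sharing = f"line:{line}"
            support = [e[0] for e in experiments if e[1] == line]
        elif klass == "singleton":
            exp = experiments[int(rng.integers(len(experiments)))][0]
            sharing = f"singleton:{exp}"
            support = [exp]
        else:  # motif-free site: universal or line-specific occupancy
            if rng.random() < 0.5:
                sharing = "universal"
                support = [e[0] for e in experiments]
            else:
                line = lines[int(rng.integers(len(lines)))]
                sharing = f"line:{line}"
                support = [e[0] for e in experiments if e[1] == line]

        # planted motif
        category = CATEGORY_NONE
        gap: int | None = None
        strand = "."
        lscore = rscore = fscore = None
        if klass != "none":
            category = cat_names[int(rng.choice(len(cat_names), p=cat_probs))]
            strand = "+" if rng.random() < 0.5 else "-"
            left_txt = _sample_segment(rng, segs.left.probs, LEFT_CONSENSUS, cfg.motif_fidelity)
            right_txt = _sample_segment(rng, segs.right.probs, RIGHT_CONSENSUS, cfg.motif_fidelity)
            lscore = left_lom.score_sequence(left_txt)
            rscore = right_lom.score_sequence(right_txt)
            if category == "canonical":
                gap = GAP_WIDTH
            elif category == "altered_gap":
                gap = int(altered_gaps[rng.integers(len(altered_gaps))])
            elif category in ("convergent", "divergent", "flipped"):
                gap = int(rng.integers(0, 50))
            gap_txt = _bg_bases(rng, gap, bg_p) if gap else ""
            if category == "canonical":
                insert = left_txt + gap_txt + right_txt
                fscore = full_lom.score_sequence(insert)
            elif category == "altered_gap":
                insert = left_txt + gap_txt + right_txt
            elif category == "flipped":
                insert = right_txt + gap_txt + left_txt
            elif category == "convergent":
                insert = left_txt + gap_txt + _revcomp(right_txt)
            elif category == "divergent":
                insert = _revcomp(left_txt) + gap_txt + right_txt
            elif category == "left_only":
                insert = left_txt
            else:  # right_only
                insert = right_txt
            if strand == "-":
                insert = _revcomp(insert)
            s = center - len(insert) // 2
            genome[s: s + len(insert)] = list(insert)
            span = (s, s + len(insert))
        else:
            span = (center, center + 1)

        # peaks: each designated experiment emits one with small edge jitter
        emitted: list[str] = []
        for exp in support:
            if cfg.detection_rate < 1.0 and rng.random() >= cfg.detection_rate:
                continue
            a = int(center - cfg.peak_halfwidth + rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
            b = int(center + cfg.peak_halfwidth + rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
            a = max(0, a)
            b = min(cfg.genome_length, b)
            peak_calls[exp].append((a, b, site_id))
            emitted.append(exp)

        truth.append(TruthRecord(
            site_id=site_id, chrom=cfg.chrom, start=span[0], end=span[1],
            category=category, gap=gap, strand=strand, sharing_class=sharing,
            experiments=tuple(emitted), blacklisted=False,
            left_score=lscore, right_score=rscore, full_score=fscore,
        ))

    # 4) blacklist: some regions on planted sites, the rest in empty space
    blacklist: list[tuple[int, int]] = []
    if cfg.n_blacklist_regions > 0 and n_sites > 0:
        n_hit = int(round(cfg.n_blacklist_regions * cfg.blacklist_overlap_fraction))
        n_hit = min(n_hit, n_sites)
        hit_idx = rng.choice(n_sites, size=n_hit, replace=False)
        for i in sorted(int(x) for x in hit_idx):
            rec = truth[i]
            c = (rec.start + rec.end) // 2
            blacklist.append((max(0, c - cfg.blacklist_halfwidth),
                              min(cfg.genome_length, c + cfg.blacklist_halfwidth)))
            truth[i] = dataclasses.replace(rec, blacklisted=True)
        slot = cfg.genome_length // (n_sites + 1)
        for k in range(cfg.n_blacklist_regions - n_hit):
            # between-slot midpoints are guaranteed clear of every peak
            pos = int(slot * (k + 1) + slot // 2)
            blacklist.append((pos - cfg.blacklist_halfwidth, pos + cfg.blacklist_halfwidth))
        blacklist.sort()

    # ---- write outputs ----
    genome_path = out / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        seq = "".join(genome)
        for i in range(0, len(seq), 80):
            fh.write(seq[i: i + 80] + "\n")

    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    peak_files: list[tuple[str, str, Path]] = []
    for exp_id, cell_line in experiments:
        path = peaks_dir / f"{exp_id}.narrowPeak"
        with open(path, "w") as fh:
            for a, b, name in sorted(peak_calls[exp_id]):
                fh.write(f"{cfg.chrom}\t{a}\t{b}\t{name}\t0\t.\t0\t-1\t-1\t-1\n")
        peak_files.append((exp_id, cell_line, path))

    blacklist_path = out / "blacklist.bed"
    with open(blacklist_path, "w") as fh:
        for a, b in blacklist:
            fh.write(f"{cfg.chrom}\t{a}\t{b}\n")

    motif_path = out / "motif.meme"
    write_meme(pfm, motif_path)

    truth_path = out / "truth.tsv"
    write_truth(truth, truth_path)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

    return SimulationOutput(
        config=cfg, genome_path=genome_path, peak_files=peak_files,
        blacklist_path=blacklist_path, truth_path=truth_path,
        motif_path=motif_path, truth=truth,
    )


_TRUTH_COLS = ("site_id", "chrom", "start", "end", "category", "gap", "strand",
               "sharing_class", "experiments", "blacklisted",
               "left_score", "right_score", "full_score")


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for r in truth:
            fh.write("\t".join([
                r.site_id, r.chrom, str(r.start), str(r.end), r.category,
                "." if r.gap is None else str(r.gap), r.strand, r.sharing_class,
                ",".join(r.experiments), "1" if r.blacklisted else "0",
                *("." if v is None else f"{v:.6f}"
                  for v in (r.left_score, r.right_score, r.full_score)),
            ]) + "\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLS:
            raise ValueError(f"{path}: unexpected truth header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(TruthRecord(
                site_id=f[0], chrom=f[1], start=int(f[2]), end=int(f[3]),
                category=f[4], gap=None if f[5] == "." else int(f[5]), strand=f[6],
                sharing_class=f[7],
                experiments=tuple(x for x in f[8].split(",") if x),
                blacklisted=f[9] == "1",
                left_score=None if f[10] == "." else float(f[10]),
                right_score=None if f[11] == "." else float(f[11]),
                full_score=None if f[12] == "." else float(f[12]),
            ))
    return out
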