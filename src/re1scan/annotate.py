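"""Simplified genomic annotation of composite sites.

Labels each site exonic, intronic, upstream or intergenic against a small
gene model, with precedence exonic > intronic > upstream > intergenic.
"Upstream" is the strand-aware 1-kb window immediately 5' of a transcription
start site; any >= 1 bp overlap of the site interval counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .composite import CompositeSite, Thresholds
from .intervals import GenomicInterval

EXONIC = "exonic"
INTRONIC = "intronic"
UPSTREAM = "upstream"
INTERGENIC = "intergenic"

__all__ = ["Transcript", "GeneModel", "annotate_site", "annotate_sites",
           "read_transcripts_bed12", "read_transcripts_tsv"]


@dataclass
class Transcript:
    name: str
    chrom: str
    strand: str          # '+' or '-'
    tx_start: int
    tx_end: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.name}: bad strand {self.strand!r}")
        for ex in self.exons:
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"transcript {self.name}: exon outside transcript body")

    def upstream_window(self, size: int) -> GenomicInterval | None:
        """Strand-aware window immediately 5' of the TSS."""
        if self.strand == "+":
            start, end = max(0, self.tx_start - size), self.tx_start
        else:
            start, end = self.tx_end, self.tx_end + size
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end)


@dataclass
class GeneModel:
    transcripts: list[Transcript] = field(default_factory=list)


def annotate_site(
    site: CompositeSite, model: GeneModel, th: Thresholds | None = None
) -> str:
    """Label one site; overlap of the whole site interval (>= 1 bp) decides."""
    th = th or Thresholds()
    iv = site.interval
    hit_intron = hit_upstream = False
    for tx in model.transcripts:
        if tx.chrom != iv.chrom:
            continue
        body = GenomicInterval(tx.chrom, tx.tx_start, tx.tx_end)
        if iv.overlaps(body):
            if any(iv.overlaps(ex) for ex in tx.exons):
                return EXONIC
            hit_intron = True
        win = tx.upstream_window(th.upstream_window)
        if win is not None and iv.overlaps(win):
            hit_upstream = True
    if hit_intron:
        return INTRONIC
    if hit_upstream:
        return UPSTREAM
    return INTERGENIC


def annotate_sites(
    sites: Sequence[CompositeSite], model: GeneModel, th: Thresholds | None = None
) -> list[str]:
    return [annotate_site(s, model, th) for s in sites]


def read_transcripts_bed12(path: str | Path) -> GeneModel:
    """Read a BED12 gene model (blockStarts relative to chromStart)."""
    txs: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            txs.append(Transcript(name, chrom, strand, start, end, exons))
    return GeneModel(txs)


def read_transcripts_tsv(path: str | Path) -> GeneModel:
    """Read a minimal 6-column model: name, chrom, strand, start, end, exons.

    The exons column is comma-separated "start-end" pairs (0-based half-open).
    """
    txs: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: need 6 columns")
            name, chrom, strand = f[0], f[1], f[2]
            tx_start, tx_end = int(f[3]), int(f[4])
            exons = []
            for tok in f[5].split(","):
                if tok:
                    a, b = tok.split("-")
                    exons.append(GenomicInterval(chrom, int(a), int(b)))
            txs.append(Transcript(name, chrom, strand, tx_start, tx_end, exons))
    return GeneModel(txs)


def write_annotations(
    sites: Sequence[CompositeSite], labels: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tannotation\n")
        for s, lab in zip(sites, labels):
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                     f"\t{s.category}\t{lab}\n")
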