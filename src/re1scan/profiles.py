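"""Experiments x peaks categorical RE1 occupancy profiles.

The profile matrix holds one label per (experiment, merged peak) cell:
``NoPeak`` where the experiment does not support the peak, otherwise the
peak's motif category (``Peak_cRE1``, ``Peak_ncRE1:<subtype>`` or
``Peak_NoRE1``).  Motif content is a property of the merged region, so all
supporting experiments of one peak share the same motif label.  Both axes
can be ordered by hierarchical clustering of an ordinal encoding of the
labels; the score-vs-recurrence summary groups full-length site scores by
how many experiments share the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .composite import (
    CompositeSite,
    FULL_LENGTH_CATEGORIES,
    NO_PEAK,
    PEAK_CANONICAL,
    PEAK_NO_MOTIF,
    PEAK_NONCANONICAL_PREFIX,
)
from .intervals import MergedPeak

# ordinal encoding used for clustering distances (configurable)
DEFAULT_ENCODING: dict[str, int] = {
    NO_PEAK: 0,
    PEAK_NO_MOTIF: 1,
    f"{PEAK_NONCANONICAL_PREFIX}:left_only": 2,
    f"{PEAK_NONCANONICAL_PREFIX}:right_only": 3,
    f"{PEAK_NONCANONICAL_PREFIX}:flipped": 4,
    f"{PEAK_NONCANONICAL_PREFIX}:divergent": 5,
    f"{PEAK_NONCANONICAL_PREFIX}:convergent": 6,
    f"{PEAK_NONCANONICAL_PREFIX}:altered_gap": 7,
    PEAK_CANONICAL: 8,
}

__all__ = [
    "ProfileMatrix",
    "build_profile_matrix",
    "cluster_matrix",
    "score_recurrence_summary",
    "DEFAULT_ENCODING",
]


@dataclass
class ProfileMatrix:
    """Categorical occupancy matrix with optional clustered orderings."""

    experiments: list[tuple[str, str]]        # (experiment_id, cell_line)
    peaks: list[MergedPeak]
    values: pd.DataFrame                      # rows: experiment ids, cols: peak names
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)

    def reordered(self) -> pd.DataFrame:
        df = self.values
        if self.row_order:
            df = df.iloc[self.row_order]
        if self.col_order:
            df = df.iloc[:, self.col_order]
        return df

    def encoded(self, encoding: Mapping[str, int] | None = None) -> np.ndarray:
        enc = DEFAULT_ENCODING if encoding is None else encoding
        try:
            return np.array([[enc[v] for v in row] for row in self.values.to_numpy()])
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} missing from encoding") from exc

    def write_tsv(self, path: str | Path, reorder: bool = True) -> None:
        (self.reordered() if reorder else self.values).to_csv(path, sep="\t")


def peak_name(pk: MergedPeak) -> str:
    iv = pk.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def build_profile_matrix(
    peaks: Sequence[MergedPeak],
    categories: Mapping[MergedPeak, str],
    experiments: Sequence[tuple[str, str]],
    drop_no_motif: bool = False,
) -> ProfileMatrix:
    """Assemble the experiments x peaks label matrix.

    ``categories`` maps each peak to its motif label.  With
    ``drop_no_motif`` peaks whose label is ``Peak_NoRE1`` are excluded
    (the profile of peaks that do carry an RE1 motif).
    """
    kept: list[MergedPeak] = []
    for pk in peaks:
        if pk not in categories:
            raise KeyError(f"no category for peak {peak_name(pk)}")
        if drop_no_motif and categories[pk] == PEAK_NO_MOTIF:
            continue
        kept.append(pk)

    exp_ids = [e[0] for e in experiments]
    data = {
        peak_name(pk): [
            categories[pk] if eid in pk.support else NO_PEAK for eid in exp_ids
        ]
        for pk in kept
    }
    values = pd.DataFrame(data, index=exp_ids, columns=[peak_name(pk) for pk in kept])
    return ProfileMatrix(list(experiments), kept, values)


def _axis_order(mat: np.ndarray, metric: str, method: str) -> list[int]:
    n = mat.shape[0]
    if n < 2:
        return list(range(n))
    dist = pdist(mat.astype(float), metric=metric)
    if not np.any(dist > 0):       # all rows identical: keep stable input order
        return list(range(n))
    return [int(i) for i in leaves_list(linkage(dist, method=method))]


def cluster_matrix(
    pm: ProfileMatrix,
    encoding: Mapping[str, int] | None = None,
    metric: str = "euclidean",
    method: str = "complete",
) -> ProfileMatrix:
    """Order both axes by agglomerative clustering of the encoded labels.

    Returns a new ProfileMatrix whose ``row_order`` / ``col_order`` are the
    dendrogram leaf orders (stable input order for degenerate axes).
    """
    mat = pm.encoded(encoding)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        return ProfileMatrix(pm.experiments, pm.peaks, pm.values,
                             list(range(mat.shape[0])), list(range(mat.shape[1])))
    row_order = _axis_order(mat, metric, method)
    col_order = _axis_order(mat.T, metric, method)
    return ProfileMatrix(pm.experiments, pm.peaks, pm.values, row_order, col_order)


def experiment_linkage(
    pm: ProfileMatrix,
    encoding: Mapping[str, int] | None = None,
    metric: str = "euclidean",
    method: str = "complete",
) -> np.ndarray:
    """Row (experiment) linkage matrix, for dendrogram cutting."""
    return linkage(pdist(pm.encoded(encoding).astype(float), metric=metric), method=method)


def score_recurrence_summary(
    sites: Sequence[CompositeSite],
) -> pd.DataFrame:
    """Per-recurrence summary of full-length composite-site scores.

    Half-only sites (left_only / right_only) are excluded; the combined
    score of each remaining site is grouped by the recurrence of its source
    peak.  Columns: recurrence, n_sites, scores (list), mean_score.
    """
    rows = [
        (s.source_peak.recurrence, s.combined_score)
        for s in sites
        if s.category in FULL_LENGTH_CATEGORIES
    ]
    if not rows:
        return pd.DataFrame(columns=["recurrence", "n_sites", "scores", "mean_score"])
    df = pd.DataFrame(rows, columns=["recurrence", "score"])
    out = (
        df.groupby("recurrence")["score"]
        .agg(n_sites="size", scores=list, mean_score="mean")
        .reset_index()
    )
    return out


def plot_heatmap(pm: ProfileMatrix, path: str | Path,
                 encoding: Mapping[str, int] | None = None) -> None:
    """Convenience PNG/SVG of the (reordered) profile; the TSV is canonical."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    enc = DEFAULT_ENCODING if encoding is None else encoding
    order = sorted(enc.items(), key=lambda kv: kv[1])
    colors = {
        "NoPeak": "#ffffff", "Peak_NoRE1": "#bbbbbb", "Peak_cRE1": "#000000",
        "Peak_ncRE1:altered_gap": "#d62728", "Peak_ncRE1:convergent": "#1f77b4",
        "Peak_ncRE1:divergent": "#2ca02c", "Peak_ncRE1:flipped": "#9467bd",
        "Peak_ncRE1:left_only": "#ff7f0e", "Peak_ncRE1:right_only": "#e6d800",
    }
    cmap = ListedColormap([colors.get(lbl, "#888888") for lbl, _ in order])
    df = pm.reordered()
    mat = np.array([[enc[v] for v in row] for row in df.to_numpy()])
    fig, ax = plt.subplots(figsize=(max(4, mat.shape[1] / 20), max(2, mat.shape[0] / 4)))
    ax.imshow(mat, aspect="auto", cmap=cmap, vmin=0, vmax=len(order) - 1,
              interpolation="nearest")
    ax.set_yticks(range(len(df.index)), labels=df.index, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel("merged peaks (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
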