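"""End-to-end orchestration: merge -> exclude -> recurrence filter -> scan ->
threshold -> pair/classify -> half-only filter -> peak category -> optional
annotation -> profile matrix + clustering -> summaries.

The run is driven by a config mapping (usually a YAML file); every stage's
record count is logged and collected into a JSON-serialisable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .annotate import GeneModel, annotate_sites, read_transcripts_bed12, read_transcripts_tsv, write_annotations
from .composite import (
    CompositeSite,
    Thresholds,
    assign_peak_category,
    call_sites_in_peak,
    write_sites,
)
from .intervals import (
    MergedPeak,
    filter_by_recurrence,
    merge_across_experiments,
    read_narrowpeak,
    recurrence_histogram,
    subtract_any_overlap,
    write_merged_peaks,
)
from .motif_model import read_meme_motif, split_segments, to_log_odds
from .profiles import (
    ProfileMatrix,
    build_profile_matrix,
    cluster_matrix,
    peak_name,
    plot_heatmap,
    score_recurrence_summary,
)
from .scanner import extract_peak_sequences, scan, threshold_by_fraction

log = logging.getLogger("re1scan")

_REQUIRED_KEYS = ("experiments", "genome", "motif", "output_dir")


@dataclass
class PipelineResult:
    merged: list[MergedPeak]
    filtered: list[MergedPeak]          # after exclusion subtraction
    kept: list[MergedPeak]              # after recurrence filter
    histogram: dict[int, int]
    sites: list[CompositeSite]
    peak_categories: dict[MergedPeak, str]
    profile: ProfileMatrix
    score_summary: pd.DataFrame
    annotations: list[str] | None
    manifest: dict[str, Any] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _validate_config(cfg: Mapping[str, Any]) -> None:
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise KeyError(f"config is missing required key {key!r}")
    for exp in cfg["experiments"]:
        for key in ("path", "experiment_id", "cell_line"):
            if key not in exp:
                raise KeyError(f"experiment entry missing key {key!r}")
        if not Path(exp["path"]).exists():
            raise FileNotFoundError(f"peak file not found: {exp['path']}")
    for key in ("genome", "motif"):
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {cfg[key]}")
    for path in cfg.get("exclusions", []):
        if not Path(path).exists():
            raise FileNotFoundError(f"exclusion file not found: {path}")
    gm = cfg.get("gene_model")
    if gm and not Path(gm).exists():
        raise FileNotFoundError(f"gene model file not found: {gm}")


def run_pipeline(config: Mapping[str, Any] | str | Path) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    ``config`` is a mapping (or the path of a YAML file) with keys:
    ``experiments`` (list of {path, experiment_id, cell_line}), ``genome``,
    ``motif`` (MEME file), ``output_dir``; optional ``exclusions`` (list of
    BED paths), ``gene_model``, ``motif_id``, ``thresholds`` (field
    overrides), ``profile`` ({drop_no_motif, metric, linkage}) and
    ``plot_heatmap``.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    _validate_config(config)
    th = Thresholds(**config.get("thresholds", {}))
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "tool": "re1scan",
        "version": __version__,
        "config": {k: v for k, v in config.items()},
        "thresholds": dataclasses.asdict(th),
        "inputs": {},
        "counts": {},
        "outputs": {},
        "seconds": {},
    }
    for exp in config["experiments"]:
        manifest["inputs"][exp["experiment_id"]] = _sha256(exp["path"])
    manifest["inputs"]["genome"] = _sha256(config["genome"])
    manifest["inputs"]["motif"] = _sha256(config["motif"])
    for i, path in enumerate(config.get("exclusions", [])):
        manifest["inputs"][f"exclusion_{i}"] = _sha256(path)

    def stage(name: str):
        log.info("stage %s", name)
        return time.perf_counter()

    # --- merge ---
    t0 = stage("merge")
    peak_sets = [
        read_narrowpeak(e["path"], e["experiment_id"], e["cell_line"])
        for e in config["experiments"]
    ]
    merged = merge_across_experiments(peak_sets)
    manifest["counts"]["raw_peaks"] = sum(len(s.peaks) for s in peak_sets)
    manifest["counts"]["merged_peaks"] = len(merged)
    manifest["seconds"]["merge"] = round(time.perf_counter() - t0, 3)

    # --- blacklist / HOT exclusion ---
    t0 = stage("exclude")
    exclusions = []
    for path in config.get("exclusions", []):
        exclusions.extend(read_narrowpeak(path, "excl", "excl").peaks)
    filtered = subtract_any_overlap(merged, exclusions)
    manifest["counts"]["peaks_after_exclusion"] = len(filtered)
    manifest["seconds"]["exclude"] = round(time.perf_counter() - t0, 3)

    # --- recurrence filter (drop singletons by default) ---
    t0 = stage("recurrence_filter")
    histogram = recurrence_histogram(filtered)
    kept = filter_by_recurrence(filtered, th.min_recurrence)
    manifest["counts"]["peaks_after_recurrence_filter"] = len(kept)
    manifest["seconds"]["recurrence_filter"] = round(time.perf_counter() - t0, 3)

    # --- motif scan ---
    t0 = stage("scan")
    pfm = read_meme_motif(config["motif"], config.get("motif_id"))
    segs = split_segments(pfm)
    full_lom = to_log_odds(pfm)
    left_lom = to_log_odds(segs.left)
    right_lom = to_log_odds(segs.right)
    seqs = extract_peak_sequences(config["genome"], kept)

    sites: list[CompositeSite] = []
    peak_categories: dict[MergedPeak, str] = {}
    n_hits = 0
    for pk, seq in seqs:
        full_hits = threshold_by_fraction(scan(full_lom, "full", pk, seq), full_lom, th.score_fraction)
        left_hits = threshold_by_fraction(scan(left_lom, "left", pk, seq), left_lom, th.score_fraction)
        right_hits = threshold_by_fraction(scan(right_lom, "right", pk, seq), right_lom, th.score_fraction)
        n_hits += len(full_hits) + len(left_hits) + len(right_hits)
        pk_sites = call_sites_in_peak(pk, full_hits, left_hits, right_hits, th)
        sites.extend(pk_sites)
        peak_categories[pk] = assign_peak_category(pk, pk_sites)
    manifest["counts"]["thresholded_hits"] = n_hits
    manifest["counts"]["composite_sites"] = len(sites)
    cat_counts: dict[str, int] = {}
    for s in sites:
        cat_counts[s.category] = cat_counts.get(s.category, 0) + 1
    manifest["counts"]["sites_by_category"] = dict(sorted(cat_counts.items()))
    label_counts: dict[str, int] = {}
    for lbl in peak_categories.values():
        label_counts[lbl] = label_counts.get(lbl, 0) + 1
    manifest["counts"]["peaks_by_label"] = dict(sorted(label_counts.items()))
    manifest["seconds"]["scan_classify"] = round(time.perf_counter() - t0, 3)

    # --- optional annotation ---
    annotations: list[str] | None = None
    if config.get("gene_model"):
        t0 = stage("annotate")
        gm_path = Path(config["gene_model"])
        model: GeneModel = (
            read_transcripts_bed12(gm_path)
            if gm_path.suffix.lower() in (".bed", ".bed12")
            else read_transcripts_tsv(gm_path)
        )
        annotations = annotate_sites(sites, model, th)
        manifest["seconds"]["annotate"] = round(time.perf_counter() - t0, 3)

    # --- profile matrix + clustering ---
    t0 = stage("profile")
    prof_cfg = config.get("profile", {})
    experiments = [(e["experiment_id"], e["cell_line"]) for e in config["experiments"]]
    pm = build_profile_matrix(
        kept, peak_categories, experiments,
        drop_no_motif=prof_cfg.get("drop_no_motif", True),
    )
    if pm.values.shape[0] >= 2 and pm.values.shape[1] >= 2:
        pm = cluster_matrix(
            pm,
            metric=prof_cfg.get("metric", "euclidean"),
            method=prof_cfg.get("linkage", "complete"),
        )
    manifest["counts"]["profile_peaks"] = len(pm.peaks)
    summary = score_recurrence_summary(sites)
    manifest["seconds"]["profile"] = round(time.perf_counter() - t0, 3)

    # --- outputs ---
    write_merged_peaks(merged, out_dir / "merged_peaks.bed")
    write_merged_peaks(filtered, out_dir / "filtered_peaks.bed")
    write_merged_peaks(kept, out_dir / "kept_peaks.bed")
    with open(out_dir / "recurrence_histogram.tsv", "w") as fh:
        fh.write("recurrence\tn_peaks\n")
        for k, v in sorted(histogram.items()):
            fh.write(f"{k}\t{v}\n")
    write_sites(sites, out_dir / "composite_sites.bed")
    with open(out_dir / "peak_categories.tsv", "w") as fh:
        fh.write("peak\trecurrence\tlabel\n")
        for pk in kept:
            fh.write(f"{peak_name(pk)}\t{pk.recurrence}\t{peak_categories[pk]}\n")
    pm.write_tsv(out_dir / "profile_matrix.tsv")
    with open(out_dir / "row_order.txt", "w") as fh:
        fh.writelines(f"{i}\n" for i in pm.row_order)
    with open(out_dir / "col_order.txt", "w") as fh:
        fh.writelines(f"{i}\n" for i in pm.col_order)
    summary.drop(columns=["scores"]).to_csv(out_dir / "score_recurrence.tsv", sep="\t", index=False)
    if annotations is not None:
        write_annotations(sites, annotations, out_dir / "site_annotations.tsv")
    if config.get("plot_heatmap") and pm.values.size:
        plot_heatmap(pm, out_dir / "profile_heatmap.png")
    for p in sorted(out_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = str(p)

    # stage-count sanity
    counts = manifest["counts"]
    assert counts["peaks_after_exclusion"] <= counts["merged_peaks"]
    assert counts["peaks_after_recurrence_filter"] <= counts["peaks_after_exclusion"]

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        merged=merged, filtered=filtered, kept=kept, histogram=histogram,
        sites=sites, peak_categories=peak_categories, profile=pm,
        score_summary=summary, annotations=annotations, manifest=manifest,
    )


def config_for_simulation(sim_output, output_dir: str | Path, **extra) -> dict:
    """Pipeline config dict pointing at a :func:`simulate` output."""
    cfg = {
        "experiments": [
            {"path": str(p), "experiment_id": eid, "cell_line": cl}
            for eid, cl, p in sim_output.peak_files
        ],
        "exclusions": [str(sim_output.blacklist_path)],
        "genome": str(sim_output.genome_path),
        "motif": str(sim_output.motif_path),
        "output_dir": str(output_dir),
    }
    cfg.update(extra)
    return cfg
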