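"""End-to-end orchestration: simulate -> dF/F0 -> ROIs -> stats -> report.

A :class:`PipelineConfig` fully determines a run; identical configs produce
byte-identical CSV/JSON outputs.  Each drug group is simulated (or loaded),
processed per session, pooled into a group table, tested, and written out
with a manifest and a run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import session_io
from .dff import (DffStack, average_intervals, compute_dff, compute_f0,
                  subtract_background, whole_image_trace)
from .roi import (ProfileMetrics, RoiParams, RoiSet, detect_rois,
                  extract_traces, profile_metrics)
from .simulate import (KineticProfile, SensorGeometry, SessionRecording,
                       SimulationParams, SimulationTruth, simulate_session)
from .stats import GroupTimeSeries, build_group_table, rm_anova, significance_report

log = logging.getLogger("microdff")

__all__ = ["PipelineConfig", "SessionResult", "run_pipeline", "process_session",
           "run_drug_group", "compare_drugs"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run.

    ``image_interval_min`` (default 5) controls the averaged-image series;
    ``trace_interval_min`` (default 15) the binning of traces and of the
    group table fed to the ANOVA.
    """

    out_dir: str = "runs/demo"
    drugs: tuple[str, ...] = ("morphine", "cocaine", "saline")
    n_animals: int = 3
    seed: int = 1
    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    sim_fps: float = 0.2
    pre_min: float = 15.0
    post_min: float = 225.0
    baseline_window: tuple[float, float] = (-15.0, 0.0)
    background_level: float = 0.0
    image_interval_min: float = 5.0
    trace_interval_min: float = 15.0
    roi: RoiParams = field(default_factory=RoiParams)
    sim: dict = field(default_factory=dict)   # SimulationParams overrides
    posthoc: str = "pooled"
    adjust: str = "holm"
    save_stacks: bool = False
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.image_interval_min <= 0 or self.trace_interval_min <= 0:
            raise ValueError("interval widths must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        for d in self.drugs:
            KineticProfile.for_drug(d)  # raises for unknown drugs

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        if "geometry" in doc:
            doc["geometry"] = SensorGeometry(**doc["geometry"])
        if "roi" in doc:
            doc["roi"] = RoiParams(**doc["roi"])
        for key in ("drugs",):
            if key in doc:
                doc[key] = tuple(doc[key])
        for key in ("baseline_window",):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(session_io._jsonable(dataclasses.asdict(self)),
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def simulation_params(self, drug: str, seed: int) -> SimulationParams:
        return SimulationParams(
            geometry=self.geometry,
            kinetics=KineticProfile.for_drug(drug),
            pre_min=self.pre_min, post_min=self.post_min,
            sim_fps=self.sim_fps, seed=seed, **self.sim)


@dataclass
class SessionResult:
    """Everything one session contributes downstream."""

    animal_id: str
    drug: str
    seed: int | None
    dff: DffStack
    trace_labels: np.ndarray       # trace-interval end times
    trace_values: np.ndarray       # whole-image binned dF/F0 %
    rois: RoiSet
    trace_matrix: object           # RoiTraceMatrix
    metrics: ProfileMetrics
    truth: SimulationTruth | None = None


def process_session(recording: SessionRecording, config: PipelineConfig) -> DffStack:
    """Background subtraction, baseline, and per-pixel dF/F0."""
    rec = subtract_background(recording, config.background_level)
    f0 = compute_f0(rec, config.baseline_window)
    return compute_dff(rec, f0)


def analyze_session(recording: SessionRecording, config: PipelineConfig, *,
                    animal_id: str, drug: str, seed: int | None = None,
                    truth: SimulationTruth | None = None) -> SessionResult:
    dff = process_session(recording, config)
    series = average_intervals(dff, config.trace_interval_min, mode="trace")
    rois = detect_rois(dff, config.roi)
    matrix = extract_traces(dff, rois, config.trace_interval_min)
    metrics = profile_metrics(series.labels, series.values)
    return SessionResult(animal_id=animal_id, drug=drug, seed=seed, dff=dff,
                         trace_labels=series.labels, trace_values=series.values,
                         rois=rois, trace_matrix=matrix, metrics=metrics,
                         truth=truth)


def run_drug_group(config: PipelineConfig, drug: str,
                   seeds: list[int] | None = None) -> tuple[list[SessionResult], GroupTimeSeries, object]:
    """Simulate and analyse one drug group; return sessions, table, ANOVA."""
    if seeds is None:
        seeds = [config.seed + i for i in range(config.n_animals)]
    results = []
    for i, seed in enumerate(seeds):
        params = config.simulation_params(drug, seed)
        recording, truth = simulate_session(params)
        results.append(analyze_session(
            recording, config, animal_id=f"{drug}_{i + 1}", drug=drug,
            seed=seed, truth=truth))
    table = build_group_table(
        {r.animal_id: (r.trace_labels, r.trace_values) for r in results})
    anova = rm_anova(table, posthoc=config.posthoc, adjust=config.adjust)
    return results, table, anova


def group_mean_trace(results: list[SessionResult]) -> tuple[np.ndarray, np.ndarray]:
    labels = results[0].trace_labels
    for r in results[1:]:
        if not np.array_equal(r.trace_labels, labels):
            raise ValueError(f"session {r.animal_id} has mismatched interval labels")
    return labels, np.mean([r.trace_values for r in results], axis=0)


def compare_drugs(groups: dict[str, list[SessionResult]]) -> pd.DataFrame:
    """Side-by-side profile metrics of the group-mean whole-image traces."""
    widths = set()
    rows = {}
    for drug, results in groups.items():
        labels, mean_trace = group_mean_trace(results)
        widths.add(round(float(labels[1] - labels[0]), 9) if len(labels) > 1 else None)
        m = profile_metrics(labels, mean_trace)
        rows[drug] = {
            "peak_label_min": m.peak_label,
            "peak_dff_pct": m.peak_value,
            "half_rise_min": m.time_to_half_rise,
            "baseline_crossing_min": m.baseline_crossing,
            "undershoot_min_pct": m.undershoot_min,
        }
    if len(widths) > 1:
        raise ValueError(f"mismatched interval widths across groups: {widths}")
    frame = pd.DataFrame(rows).T
    frame.index.name = "drug"
    return frame


def _figures(drug: str, results: list[SessionResult], report: pd.DataFrame):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figs = {}
    rep = results[0]

    # ROI heatmap in the style of the representative-animal figure:
    # one intensity strip per numbered ROI plus the whole-image row W.
    mat = rep.trace_matrix
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.18 * len(mat.row_ids))))
    im = ax.imshow(mat.values, aspect="auto", cmap="viridis",
                   extent=[mat.labels[0] - (mat.labels[1] - mat.labels[0]),
                           mat.labels[-1], len(mat.row_ids) - 0.5, -0.5])
    ax.set_yticks(range(len(mat.row_ids)))
    ax.set_yticklabels(mat.row_ids, fontsize=6)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("ROI")
    fig.colorbar(im, ax=ax, label="dF/F0 (%)")
    ax.set_title(f"{drug}: ROI x time heatmap (representative session)")
    figs[f"{drug}_heatmap"] = fig

    # ROI outline overlay on the session-mean dF/F0 image.
    fig, ax = plt.subplots(figsize=(8, 4))
    mean_img = np.nanmean(rep.dff.values[rep.dff.timestamps > 0], axis=0)
    ax.imshow(mean_img, cmap="magma")
    for roi in rep.rois.rois:
        rr, cc = roi.centroid
        ax.annotate(str(roi.id), (cc, rr), color="w", fontsize=6, ha="center")
        ax.contour(roi.mask, levels=[0.5], colors="w", linewidths=0.5)
    ax.set_title(f"{drug}: detected ROIs over mean post-injection dF/F0")
    figs[f"{drug}_rois"] = fig

    # Group bar chart (mean +/- SD with significance stars).
    fig, ax = plt.subplots(figsize=(8, 3))
    xs = np.arange(len(report))
    ax.bar(xs, report["mean_dff_pct"], yerr=report["sd"], capsize=2,
           color="tab:blue")
    for x, (_, row) in zip(xs, report.iterrows()):
        if row["stars"]:
            ax.annotate(row["stars"], (x, row["mean_dff_pct"] + row["sd"]),
                        ha="center", fontsize=8)
    ax.set_xticks(xs)
    ax.set_xticklabels(report.index, rotation=90, fontsize=6)
    ax.set_ylabel("dF/F0 (%)")
    ax.set_title(f"{drug}: group mean per 15-min interval (n = {len(results)})")
    fig.tight_layout()
    figs[f"{drug}_group"] = fig
    return figs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every drug group and write all artifacts.

    Returns the run manifest (also written to ``<out_dir>/manifest.json``
    along with ``run_log.json`` recording the config hash, seeds, stage
    timings and package versions).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}
    records: dict[str, object] = {}
    figures: dict[str, object] = {}
    groups: dict[str, list[SessionResult]] = {}

    for drug in config.drugs:
        t0 = time.time()
        log.info("stage simulate+process: %s", drug)
        try:
            results, table, anova = run_drug_group(config, drug)
        except Exception as exc:
            raise RuntimeError(f"stage '{drug}' failed: {exc}") from exc
        groups[drug] = results
        report = significance_report(anova, table)

        labels, mean_trace = group_mean_trace(results)
        tables[f"{drug}_group_table"] = table.data
        tables[f"{drug}_group_report"] = report
        tables[f"{drug}_mean_trace"] = pd.DataFrame(
            {"time_min": labels, "dff_pct": mean_trace}).set_index("time_min")
        rep = results[0]
        tables[f"{drug}_heatmap"] = rep.trace_matrix.to_frame()
        records[f"{drug}_anova"] = anova
        records[f"{drug}_rois"] = rep.rois
        records[f"{drug}_profile"] = {
            r.animal_id: dataclasses.asdict(r.metrics) for r in results}
        if config.save_stacks:
            for r, seed in zip(results, [config.seed + i
                                         for i in range(config.n_animals)]):
                session_io.write_session(
                    simulate_session(config.simulation_params(drug, seed))[0],
                    out_dir / "sessions" / r.animal_id,
                    truth=r.truth)
        if config.make_figures:
            figures.update(_figures(drug, results, report))
        stage_times[drug] = time.time() - t0

    if len(groups) > 1:
        tables["drug_comparison"] = compare_drugs(groups)

    manifest = session_io.write_results(out_dir, tables=tables,
                                        records=records, figures=figures)
    run_log = {
        "config": session_io._jsonable(dataclasses.asdict(config)),
        "config_hash": config.config_hash(),
        "seeds": {d: [config.seed + i for i in range(config.n_animals)]
                  for d in config.drugs},
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "total_seconds": round(time.time() - t_start, 3),
        "versions": _versions(),
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1,
                                                     sort_keys=True))
    return manifest


def _versions() -> dict[str, str]:
    import matplotlib
    import scipy
    import skimage
    import tifffile

    import microdff
    return {"microdff": microdff.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
            "tifffile": tifffile.__version__,
            "matplotlib": matplotlib.__version__}
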