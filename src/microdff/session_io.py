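"""Reading and writing sessions, tables, and result artifacts.

Stacks travel as multi-page TIFF (one page per frame, float32 or uint16)
with a JSON sidecar holding geometry, timing, the injection convention and,
for simulated sessions, the ground truth.  Tabular results are CSV, result
objects JSON, figures PNG; every write is listed in a manifest with a
content hash so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import (
    KineticProfile,
    ReleaseSite,
    SensorGeometry,
    SessionRecording,
    SimulationParams,
    SimulationTruth,
)

__all__ = [
    "SessionMetadata",
    "read_session",
    "write_session",
    "read_truth",
    "write_results",
]

STACK_NAME = "stack.tif"
META_NAME = "session.json"


@dataclass(frozen=True)
class SessionMetadata:
    """Per-session sidecar metadata.

    Times are minutes relative to the injection (0 by convention);
    ``record_start_min`` is when the recording physically starts, so frame
    centres sit at ``record_start_min + (k + 0.5) / (60 * fps)``.
    """

    fps: float
    record_start_min: float
    injection_time: float = 0.0
    baseline_window: tuple[float, float] = (-15.0, 0.0)
    drug_label: str = ""
    animal_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        start, end = self.baseline_window
        if end <= start:
            raise ValueError("baseline_window end must exceed its start")
        if end > self.injection_time:
            raise ValueError(
                f"baseline_window end ({end}) must not exceed injection_time "
                f"({self.injection_time})")


def _geometry_dict(g: SensorGeometry) -> dict:
    return {"n_rows": g.n_rows, "n_cols": g.n_cols,
            "pixel_pitch": g.pixel_pitch, "fps": g.fps}


def _truth_dict(truth: SimulationTruth) -> dict:
    p = truth.params
    return {
        "sites": [dataclasses.asdict(s) for s in truth.sites],
        "kinetic_curve": [round(float(v), 9) for v in truth.kinetic_curve],
        "params": {
            "kinetics": dataclasses.asdict(p.kinetics) | {
                "drug_class": p.kinetics.drug_class.value},
            "n_sites": p.n_sites,
            "site_sigma_range": list(p.site_sigma_range),
            "site_gain_range": list(p.site_gain_range),
            "site_min_separation": p.site_min_separation,
            "site_edge_margin": p.site_edge_margin,
            "baseline_mean": p.baseline_mean,
            "illumination_gradient": p.illumination_gradient,
            "bleaching_tau": p.bleaching_tau,
            "read_noise_sd": p.read_noise_sd,
            "shot_noise_gain": p.shot_noise_gain,
            "background_coupling": p.background_coupling,
            "pre_min": p.pre_min,
            "post_min": p.post_min,
            "sim_fps": p.sim_fps,
            "seed": p.seed,
        },
    }


def write_session(recording: SessionRecording, out_dir, *,
                  metadata: SessionMetadata | None = None,
                  truth: SimulationTruth | None = None,
                  dtype: str = "float32") -> dict[str, Path]:
    """Write a session as ``stack.tif`` plus ``session.json``.

    ``dtype`` selects the TIFF page type (``float32`` or ``uint16``); float
    pages round-trip losslessly for float32-valued stacks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dtype not in ("float32", "uint16"):
        raise ValueError(f"dtype must be float32 or uint16, got {dtype!r}")
    frames = recording.frames.astype(dtype)
    stack_path = out_dir / STACK_NAME
    tifffile.imwrite(stack_path, frames, photometric="minisblack")

    fps = 1.0 / (60.0 * recording.frame_interval_min)
    if metadata is None:
        metadata = SessionMetadata(
            fps=fps,
            record_start_min=float(recording.timestamps[0]
                                   - 0.5 * recording.frame_interval_min),
            injection_time=recording.injection_time,
            drug_label=recording.label,
        )
    doc = {
        "format": "microdff-session/1",
        "dtype": dtype,
        "n_frames": recording.n_frames,
        "geometry": _geometry_dict(recording.geometry),
        "metadata": dataclasses.asdict(metadata),
        "timestamps_policy": "frame centers: record_start_min + (k + 0.5) / (60 * fps)",
    }
    if truth is not None:
        doc["truth"] = _truth_dict(truth)
    meta_path = out_dir / META_NAME
    meta_path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return {"stack": stack_path, "metadata": meta_path}


def _require(doc: dict, key: str, context: str):
    if key not in doc:
        raise ValueError(f"missing metadata key {key!r} in {context}")
    return doc[key]


def read_session(stack_path, metadata_path=None) -> tuple[SessionRecording, SessionMetadata]:
    """Load a session written by :func:`write_session`.

    ``stack_path`` may be the session directory.  Frames come back ordered
    by page index; timestamps are rebuilt from the sidecar timing fields.
    """
    stack_path = Path(stack_path)
    if stack_path.is_dir():
        metadata_path = metadata_path or stack_path / META_NAME
        stack_path = stack_path / STACK_NAME
    if metadata_path is None:
        metadata_path = stack_path.with_name(META_NAME)
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise FileNotFoundError(f"session metadata not found: {metadata_path}")

    doc = json.loads(metadata_path.read_text())
    with tifffile.TiffFile(stack_path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"ragged TIFF pages in {stack_path}: shapes {sorted(shapes)}")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]

    geom_doc = _require(doc, "geometry", str(metadata_path))
    for key in ("n_rows", "n_cols", "pixel_pitch", "fps"):
        _require(geom_doc, key, "geometry")
    geometry = SensorGeometry(**geom_doc)

    meta_doc = dict(_require(doc, "metadata", str(metadata_path)))
    for key in ("fps", "record_start_min"):
        _require(meta_doc, key, "metadata")
    if meta_doc.get("baseline_window") is not None:
        meta_doc["baseline_window"] = tuple(meta_doc["baseline_window"])
    metadata = SessionMetadata(**meta_doc)

    timestamps = (metadata.record_start_min
                  + (np.arange(frames.shape[0]) + 0.5) / (60.0 * metadata.fps))
    recording = SessionRecording(
        frames=np.asarray(frames, dtype=np.float64),
        timestamps=timestamps,
        geometry=geometry,
        injection_time=metadata.injection_time,
        label=metadata.drug_label,
    )
    return recording, metadata


def read_truth(session_dir) -> SimulationTruth:
    """Reconstruct the planted ground truth from a simulated session dir."""
    doc = json.loads((Path(session_dir) / META_NAME).read_text())
    tdoc = _require(doc, "truth", str(session_dir))
    pdoc = dict(tdoc["params"])
    kdoc = dict(pdoc.pop("kinetics"))
    geometry = SensorGeometry(**doc["geometry"])
    kinetics = KineticProfile(**kdoc)
    params = SimulationParams(
        geometry=geometry, kinetics=kinetics,
        site_sigma_range=tuple(pdoc.pop("site_sigma_range")),
        site_gain_range=tuple(pdoc.pop("site_gain_range")),
        **pdoc)
    sites = [ReleaseSite(**s) for s in tdoc["sites"]]
    return SimulationTruth(sites=sites,
                           kinetic_curve=np.asarray(tdoc["kinetic_curve"]),
                           params=params)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if hasattr(obj, "to_json_dict"):
        return obj.to_json_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def write_results(out_dir, *, tables: dict[str, pd.DataFrame] | None = None,
                  records: dict[str, object] | None = None,
                  figures: dict | None = None) -> dict[str, dict]:
    """Write CSV tables, JSON records and PNG figures; return the manifest.

    The manifest (also written to ``manifest.json``) maps artifact name to
    relative path and SHA-256, so identical inputs yield identical hashes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create results directory {out_dir}: {exc}") from exc

    manifest: dict[str, dict] = {}

    def register(name: str, path: Path) -> None:
        manifest[name] = {"path": path.name, "sha256": _sha256(path)}

    for name, frame in (tables or {}).items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, float_format="%.10g")
        register(name, path)
    for name, obj in (records or {}).items():
        path = out_dir / f"{name}.json"
        path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
        register(name, path)
    for name, fig in (figures or {}).items():
        path = out_dir / f"{name}.png"
        fig.savefig(path, dpi=150)
        register(name, path)

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
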