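"""Shared fixtures: default-scale drug triplets and small synthetic stacks.

The triplet fixtures run the full simulate -> dF/F0 -> ROI -> stats path at
the generator's default study conditions (40x90 sensor, 15 min pre /
225 min post at 0.2 frames/s, seeds 1-3) and are session-scoped so the
pipeline runs once per suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from microdff import (DffStack, PipelineConfig, SensorGeometry,
                      SimulationParams, run_drug_group)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig(seed=1, make_figures=False)


@pytest.fixture(scope="session")
def morphine_triplet(default_config):
    """(session results, group table, ANOVA) for morphine seeds 1-3."""
    return run_drug_group(default_config, "morphine")


@pytest.fixture(scope="session")
def cocaine_triplet(default_config):
    return run_drug_group(default_config, "cocaine")


@pytest.fixture
def small_geometry() -> SensorGeometry:
    return SensorGeometry(n_rows=12, n_cols=20)


def make_dff(values: np.ndarray, timestamps: np.ndarray,
             valid: np.ndarray | None = None) -> DffStack:
    """Build a DffStack directly from percent values (test helper)."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape[1:], dtype=bool)
    return DffStack(values=values, timestamps=np.asarray(timestamps, dtype=float),
                    valid_mask=valid)


def match_sites(truth_sites, rois, tol_px: float = 2.0) -> tuple[int, int]:
    """(matched planted sites, spurious detected ROIs) by nearest centroid."""
    centers = np.array([[s.center_row, s.center_col] for s in truth_sites])
    cents = np.array([r.centroid for r in rois.rois]).reshape(-1, 2)
    matched, used = 0, set()
    for s in centers:
        if len(cents):
            d = np.linalg.norm(cents - s, axis=1)
            j = int(np.argmin(d))
            if d[j] <= tol_px:
                matched += 1
                used.add(j)
    return matched, len(cents) - len(used)


def noiseless_params(drug: str = "morphine", seed: int = 0,
                     geometry: SensorGeometry | None = None,
                     **overrides) -> SimulationParams:
    """Default kinetics with noise, artifact and bleaching switched off."""
    from microdff import KineticProfile
    kin = KineticProfile.for_drug(drug, artifact_depth=0.0)
    kw = dict(kinetics=kin, read_noise_sd=0.0, shot_noise_gain=0.0,
              bleaching_tau=None, seed=seed)
    if geometry is not None:
        kw["geometry"] = geometry
    kw.update(overrides)
    return SimulationParams(**kw)
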