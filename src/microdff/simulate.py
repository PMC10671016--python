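"""Synthetic recording sessions for an implanted micro-CMOS dopamine sensor.

The generator emulates a needle-shaped CMOS imager (40x90 pixels, 7.5 um
pitch, excitation micro-LEDs above and below the array) recording dLight1.2
fluorescence in the nucleus accumbens while a mouse receives a subcutaneous
drug injection at t = 0.  Three pharmacological classes are modelled:

* ``morphine_like`` -- GABAergic disinhibition of VTA dopamine neurons: a
  slow Bateman (difference-of-exponentials) transient peaking tens of
  minutes post-injection, followed by a shallow late undershoot.
* ``cocaine_like`` -- dopamine-transporter blockade: a faster, larger
  transient with a sharper and deeper sub-baseline plateau once reuptake
  overcompensation sets in.
* ``saline`` -- no dopamine signal; only the injection-handling artifact.

Every session carries its ground truth (planted release sites and the
noiseless kinetic curve) so downstream detection and statistics can be
scored against what was actually planted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "DrugClass",
    "SensorGeometry",
    "KineticProfile",
    "ReleaseSite",
    "SimulationParams",
    "SessionRecording",
    "SimulationTruth",
    "field_dimensions",
    "kinetic_value",
    "bateman_peak_time",
    "simulate_session",
]


class DrugClass(str, enum.Enum):
    MORPHINE_LIKE = "morphine_like"
    COCAINE_LIKE = "cocaine_like"
    SALINE = "saline"


@dataclass(frozen=True)
class SensorGeometry:
    """Pixel layout of the implanted imager.

    Defaults match the fabricated device: 40 x 90 pixels at 7.5 um pitch
    (300 um x 675 um field) captured at 10 frames per second.
    """

    n_rows: int = 40
    n_cols: int = 90
    pixel_pitch: float = 7.5  # um
    fps: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be >= 1, got {self.n_rows}")
        if self.n_cols < 1:
            raise ValueError(f"n_cols must be >= 1, got {self.n_cols}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def field_dimensions(geometry: SensorGeometry) -> tuple[float, float]:
    """Physical imaging field (short axis, long axis) in micrometres."""
    return (geometry.n_rows * geometry.pixel_pitch,
            geometry.n_cols * geometry.pixel_pitch)


@dataclass(frozen=True)
class KineticProfile:
    """Drug-class kinetic template for the whole-session dF/F0 curve.

    The post-injection response is ``A * B(t) - U * S(t)`` where ``B`` is a
    Bateman difference of exponentials normalised to unit peak and ``S`` a
    logistic step switching on the sub-baseline undershoot.  An injection
    handling artifact subtracts ``artifact_depth`` inside a rectangular
    window of ``artifact_duration`` minutes straddling t = 0 (this is the
    one intentional discontinuity of the curve).
    """

    drug_class: DrugClass
    amplitude: float          # peak dF/F0 as a fraction (0.10 == 10 %)
    tau_rise: float           # min
    tau_decay: float          # min
    undershoot_depth: float   # dF/F0 fraction >= 0
    undershoot_onset: float   # min
    undershoot_sharpness: float  # min
    artifact_depth: float = 0.03     # dF/F0 fraction
    artifact_duration: float = 4.0   # min, window straddles t = 0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau_rise >= self.tau_decay:
            raise ValueError(
                f"tau_rise ({self.tau_rise}) must be < tau_decay ({self.tau_decay})")
        if self.undershoot_onset <= 0 or self.undershoot_sharpness <= 0:
            raise ValueError("undershoot time constants must be > 0")
        if self.undershoot_depth < 0:
            raise ValueError("undershoot_depth must be >= 0")
        if self.artifact_duration < 0:
            raise ValueError("artifact_duration must be >= 0")
        if self.drug_class is DrugClass.SALINE:
            if self.amplitude != 0 or self.undershoot_depth != 0:
                raise ValueError("saline requires amplitude = undershoot_depth = 0")

    @classmethod
    def morphine_like(cls, **overrides) -> "KineticProfile":
        kw = dict(drug_class=DrugClass.MORPHINE_LIKE, amplitude=0.10,
                  tau_rise=18.0, tau_decay=90.0, undershoot_depth=0.015,
                  undershoot_onset=150.0, undershoot_sharpness=20.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def cocaine_like(cls, **overrides) -> "KineticProfile":
        kw = dict(drug_class=DrugClass.COCAINE_LIKE, amplitude=0.12,
                  tau_rise=8.0, tau_decay=50.0, undershoot_depth=0.04,
                  undershoot_onset=130.0, undershoot_sharpness=8.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def saline(cls, **overrides) -> "KineticProfile":
        kw = dict(drug_class=DrugClass.SALINE, amplitude=0.0,
                  tau_rise=1.0, tau_decay=2.0, undershoot_depth=0.0,
                  undershoot_onset=1.0, undershoot_sharpness=1.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_drug(cls, drug: str, **overrides) -> "KineticProfile":
        key = drug.lower().replace("_like", "")
        factory = {"morphine": cls.morphine_like,
                   "cocaine": cls.cocaine_like,
                   "saline": cls.saline}.get(key)
        if factory is None:
            raise ValueError(f"unknown drug {drug!r}")
        return factory(**overrides)


def bateman_peak_time(profile: KineticProfile) -> float:
    """Closed-form argmax of the Bateman transient (minutes post-injection)."""
    tr, td = profile.tau_rise, profile.tau_decay
    return tr * td / (td - tr) * math.log(td / tr)


def kinetic_value(profile: KineticProfile, t):
    """Noiseless session-level dF/F0 fraction at time(s) ``t`` (minutes).

    Zero for t <= 0 and identically zero for saline, apart from the
    rectangular injection artifact on ``(-duration/2, duration/2]``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    if profile.amplitude != 0 and pos.any():
        tr, td = profile.tau_rise, profile.tau_decay
        tpk = bateman_peak_time(profile)
        norm = math.exp(-tpk / td) - math.exp(-tpk / tr)
        tp = t_arr[pos]
        out[pos] += profile.amplitude * (np.exp(-tp / td) - np.exp(-tp / tr)) / norm
    if profile.undershoot_depth != 0 and pos.any():
        s = expit((t_arr[pos] - profile.undershoot_onset) / profile.undershoot_sharpness)
        out[pos] -= profile.undershoot_depth * s
    if profile.artifact_duration > 0 and profile.artifact_depth != 0:
        half = profile.artifact_duration / 2.0
        out[(t_arr > -half) & (t_arr <= half)] -= profile.artifact_depth
    out = out.reshape(np.shape(t))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ReleaseSite:
    """A localised dopamine release region with a Gaussian spatial footprint."""

    center_row: float
    center_col: float
    sigma: float   # px
    gain: float    # multiplier on the session kinetic amplitude

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass(frozen=True)
class SimulationParams:
    """Everything needed to generate one session deterministically.

    ``sim_fps`` defaults to 0.2 (one frame per 5 s) so a full 15 + 225 min
    session stays desk-scale; the hardware rate (``geometry.fps`` = 10) is
    the upper bound.  Analysis code downstream is rate-agnostic.
    """

    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    kinetics: KineticProfile = field(default_factory=KineticProfile.morphine_like)
    n_sites: int = 12
    site_sigma_range: tuple[float, float] = (1.5, 3.0)
    site_gain_range: tuple[float, float] = (0.7, 1.3)
    site_min_separation: float = 12.0  # px between planted centres
    site_edge_margin: float = 4.0      # px kept clear of the sensor border
    baseline_mean: float = 1000.0      # counts (sensor DN)
    illumination_gradient: float = 0.10  # fractional drop across rows
    bleaching_tau: float | None = None   # min; None disables bleaching
    read_noise_sd: float = 5.0         # counts
    shot_noise_gain: float = 0.5       # counts of variance per count of signal
    background_coupling: float = 0.3   # kinetic fraction seen by every pixel
    pre_min: float = 15.0
    post_min: float = 225.0
    sim_fps: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pre_min <= 0 or self.post_min <= 0:
            raise ValueError("pre_min and post_min must be > 0")
        if self.sim_fps <= 0:
            raise ValueError("sim_fps must be > 0")
        if self.sim_fps > self.geometry.fps:
            raise ValueError(
                f"sim_fps ({self.sim_fps}) cannot exceed the sensor rate "
                f"({self.geometry.fps})")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.read_noise_sd < 0 or self.shot_noise_gain < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.illumination_gradient < 1:
            raise ValueError("illumination_gradient must lie in [0, 1)")
        if self.background_coupling < 0:
            raise ValueError("background_coupling must be >= 0")
        lo, hi = self.site_sigma_range
        if lo <= 0 or hi < lo:
            raise ValueError("site_sigma_range must be 0 < lo <= hi")
        lo, hi = self.site_gain_range
        if lo <= 0 or hi < lo:
            raise ValueError("site_gain_range must be 0 < lo <= hi")

    def with_(self, **overrides) -> "SimulationParams":
        return replace(self, **overrides)


@dataclass
class SessionRecording:
    """A raw frame stack with its timing and geometry metadata.

    ``timestamps`` are frame-centre times in minutes relative to the
    injection (negative = pre-injection), strictly increasing and uniformly
    spaced.
    """

    frames: np.ndarray            # (n_frames, n_rows, n_cols) counts, >= 0
    timestamps: np.ndarray        # min
    geometry: SensorGeometry
    injection_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, n_rows, n_cols) stack")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("frames and timestamps disagree on frame count")
        if self.frames.shape[1:] != self.geometry.shape:
            raise ValueError("frames do not match the stated sensor geometry")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frames must be >= 0")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_interval_min(self) -> float:
        if len(self.timestamps) > 1:
            return float(self.timestamps[1] - self.timestamps[0])
        return 1.0 / (60.0 * self.geometry.fps)


@dataclass
class SimulationTruth:
    """Ground truth carried alongside a simulated session."""

    sites: list[ReleaseSite]
    kinetic_curve: np.ndarray     # noiseless dF/F0 fraction per frame
    params: SimulationParams

    def coupling_map(self) -> np.ndarray:
        """Per-pixel kinetic coupling (site Gaussians + background)."""
        return _coupling_map(self.params, self.sites)


def _frame_times(params: SimulationParams) -> np.ndarray:
    """Frame-centre timestamps: floor(D*60*r) frames over the session."""
    rate_per_min = 60.0 * params.sim_fps
    n_frames = int(math.floor((params.pre_min + params.post_min) * rate_per_min))
    if n_frames < 1:
        raise ValueError("session too short for a single frame")
    return -params.pre_min + (np.arange(n_frames) + 0.5) / rate_per_min


def _baseline_image(params: SimulationParams) -> np.ndarray:
    rows = np.arange(params.geometry.n_rows, dtype=float)
    if params.geometry.n_rows > 1:
        drop = params.illumination_gradient * rows / (params.geometry.n_rows - 1)
    else:
        drop = np.zeros(1)
    profile = params.baseline_mean * (1.0 - drop)
    return np.repeat(profile[:, None], params.geometry.n_cols, axis=1)


def _place_sites(params: SimulationParams, rng: np.random.Generator) -> list[ReleaseSite]:
    """Uniform seeded placement with an edge margin and minimum separation."""
    n_rows, n_cols = params.geometry.shape
    m = min(params.site_edge_margin,
            (n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < params.n_sites:
        attempts += 1
        if attempts > 1000 * max(params.n_sites, 1):
            raise ValueError("could not place sites with the requested separation")
        r = rng.uniform(m, n_rows - 1 - m)
        c = rng.uniform(m, n_cols - 1 - m)
        if all(math.hypot(r - r0, c - c0) >= params.site_min_separation
               for r0, c0 in centers):
            centers.append((r, c))
    sites = []
    for r, c in centers:
        sigma = rng.uniform(*params.site_sigma_range)
        gain = rng.uniform(*params.site_gain_range)
        sites.append(ReleaseSite(center_row=r, center_col=c, sigma=sigma, gain=gain))
    return sites


def _coupling_map(params: SimulationParams, sites: list[ReleaseSite]) -> np.ndarray:
    n_rows, n_cols = params.geometry.shape
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    coupling = np.full((n_rows, n_cols), params.background_coupling, dtype=float)
    for s in sites:
        d2 = (rr - s.center_row) ** 2 + (cc - s.center_col) ** 2
        coupling += s.gain * np.exp(-d2 / (2.0 * s.sigma ** 2))
    return coupling


def simulate_session(params: SimulationParams) -> tuple[SessionRecording, SimulationTruth]:
    """Generate one seeded session.

    Pixel model: ``I(x, t) = B(x) * bleach(t) * (1 + c(x) * k(t)) + noise``
    where ``B`` is the illumination-graded baseline, ``c`` the coupling map,
    ``k`` the drug kinetic curve, and noise is Gaussian read noise plus a
    variance-proportional shot-like term.  Identical params (including the
    seed) produce bit-identical stacks.
    """
    rng = np.random.default_rng(params.seed)
    timestamps = _frame_times(params)
    baseline = _baseline_image(params)
    sites = _place_sites(params, rng)
    coupling = _coupling_map(params, sites)
    kinetic = kinetic_value(params.kinetics, timestamps)

    signal = baseline[None, :, :] * (1.0 + coupling[None, :, :] * kinetic[:, None, None])
    if params.bleaching_tau is not None:
        bleach = np.exp(-(timestamps - timestamps[0]) / params.bleaching_tau)
        signal *= bleach[:, None, None]

    frames = signal.copy()
    if params.read_noise_sd > 0:
        frames += rng.normal(0.0, params.read_noise_sd, size=signal.shape)
    if params.shot_noise_gain > 0:
        shot_sd = np.sqrt(params.shot_noise_gain * np.clip(signal, 0.0, None))
        frames += rng.standard_normal(signal.shape) * shot_sd
    np.clip(frames, 0.0, None, out=frames)

    recording = SessionRecording(
        frames=frames,
        timestamps=timestamps,
        geometry=params.geometry,
        injection_time=0.0,
        label=params.kinetics.drug_class.value,
    )
    truth = SimulationTruth(sites=sites, kinetic_curve=kinetic, params=params)
    return recording, truth
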