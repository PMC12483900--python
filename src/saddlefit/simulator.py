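"""Synthetic lower-limb cycling kinematics.

Generates per-ride joint-angle time series (hip/knee/ankle in the sagittal,
coronal and transverse planes) and a lateral-malleolus (RANK) marker
trajectory from a planar crank–pedal–leg linkage. The sagittal hip and knee
angles come from two-link law-of-cosines inverse kinematics driven by the
crank; the sagittal ankle angle follows a one-harmonic "ankling" model; the
six out-of-plane components are phenomenological sinusoids whose noise SD
grows with saddle height. Saddle height is expressed as a fraction of the
rider's greater trochanter height (GTH): 95% = low, 97–103% = moderate,
105% = high.

Crank phase convention: 0° at top dead center (TDC), increasing in the
pedaling direction, so bottom dead center (BDC) is 180°. Coordinates:
x forward, z up, bottom-bracket axis at ``bb_origin``; the saddle sits
behind and above the bottom bracket along the seat tube.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "ANGLE_COMPONENTS",
    "AnthropometricProfile",
    "RigGeometry",
    "SaddleLevel",
    "SimulationConfig",
    "SubjectStyle",
    "AnthropometrySampler",
    "KinematicRecording",
    "ReachabilityError",
    "pedal_position",
    "hip_position",
    "solve_leg_ik",
    "forward_leg_fk",
    "simulate_recording",
    "generate_cohort",
    "solve_saddle_for_bdc_knee_angle",
    "write_recording",
    "read_recording",
]

#: The nine angle components, named ``{plane symbol}_{joint}``:
#: theta = sagittal, beta = coronal, gamma = transverse.
ANGLE_COMPONENTS = [
    "theta_hip", "beta_hip", "gamma_hip",
    "theta_knee", "beta_knee", "gamma_knee",
    "theta_ankle", "beta_ankle", "gamma_ankle",
]

OFFPLANE_COMPONENTS = [c for c in ANGLE_COMPONENTS if not c.startswith("theta")]

#: Fixed per-component phase offsets (degrees) for the out-of-plane sinusoids,
#: so the six components are not mutually in phase.
_OFFPLANE_PHASES = {c: 55.0 * i for i, c in enumerate(OFFPLANE_COMPONENTS)}

LEVEL_NAMES = {1: "low", 2: "moderate", 3: "high"}


class ReachabilityError(ValueError):
    """The pedal is outside the leg's reachable annulus at some crank angle."""


@dataclass(frozen=True)
class AnthropometricProfile:
    """Per-subject segment lengths, in millimetres.

    ``greater_trochanter_height`` (GTH) is the standing height of the greater
    trochanter above the floor and serves as the saddle-height reference; it
    is not the sum of the modelled segments.
    """

    greater_trochanter_height: float
    thigh_length: float
    shank_length: float
    ankle_pedal_offset: float = 80.0
    subject_id: int = 1

    def __post_init__(self) -> None:
        for name in ("greater_trochanter_height", "thigh_length",
                     "shank_length", "ankle_pedal_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RigGeometry:
    """Bicycle geometry: crank length, saddle height along the seat tube
    (bottom-bracket axis to saddle top) and seat-tube angle from horizontal."""

    crank_length: float = 170.0
    saddle_height: float = 850.0
    seat_tube_angle: float = 73.0
    bb_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.crank_length < self.saddle_height:
            raise ValueError("require 0 < crank_length < saddle_height")
        if not 60.0 <= self.seat_tube_angle <= 80.0:
            raise ValueError("seat_tube_angle must be in [60, 80] degrees")


@dataclass(frozen=True)
class SaddleLevel:
    """Saddle-height class: 1 = low (0.95 GTH), 2 = moderate (0.97–1.03 GTH,
    drawn once per recording), 3 = high (1.05 GTH)."""

    level: int
    gth_fraction: float

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")
        lo, hi = {1: (0.95, 0.95), 2: (0.97, 1.03), 3: (1.05, 1.05)}[self.level]
        if not lo <= self.gth_fraction <= hi:
            raise ValueError(
                f"gth_fraction {self.gth_fraction} outside [{lo}, {hi}] "
                f"for level {self.level}")

    @property
    def name(self) -> str:
        return LEVEL_NAMES[self.level]

    @classmethod
    def low(cls) -> "SaddleLevel":
        return cls(1, 0.95)

    @classmethod
    def high(cls) -> "SaddleLevel":
        return cls(3, 1.05)

    @classmethod
    def moderate(cls, rng: np.random.Generator | None = None,
                 fraction: float | None = None) -> "SaddleLevel":
        if fraction is None:
            if rng is None:
                fraction = 1.0
            else:
                fraction = float(rng.uniform(0.97, 1.03))
        return cls(2, fraction)


@dataclass(frozen=True)
class SubjectStyle:
    """Per-subject idiosyncrasies that are constant across that subject's
    rides: ankling preferences and out-of-plane posture offsets."""

    ankle_mean_offset: float = 0.0
    ankle_amplitude_offset: float = 0.0
    offplane_mean_offsets: dict[str, float] = field(default_factory=dict)
    offplane_phase_offsets: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulated ride.

    The out-of-plane noise SD is ``offplane_sd_base +
    offplane_sd_slope * (gth_fraction - 1)``: riding high on the saddle
    makes the out-of-plane components noisier, riding low steadier. The
    sagittal ankle amplitude shrinks slightly with saddle height
    (``ankle_amplitude_slope`` per unit gth_fraction).

    ``sagittal_cycle_sd`` / ``offplane_cycle_sd`` model cycle-to-cycle
    posture variability: each cycle draws one offset per component that
    shifts that whole cycle, on top of the per-sample measurement noise.
    """

    cadence_rpm: float = 80.0
    cadence_jitter_sd: float = 1.0
    n_cycles: int = 30
    sample_rate: float = 250.0
    sagittal_noise_sd: float = 1.0
    sagittal_cycle_sd: float = 1.5
    offplane_cycle_sd: float = 1.0
    ankle_mean: float = 10.0
    ankle_amplitude: float = 15.0
    ankle_phase_deg: float = 210.0
    ankle_mean_slope: float = 15.0
    ankle_amplitude_slope: float = -12.0
    offplane_mean: float = 5.0
    offplane_amplitude: float = 2.0
    offplane_sd_base: float = 1.0
    offplane_sd_slope: float = 6.5
    rank_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("cadence_jitter_sd", "sagittal_noise_sd",
                     "sagittal_cycle_sd", "offplane_cycle_sd",
                     "offplane_sd_base", "rank_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cadence_rpm <= 0:
            raise ValueError("cadence_rpm must be positive")


@dataclass(frozen=True)
class AnthropometrySampler:
    """Cohort anthropometry distribution: GTH ~ Normal(mean, sd) truncated at
    ±2 SD; thigh and shank are fixed ratios of GTH with multiplicative
    Gaussian noise on the ratio.

    The two links are *effective* lengths: the distal link folds the foot
    lever (ankle-to-pedal, plantarflexed at bottom dead center) into the
    shank, which is why the ratios sum to more than 1 — a saddle at
    0.95–1.05 GTH plus a crank is only reachable through the foot.
    """

    gth_mean: float = 880.0
    gth_sd: float = 45.0
    thigh_ratio: float = 0.64
    shank_ratio: float = 0.60
    ratio_noise: float = 0.02
    ankle_pedal_offset: float = 80.0

    def draw(self, subject_id: int, rng: np.random.Generator) -> AnthropometricProfile:
        z = rng.normal()
        while abs(z) > 2.0:
            z = rng.normal()
        gth = self.gth_mean + self.gth_sd * z
        thigh = self.thigh_ratio * gth * (1.0 + self.ratio_noise * rng.normal())
        shank = self.shank_ratio * gth * (1.0 + self.ratio_noise * rng.normal())
        return AnthropometricProfile(
            greater_trochanter_height=gth, thigh_length=thigh,
            shank_length=shank, ankle_pedal_offset=self.ankle_pedal_offset,
            subject_id=subject_id)


@dataclass
class KinematicRecording:
    """One ride: nine joint-angle series, the RANK marker trajectory and
    metadata. ``angles`` has columns ``time_s`` plus the nine component
    names; ``rank`` has ``time_s, x_mm, y_mm, z_mm``."""

    angles: pd.DataFrame
    rank: pd.DataFrame
    subject_id: int
    saddle_level: SaddleLevel
    true_saddle_height: float
    sample_rate: float

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.rank):
            raise ValueError("angle and RANK series must have equal length")

    @property
    def label(self) -> int:
        return self.saddle_level.level


# ---------------------------------------------------------------------------
# geometry

def pedal_position(crank_angle: np.ndarray | float, rig: RigGeometry) -> np.ndarray:
    """Pedal spindle position for a crank angle measured from TDC.

    ``point = bb_origin + crank_length * (sin(phi), cos(phi))`` so TDC (0°)
    puts the pedal straight above the bottom bracket and BDC (180°) straight
    below. Returns shape (..., 2) in mm.
    """
    phi = np.deg2rad(np.asarray(crank_angle, dtype=float))
    bx, bz = rig.bb_origin
    return np.stack(
        [bx + rig.crank_length * np.sin(phi), bz + rig.crank_length * np.cos(phi)],
        axis=-1)


def hip_position(rig: RigGeometry) -> np.ndarray:
    """Hip joint position: up the seat tube from the bottom bracket, behind
    it in x (x forward, z up)."""
    a = np.deg2rad(rig.seat_tube_angle)
    bx, bz = rig.bb_origin
    return np.array([bx - rig.saddle_height * np.cos(a),
                     bz + rig.saddle_height * np.sin(a)])


def solve_leg_ik(pedal_point: np.ndarray, hip_point: np.ndarray,
                 profile: AnthropometricProfile,
                 crank_angle: np.ndarray | float | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Two-link inverse kinematics: (hip_flexion, knee_flexion) in degrees.

    The ankle joint sits ``ankle_pedal_offset`` vertically above the pedal
    point. Knee flexion is 0° for a straight leg; hip flexion is the thigh's
    angle from the straight-down trunk reference, positive forward. The
    knee-forward solution branch is always chosen.

    Raises :class:`ReachabilityError` when the hip–ankle distance leaves the
    annulus ``|thigh − shank| < d <= thigh + shank``; ``crank_angle`` (if
    given) is named in the message.
    """
    t, s = profile.thigh_length, profile.shank_length
    pedal = np.asarray(pedal_point, dtype=float)
    ankle = pedal + np.array([0.0, profile.ankle_pedal_offset])
    v = ankle - np.asarray(hip_point, dtype=float)
    d = np.linalg.norm(v, axis=-1)

    eps = 1e-9
    too_far = d > t + s + eps
    too_close = d <= abs(t - s) + eps
    if np.any(too_far) or np.any(too_close):
        bad = too_far | too_close
        where = ""
        if crank_angle is not None:
            phi = np.broadcast_to(np.asarray(crank_angle, float), np.shape(d))
            where = f" at crank angle {float(np.atleast_1d(phi[bad])[0]):.1f} deg"
        kind = "beyond full extension" if np.any(too_far) else "degenerate (too close)"
        raise ReachabilityError(
            f"pedal unreachable{where}: hip-ankle distance "
            f"{float(np.atleast_1d(d[bad])[0]):.1f} mm is {kind} for thigh "
            f"{t:.1f} + shank {s:.1f} mm")

    cos_knee = np.clip((t * t + s * s - d * d) / (2.0 * t * s), -1.0, 1.0)
    knee_flexion = 180.0 - np.degrees(np.arccos(cos_knee))
    # angle of the hip->ankle line from straight-down, positive toward +x
    phi_v = np.degrees(np.arctan2(v[..., 0], -v[..., 1]))
    cos_hip = np.clip((t * t + d * d - s * s) / (2.0 * t * d), -1.0, 1.0)
    hip_flexion = phi_v + np.degrees(np.arccos(cos_hip))
    return hip_flexion, knee_flexion


def forward_leg_fk(hip_point: np.ndarray, hip_flexion: np.ndarray,
                   knee_flexion: np.ndarray, profile: AnthropometricProfile,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics of the planar leg; returns (knee_point, ankle_point).

    Inverse of :func:`solve_leg_ik` on the knee-forward branch: the thigh
    leaves the hip at ``hip_flexion`` from straight-down and the shank is
    rotated back from the thigh line by ``knee_flexion``.
    """
    hip_flexion = np.asarray(hip_flexion, float)
    knee_flexion = np.asarray(knee_flexion, float)
    hip_point = np.asarray(hip_point, float)

    def unit(angle_deg: np.ndarray) -> np.ndarray:
        a = np.deg2rad(angle_deg)
        return np.stack([np.sin(a), -np.cos(a)], axis=-1)

    knee = hip_point + profile.thigh_length * unit(hip_flexion)
    ankle = knee + profile.shank_length * unit(hip_flexion - knee_flexion)
    return knee, ankle


def check_reachable(profile: AnthropometricProfile, rig: RigGeometry,
                    n_grid: int = 720) -> None:
    """Raise :class:`ReachabilityError` if any crank angle is unreachable."""
    phi = np.linspace(0.0, 360.0, n_grid, endpoint=False)
    solve_leg_ik(pedal_position(phi, rig), hip_position(rig), profile,
                 crank_angle=phi)


# ---------------------------------------------------------------------------
# simulation

def _phase_timeline(config: SimulationConfig, rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crank phase per sample with half-cycle lead-in/out padding so every
    TDC z-maximum (n_cycles + 1 of them) is interior to the record.

    Returns (time_s, phase_deg in [0, 360), cycle_id per sample). The
    lead-in shares the first cycle's id and the lead-out the last's.
    """
    fs = config.sample_rate
    nominal_t = 60.0 / config.cadence_rpm
    if config.cadence_jitter_sd > 0:
        jitter = rng.normal(0.0, config.cadence_jitter_sd, size=config.n_cycles)
    else:
        jitter = np.zeros(config.n_cycles)
    cadences = np.clip(config.cadence_rpm + jitter, 10.0, None)
    durations = 60.0 / cadences

    segments, ids = [], []
    # lead-in: last half of a nominal cycle, ending at the first TDC; long
    # enough that zero-lag filter edge transients stay clear of the peaks
    n_lead = max(int(round(nominal_t / 2 * fs)), 2)
    segments.append(180.0 + 180.0 * np.arange(n_lead) / n_lead)
    ids.append(np.zeros(n_lead, dtype=int))
    for c, dur in enumerate(durations):
        n = max(int(round(dur * fs)), 2)
        segments.append(360.0 * np.arange(n) / n)
        ids.append(np.full(n, c, dtype=int))
    n_out = max(int(round(nominal_t / 2 * fs)), 2)
    segments.append(180.0 * np.arange(n_out + 1) / n_out)
    ids.append(np.full(n_out + 1, config.n_cycles - 1, dtype=int))
    phase = np.concatenate(segments)
    time_s = np.arange(phase.size) / fs
    return time_s, np.mod(phase, 360.0), np.concatenate(ids)


def simulate_recording(profile: AnthropometricProfile, rig: RigGeometry,
                       level: SaddleLevel, config: SimulationConfig,
                       style: SubjectStyle | None = None) -> KinematicRecording:
    """Simulate one ride at a given saddle level.

    ``rig.saddle_height`` must equal ``level.gth_fraction *
    profile.greater_trochanter_height``. Reachability over the whole cycle is
    verified before any output is produced. Identical arguments (including
    ``config.seed``) give an identical recording.
    """
    expected = level.gth_fraction * profile.greater_trochanter_height
    if abs(rig.saddle_height - expected) > 1e-6 * expected:
        raise ValueError(
            f"rig.saddle_height {rig.saddle_height:.2f} != gth_fraction x GTH "
            f"= {expected:.2f}")
    check_reachable(profile, rig)
    style = style or SubjectStyle()
    rng = np.random.default_rng(
        [int(config.seed), int(profile.subject_id), int(level.level)])

    time_s, phase, cycle_id = _phase_timeline(config, rng)
    hip = hip_position(rig)
    pedal = pedal_position(phase, rig)
    theta_hip, theta_knee = solve_leg_ik(pedal, hip, profile, crank_angle=phase)

    def cycle_offsets(sd: float) -> np.ndarray:
        """One offset per cycle, broadcast to samples via cycle_id."""
        if sd <= 0:
            return np.zeros(phase.size)
        return rng.normal(0.0, sd, size=config.n_cycles)[cycle_id]

    dfrac = level.gth_fraction - 1.0
    ankle_mean = (config.ankle_mean + style.ankle_mean_offset
                  + config.ankle_mean_slope * dfrac)
    ankle_amp = max(config.ankle_amplitude + style.ankle_amplitude_offset
                    + config.ankle_amplitude_slope * dfrac, 0.0)
    theta_ankle = ankle_mean + ankle_amp * np.sin(
        np.deg2rad(phase + config.ankle_phase_deg))

    def noise(sd: float) -> np.ndarray:
        return rng.normal(0.0, sd, size=phase.size) if sd > 0 else 0.0

    series = {
        "theta_hip": theta_hip + cycle_offsets(config.sagittal_cycle_sd)
        + noise(config.sagittal_noise_sd),
        "theta_knee": theta_knee + cycle_offsets(config.sagittal_cycle_sd)
        + noise(config.sagittal_noise_sd),
        "theta_ankle": theta_ankle + cycle_offsets(config.sagittal_cycle_sd)
        + noise(config.sagittal_noise_sd),
    }
    offplane_sd = max(config.offplane_sd_base + config.offplane_sd_slope * dfrac, 0.0)
    for comp in OFFPLANE_COMPONENTS:
        mean_c = config.offplane_mean + style.offplane_mean_offsets.get(comp, 0.0)
        phase_c = _OFFPLANE_PHASES[comp] + style.offplane_phase_offsets.get(comp, 0.0)
        series[comp] = (mean_c
                        + config.offplane_amplitude
                        * np.sin(np.deg2rad(phase + phase_c))
                        + cycle_offsets(config.offplane_cycle_sd)
                        + noise(offplane_sd))

    angles = pd.DataFrame({"time_s": time_s,
                           **{c: series[c] for c in ANGLE_COMPONENTS}})

    # RANK marker rides on the ankle joint (pedal + vertical offset); small
    # mediolateral sway in y plus marker noise.
    ankle_xz = pedal + np.array([0.0, profile.ankle_pedal_offset])
    rank = pd.DataFrame({
        "time_s": time_s,
        "x_mm": ankle_xz[:, 0] + noise(config.rank_noise_sd),
        "y_mm": 5.0 * np.sin(np.deg2rad(phase)) + noise(config.rank_noise_sd),
        "z_mm": ankle_xz[:, 1] + noise(config.rank_noise_sd),
    })
    return KinematicRecording(
        angles=angles, rank=rank, subject_id=profile.subject_id,
        saddle_level=level, true_saddle_height=rig.saddle_height,
        sample_rate=config.sample_rate)


def _draw_style(rng: np.random.Generator) -> SubjectStyle:
    return SubjectStyle(
        ankle_mean_offset=float(rng.normal(0.0, 3.0)),
        ankle_amplitude_offset=float(rng.normal(0.0, 0.3)),
        offplane_mean_offsets={c: float(rng.normal(0.0, 2.0))
                               for c in OFFPLANE_COMPONENTS},
        offplane_phase_offsets={c: float(rng.normal(0.0, 15.0))
                                for c in OFFPLANE_COMPONENTS},
    )


def generate_cohort(n_subjects: int, config: SimulationConfig,
                    sampler: AnthropometrySampler | None = None,
                    rig_template: RigGeometry | None = None,
                    max_retries: int = 20) -> list[KinematicRecording]:
    """Simulate a cohort: one anthropometric profile per subject and three
    rides each (low, moderate, high saddle). Subject ids run 1..n.

    Profiles whose geometry cannot reach the pedal at the high saddle are
    re-drawn (with a warning) up to ``max_retries`` times.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    sampler = sampler or AnthropometrySampler()
    rig_template = rig_template or RigGeometry()
    rng = np.random.default_rng([int(config.seed), 7770])

    recordings: list[KinematicRecording] = []
    for sid in range(1, n_subjects + 1):
        profile = None
        for attempt in range(max_retries):
            candidate = sampler.draw(sid, rng)
            try:
                rig_high = replace(
                    rig_template,
                    saddle_height=1.05 * candidate.greater_trochanter_height)
                check_reachable(candidate, rig_high)
            except ReachabilityError:
                import warnings
                warnings.warn(
                    f"subject {sid}: drawn anthropometry unreachable at high "
                    f"saddle (attempt {attempt + 1}); resampling")
                continue
            profile = candidate
            break
        if profile is None:
            raise ReachabilityError(
                f"could not sample reachable anthropometry for subject {sid} "
                f"after {max_retries} attempts")
        style = _draw_style(rng)
        levels = [SaddleLevel.low(), SaddleLevel.moderate(rng), SaddleLevel.high()]
        for level in levels:
            rig = replace(rig_template,
                          saddle_height=level.gth_fraction
                          * profile.greater_trochanter_height)
            recordings.append(
                simulate_recording(profile, rig, level, config, style))
    return recordings


def solve_saddle_for_bdc_knee_angle(profile: AnthropometricProfile,
                                    rig: RigGeometry, target: float,
                                    tol: float = 0.01) -> float:
    """Saddle height (mm) at which the noiseless knee flexion at BDC equals
    ``target`` degrees, the classical static bike-fit rule (25–35° at BDC).

    Bisection on the monotone saddle-height → BDC-knee-flexion map; raises
    with the attainable range when the target cannot be met.
    """
    if not 0.0 < target < 90.0:
        raise ValueError("target must be in (0, 90) degrees")

    def bdc_knee(height: float) -> float:
        r = replace(rig, saddle_height=height)
        pedal = pedal_position(180.0, r)
        _, knee = solve_leg_ik(pedal, hip_position(r), profile,
                               crank_angle=180.0)
        return float(knee)

    # bracket: the highest saddle keeping BDC reachable, down to just above
    # the crank
    lo = rig.crank_length + 1.0
    hi = lo
    step = (profile.thigh_length + profile.shank_length + rig.crank_length)
    # binary search for the largest reachable height at BDC
    low_ok, high_bad = lo, lo + step
    while high_bad - low_ok > 1e-6:
        mid = 0.5 * (low_ok + high_bad)
        try:
            bdc_knee(mid)
            low_ok = mid
        except ReachabilityError:
            high_bad = mid
    hi = low_ok

    k_lo, k_hi = bdc_knee(lo), bdc_knee(hi)  # k_lo large (bent), k_hi ~ 0
    if not (min(k_lo, k_hi) <= target <= max(k_lo, k_hi)):
        raise ValueError(
            f"target {target:.2f} deg outside attainable BDC knee-flexion "
            f"range [{min(k_lo, k_hi):.2f}, {max(k_lo, k_hi):.2f}] deg for "
            f"this geometry")
    height = brentq(lambda h: bdc_knee(h) - target, lo, hi, xtol=1e-4)
    assert abs(bdc_knee(height) - target) <= tol
    return float(height)


# ---------------------------------------------------------------------------
# CSV round trip

def _recording_dirname(rec: KinematicRecording) -> str:
    return f"subject_{rec.subject_id:02d}_{rec.saddle_level.name}"


def write_recording(rec: KinematicRecording, out_dir: str | Path) -> Path:
    """Write ``angles.csv``, ``rank.csv`` and ``manifest.yaml`` under
    ``out_dir/subject_XX_level/``; returns the directory."""
    d = Path(out_dir) / _recording_dirname(rec)
    d.mkdir(parents=True, exist_ok=True)
    rec.angles.to_csv(d / "angles.csv", index=False)
    rec.rank.to_csv(d / "rank.csv", index=False)
    manifest = {
        "subject_id": int(rec.subject_id),
        "level": int(rec.saddle_level.level),
        "gth_fraction": float(rec.saddle_level.gth_fraction),
        "saddle_height_mm": float(rec.true_saddle_height),
        "sample_rate": float(rec.sample_rate),
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return d


def read_recording(rec_dir: str | Path) -> KinematicRecording:
    d = Path(rec_dir)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    level = SaddleLevel(int(manifest["level"]), float(manifest["gth_fraction"]))
    return KinematicRecording(
        angles=pd.read_csv(d / "angles.csv"),
        rank=pd.read_csv(d / "rank.csv"),
        subject_id=int(manifest["subject_id"]),
        saddle_level=level,
        true_saddle_height=float(manifest["saddle_height_mm"]),
        sample_rate=float(manifest["sample_rate"]),
    )
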