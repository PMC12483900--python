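"""Cycle segmentation of cycling recordings.

The RANK (right lateral malleolus) marker's vertical coordinate peaks once
per crank revolution at top dead center; the interval between two adjacent
z-maxima is one pedaling cycle. The trajectory is low-pass filtered with a
zero-lag (forward–backward) 4th-order Butterworth at 6 Hz before peak
detection. Outlier cycles are excluded on cycle-duration and
angle-plausibility rules, and each kept cycle gets a linear 0–360° crank
phase anchored at its starting z-maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from saddlefit.simulator import ANGLE_COMPONENTS, KinematicRecording

log = logging.getLogger(__name__)

__all__ = [
    "CycleIndex",
    "AngleCycle",
    "lowpass_zero_lag",
    "detect_cycles",
    "exclude_outlier_cycles",
    "assign_crank_phase",
    "segment_recording",
]


@dataclass(frozen=True)
class CycleIndex:
    """Half-open sample interval [start_sample, end_sample) of one cycle."""

    start_sample: int
    end_sample: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("end_sample must exceed start_sample")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class AngleCycle:
    """One pedaling cycle: the nine angle series sliced to the cycle, the
    per-sample crank phase in [0, 360), and its provenance."""

    angles: pd.DataFrame
    crank_phase: np.ndarray
    subject_id: int
    label: int
    cycle_ordinal: int

    def __post_init__(self) -> None:
        missing = [c for c in ANGLE_COMPONENTS if c not in self.angles.columns]
        if missing:
            raise ValueError(f"missing angle components: {missing}")
        if len(self.angles) != len(self.crank_phase):
            raise ValueError("crank_phase length must match the angle slice")


def lowpass_zero_lag(signal: np.ndarray, sample_rate: float,
                     cutoff: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-lag low-pass: an order-``order`` Butterworth applied forward and
    backward, so the phase shift cancels and the magnitude response is
    squared (|H(cutoff)|^2 = 1/2)."""
    x = np.asarray(signal, dtype=float)
    if sample_rate <= 2.0 * cutoff:
        raise ValueError("sample_rate must exceed twice the cutoff")
    b, a = butter(order, cutoff, btype="low", fs=sample_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise ValueError(
            f"signal length {x.size} too short for zero-lag filtering "
            f"(needs > {padlen} samples)")
    return filtfilt(b, a, x)


def detect_cycles(rank_z: np.ndarray, sample_rate: float,
                  min_cadence: float = 30.0, max_cadence: float = 130.0,
                  prominence_frac: float = 0.10) -> list[CycleIndex]:
    """Pedaling cycles as intervals between adjacent z-coordinate maxima.

    Peaks must be separated by at least one revolution at ``max_cadence``
    and rise by at least ``prominence_frac`` of the signal's peak-to-peak
    range, which rejects sub-revolution ripple. Fewer than two maxima yields
    an empty list (with a warning).
    """
    z = np.asarray(rank_z, dtype=float)
    ptp = float(np.ptp(z)) if z.size else 0.0
    if ptp == 0.0:
        warnings.warn("constant RANK z signal: no cycles detected")
        return []
    distance = max(int(round(60.0 / max_cadence * sample_rate)), 1)
    peaks, _ = find_peaks(z, distance=distance, prominence=prominence_frac * ptp)
    if peaks.size < 2:
        warnings.warn(f"only {peaks.size} z-maxima found: no complete cycle")
        return []
    cycles = [
        CycleIndex(int(a), int(b), (int(b) - int(a)) / sample_rate)
        for a, b in zip(peaks[:-1], peaks[1:])
    ]
    max_dur = 60.0 / min_cadence
    return [c for c in cycles if c.duration_s <= max_dur]


def exclude_outlier_cycles(cycles: list[CycleIndex], angles: pd.DataFrame,
                           duration_tol: float = 0.20,
                           angle_bound: float = 200.0,
                           ) -> tuple[list[CycleIndex], list[dict]]:
    """Drop implausible cycles; returns (kept, exclusion report).

    A cycle is excluded iff its duration deviates from the median cycle
    duration by more than ``duration_tol`` (fractional), or any angle sample
    inside it exceeds ``angle_bound`` degrees in magnitude. The result does
    not depend on the order of ``cycles``.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    median = float(np.median([c.duration_s for c in cycles]))
    comp = angles[ANGLE_COMPONENTS].to_numpy()
    kept, report = [], []
    for c in cycles:
        reason = None
        if abs(c.duration_s - median) > duration_tol * median:
            reason = (f"duration {c.duration_s:.3f}s deviates more than "
                      f"{duration_tol:.0%} from median {median:.3f}s")
        else:
            window = comp[c.start_sample:c.end_sample]
            if window.size and np.abs(window).max() > angle_bound:
                reason = (f"angle magnitude {np.abs(window).max():.1f} deg "
                          f"exceeds bound {angle_bound:.0f} deg")
        if reason is None:
            kept.append(c)
        else:
            report.append({"start_sample": c.start_sample,
                           "end_sample": c.end_sample, "reason": reason})
            log.info("excluded cycle [%d, %d): %s",
                     c.start_sample, c.end_sample, reason)
    if not kept:
        raise ValueError("all cycles excluded as outliers")
    return kept, report


def assign_crank_phase(cycle: CycleIndex) -> np.ndarray:
    """Linear crank phase over the cycle: ``360 * i / n`` for the i-th of n
    samples, 0° at the starting z-maximum, strictly below 360°."""
    n = cycle.n_samples
    if n < 2:
        raise ValueError("cycle must span at least 2 samples")
    return 360.0 * np.arange(n) / n


def segment_recording(rec: KinematicRecording, cutoff: float = 6.0,
                      duration_tol: float = 0.20, angle_bound: float = 200.0,
                      filter_angles: bool = False,
                      min_cadence: float = 30.0, max_cadence: float = 130.0,
                      ) -> tuple[list[AngleCycle], list[dict]]:
    """Full preprocessing of one recording: filter the RANK z trajectory,
    detect cycles, drop outliers, slice the angle series and attach crank
    phase. Set ``filter_angles`` to also low-pass the angle series before
    slicing. Returns (cycles, exclusion report)."""
    z = lowpass_zero_lag(rec.rank["z_mm"].to_numpy(), rec.sample_rate, cutoff)
    idx = detect_cycles(z, rec.sample_rate, min_cadence, max_cadence)
    if not idx:
        return [], []
    angles = rec.angles
    if filter_angles:
        angles = angles.copy()
        for comp in ANGLE_COMPONENTS:
            angles[comp] = lowpass_zero_lag(
                angles[comp].to_numpy(), rec.sample_rate, cutoff)
    kept, report = exclude_outlier_cycles(idx, angles, duration_tol, angle_bound)
    out = []
    for ordinal, c in enumerate(kept):
        out.append(AngleCycle(
            angles=angles.iloc[c.start_sample:c.end_sample].reset_index(drop=True),
            crank_phase=assign_crank_phase(c),
            subject_id=rec.subject_id,
            label=rec.saddle_level.level,
            cycle_ordinal=ordinal,
        ))
    return out, report
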