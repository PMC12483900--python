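"""Per-cycle joint-angle statistics.

Each pedaling cycle yields 81 features: 9 statistics × 3 joints (hip, knee,
ankle) × 3 planes (theta = sagittal, beta = coronal, gamma = transverse).
The statistics are Max, Min, the crank angles at which they occur
(maxTiming, minTiming, 0–360°), RMS, Mean, sample SD, CV (= SD / |Mean|)
and ROM (= Max − Min). Feature columns are named
``{plane}_{joint}_{stat}``, e.g. ``theta_knee_Max``.

Feature tables are normalized column-wise by the maximum absolute value,
either of the table itself or of a reference (training) table, so signed
angles stay within [−1, 1] on the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from saddlefit.preprocess import AngleCycle
from saddlefit.simulator import ANGLE_COMPONENTS

log = logging.getLogger(__name__)

STAT_NAMES = ["Max", "Min", "maxTiming", "minTiming",
              "RMS", "Mean", "SD", "CV", "ROM"]

#: The 81 feature names, grouped joint-major (hip, knee, ankle), plane
#: (theta, beta, gamma), statistic.
FEATURE_NAMES: list[str] = [
    f"{plane}_{joint}_{stat}"
    for joint in ("hip", "knee", "ankle")
    for plane in ("theta", "beta", "gamma")
    for stat in STAT_NAMES
]

__all__ = [
    "STAT_NAMES",
    "FEATURE_NAMES",
    "FeatureTable",
    "summarize_component",
    "extract_features",
    "build_feature_table",
    "normalize_columns",
]


def summarize_component(series: np.ndarray, crank_phase: np.ndarray) -> dict[str, float]:
    """The nine statistics of one angle component over one cycle.

    Timing statistics are the crank phase at the (first, on ties) extreme
    sample. RMS is computed on the signed values; SD uses the n−1
    denominator; CV = SD / |Mean| and is NaN (logged) when |Mean| < 1e-9.
    """
    x = np.asarray(series, dtype=float)
    phase = np.asarray(crank_phase, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size != phase.size:
        raise ValueError("series and crank_phase must have equal length")
    imax, imin = int(np.argmax(x)), int(np.argmin(x))
    mx, mn = float(x[imax]), float(x[imin])
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if abs(mean) < 1e-9:
        log.warning("near-zero mean: CV undefined, reporting NaN")
        cv = float("nan")
    else:
        cv = sd / abs(mean)
    return {
        "Max": mx,
        "Min": mn,
        "maxTiming": float(phase[imax]),
        "minTiming": float(phase[imin]),
        "RMS": float(np.sqrt(np.mean(x * x))),
        "Mean": mean,
        "SD": sd,
        "CV": cv,
        "ROM": mx - mn,
    }


def extract_features(cycle: AngleCycle) -> pd.Series:
    """All 81 statistics of one cycle, indexed by ``FEATURE_NAMES``."""
    values: dict[str, float] = {}
    for comp in ANGLE_COMPONENTS:
        if comp not in cycle.angles.columns:
            raise ValueError(f"missing angle component: {comp}")
        stats = summarize_component(cycle.angles[comp].to_numpy(),
                                    cycle.crank_phase)
        for stat, v in stats.items():
            values[f"{comp}_{stat}"] = v
    return pd.Series([values[name] for name in FEATURE_NAMES],
                     index=FEATURE_NAMES, dtype=float)


@dataclass
class FeatureTable:
    """Cycle-level feature matrix with class labels and subject ids.

    ``X`` has exactly the 81 feature columns; ``y`` holds saddle-height
    classes (1 = low, 2 = moderate, 3 = high); ``scales`` is None for a raw
    table or the per-column max-|.| divisors applied to normalize it.
    """

    X: pd.DataFrame
    y: np.ndarray
    subjects: np.ndarray
    scales: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.X.columns) != FEATURE_NAMES:
            raise ValueError("feature columns must be the 81 canonical names")
        n = len(self.X)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if len(self.y) != n or len(self.subjects) != n:
            raise ValueError("y and subjects must have one entry per row")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def is_normalized(self) -> bool:
        return self.scales is not None

    def to_csv(self, path: str | Path, scales_path: str | Path | None = None) -> None:
        df = self.X.copy()
        df["label"] = self.y
        df["subject_id"] = self.subjects
        df.to_csv(path, index=False)
        if self.scales is not None and scales_path is not None:
            Path(scales_path).write_text(yaml.safe_dump(
                {k: float(v) for k, v in self.scales.items()}, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path,
                 scales_path: str | Path | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        scales = None
        if scales_path is not None and Path(scales_path).exists():
            scales = pd.Series(yaml.safe_load(Path(scales_path).read_text()))
            scales = scales.reindex(FEATURE_NAMES)
        return cls(X=df[FEATURE_NAMES], y=df["label"].to_numpy(),
                   subjects=df["subject_id"].to_numpy(), scales=scales)


def build_feature_table(cycles: list[AngleCycle]) -> FeatureTable:
    """Extract features from every cycle and stack them into a raw table."""
    if not cycles:
        raise ValueError("no cycles to extract features from")
    rows = [extract_features(c) for c in cycles]
    X = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureTable(
        X=X[FEATURE_NAMES],
        y=np.array([c.label for c in cycles], dtype=int),
        subjects=np.array([c.subject_id for c in cycles], dtype=int),
    )


def normalize_columns(table: FeatureTable,
                      reference: FeatureTable | None = None) -> FeatureTable:
    """Divide each column by its maximum absolute value in ``reference``
    (default: the table itself), so reference values land in [−1, 1].

    The divisors are stored on the result; applying a stored scale vector to
    new data via ``reference`` scaling is exact. A column whose reference
    max-|.| is zero raises, naming the column.
    """
    ref = reference if reference is not None else table
    if ref.scales is not None and ref is not table:
        # a distinct (training) reference: its stored factors live in the
        # raw domain and apply verbatim to new raw data
        scales = ref.scales
    else:
        scales = ref.X.abs().max(axis=0)
    zero = scales.index[(scales == 0) | scales.isna()]
    if len(zero):
        raise ValueError(f"cannot normalize zero/NaN max-abs column(s): "
                         f"{list(zero)}")
    return FeatureTable(X=table.X / scales, y=table.y.copy(),
                        subjects=table.subjects.copy(), scales=scales.copy())
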