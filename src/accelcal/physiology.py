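"""Criterion measures: resting VO2 (REE), VO2net, MET and equivalent speed."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

GRAVITY = 9.81  # m s^-2, fixed by convention

#: Calibration-study age bands per group.
CALIBRATION_AGE_BANDS = {"children": (9, 11), "adolescents": (14, 16), "adults": (23, 44)}

#: Treadmill protocol stages and speeds (km/h); rest and stand carry speed 0.
STAGE_SPEEDS_KMH = {
    "rest": 0.0,
    "stand": 0.0,
    "walk3": 3.0,
    "walk4": 4.0,
    "walk5": 5.0,
    "walk6": 6.0,
    "run8": 8.0,
    "run10": 10.0,
}
MOVING_STAGES = ("walk3", "walk4", "walk5", "walk6", "run8", "run10")


@dataclass
class SubjectProfile:
    subject_id: str
    age: float
    age_group: str  # children | adolescents | adults
    height_m: float
    weight_kg: float
    sex: str = "NA"

    def __post_init__(self) -> None:
        if not 0.5 < self.height_m < 2.5:
            raise DataError(f"implausible height {self.height_m} m")
        if self.weight_kg <= 0:
            raise DataError("weight must be positive")
        if self.age_group not in CALIBRATION_AGE_BANDS:
            raise DataError(f"unknown age group {self.age_group!r}")


@dataclass
class VO2Trace:
    """Absolute oxygen consumption over time with per-sample stage labels."""

    time_s: np.ndarray
    vo2_ml_min: np.ndarray
    stage: np.ndarray  # str labels from STAGE_SPEEDS_KMH

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.vo2_ml_min = np.asarray(self.vo2_ml_min, dtype=float)
        self.stage = np.asarray(self.stage)
        if np.any(np.diff(self.time_s) <= 0):
            raise DataError("time must be strictly increasing")
        if np.any(self.vo2_ml_min <= 0):
            raise DataError("VO2 must be positive")

    def stage_slice(self, label: str) -> "VO2Trace":
        m = self.stage == label
        if not m.any():
            raise DataError(f"stage {label!r} missing from trace")
        return VO2Trace(self.time_s[m], self.vo2_ml_min[m], self.stage[m])


def kmh_to_ms(speed_kmh: float) -> float:
    """Exact km/h -> m/s conversion."""
    return speed_kmh / 3.6


def compute_ree(trace: VO2Trace, window_s: float = 120.0, grid_s: float = 5.0) -> float:
    """Minimum of the ``window_s`` moving average of the resting trace.

    The trace is linearly resampled onto a regular ``grid_s`` grid first
    (breath-by-breath irregularity is not modelled otherwise); the moving
    mean is evaluated over every full window on that grid.
    """
    rest = trace.stage_slice("rest") if (trace.stage == "rest").any() else trace
    t, v = rest.time_s, rest.vo2_ml_min
    if t[-1] - t[0] < window_s:
        raise DataError(f"rest trace spans {t[-1] - t[0]:.0f}s < window {window_s}s")
    grid = np.arange(t[0], t[-1] + 1e-9, grid_s)
    vg = np.interp(grid, t, v)
    w = int(round(window_s / grid_s))
    means = np.convolve(vg, np.ones(w) / w, mode="valid")
    return float(means.min())


def compute_met(vo2_gross: float, vo2_rest: float) -> float:
    """MET = gross / resting oxygen consumption."""
    if vo2_rest <= 0:
        raise DataError("resting VO2 must be positive")
    return vo2_gross / vo2_rest


def compute_vo2net(vo2_gross: float, vo2_stand: float, weight_kg: float) -> float:
    """(VO2gross - VO2stand) / weight, in mL/min/kg.

    May be negative for sub-standing activities; callers decide exclusion.
    """
    if weight_kg <= 0:
        raise DataError("weight must be positive")
    return (vo2_gross - vo2_stand) / weight_kg


def is_substanding(vo2_net: float) -> bool:
    """Flag for activities below standing energy cost (negative net VO2)."""
    return vo2_net < 0


def compute_speed_eq(speed_ms: float, height_m: float) -> float:
    """Dimensionless (Froude-type) equivalent speed V^2 / (g h)."""
    if height_m <= 0:
        raise ConfigError("height must be positive")
    if speed_ms < 0:
        raise ConfigError("speed must be non-negative")
    return speed_ms ** 2 / (GRAVITY * height_m)


def stage_vo2_means(trace: VO2Trace, window: tuple[float, float] = (165.0, 225.0)
                    ) -> dict[str, float]:
    """Steady-state window mean of VO2 for stand and each moving stage."""
    from .signal_processing import calibration_window

    out: dict[str, float] = {}
    for label in ("stand",) + MOVING_STAGES:
        if not (trace.stage == label).any():
            continue
        sub = trace.stage_slice(label)
        out[label] = calibration_window(sub.time_s, sub.vo2_ml_min,
                                        stage_start=sub.time_s[0], window=window)
    return out
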