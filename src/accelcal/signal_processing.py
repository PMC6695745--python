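"""Raw triaxial acceleration -> band-pass-filtered mg intensity per epoch.

The processing chain is: resample to the target rate, truncate to the clip
limit, band-pass filter each axis (zero phase), then aggregate the vector
norm of the filtered signal into fixed-length epochs expressed in milli-g.
ENMO (Euclidean norm minus one, negatives clipped) is provided as a
comparison metric computed from the *unfiltered* signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Union

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, DataError, InvalidBandError, UpsamplingError

TimeLike = Union[float, pd.Timestamp]

#: Default band-pass corner frequencies (Hz).
DEFAULT_BAND = (0.29, 10.0)
#: Default processing rate (Hz) and clip limit (g).
DEFAULT_RATE = 30.0
DEFAULT_CLIP_G = 6.0


@dataclass
class TriaxialRecording:
    """Equal-length x/y/z acceleration traces in units of g.

    ``start_time`` is either a local wall-clock timestamp or elapsed seconds
    from a session origin (lab protocols use the latter).
    """

    subject_id: str
    placement: str  # "hip" | "thigh"
    sample_rate: float
    start_time: TimeLike
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise DataError("x, y, z must have equal length")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.isnan(a).any():
                raise DataError(f"NaN samples in axis {name}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.x) / self.sample_rate

    def axes(self) -> np.ndarray:
        """(n, 3) view of the three axes."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class EpochSeries:
    """Per-epoch intensity (milli-g) with parallel wear flags.

    ``times`` holds the start of every epoch; after filtering operations
    (night exclusion, subsetting) the series is no longer contiguous, so
    explicit per-epoch times are kept rather than a single origin.
    """

    epoch_length: float  # seconds
    times: np.ndarray  # epoch start times (float seconds or datetime64[ns])
    intensity: np.ndarray  # mg
    wear: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wear is None:
            self.wear = np.ones(len(self.intensity), dtype=bool)
        self.wear = np.asarray(self.wear, dtype=bool)
        if len(self.times) != len(self.intensity) or len(self.wear) != len(self.intensity):
            raise DataError("times, intensity and wear must have equal length")
        if not 1 <= self.epoch_length <= 60:
            raise ConfigError("epoch_length must be in [1, 60] s")
        if np.any(self.intensity < -1e-9):
            raise DataError("negative epoch intensity")

    @classmethod
    def regular(cls, start_time: TimeLike, epoch_length: float,
                intensity: np.ndarray, wear: np.ndarray | None = None) -> "EpochSeries":
        """Build a contiguous series starting at ``start_time``."""
        n = len(intensity)
        if isinstance(start_time, (int, float)):
            times = np.asarray(start_time) + epoch_length * np.arange(n)
        else:
            origin = pd.Timestamp(start_time)
            times = (origin + pd.to_timedelta(epoch_length * np.arange(n), unit="s")).values
        return cls(epoch_length, times, np.asarray(intensity, float), wear)

    @property
    def start_time(self):
        return self.times[0] if len(self.times) else None

    def __len__(self) -> int:
        return len(self.intensity)

    def subset(self, mask: np.ndarray) -> "EpochSeries":
        return EpochSeries(self.epoch_length, self.times[mask],
                           self.intensity[mask], self.wear[mask])


def resample(rec: TriaxialRecording, target_rate: float) -> TriaxialRecording:
    """Anti-aliased polyphase resampling to ``target_rate`` (down only)."""
    if target_rate > rec.sample_rate:
        raise UpsamplingError(
            f"cannot upsample {rec.sample_rate} Hz to {target_rate} Hz")
    if target_rate == rec.sample_rate:
        return rec
    frac = Fraction(target_rate / rec.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    new = {ax: sps.resample_poly(getattr(rec, ax), up, down) for ax in "xyz"}
    return replace(rec, sample_rate=target_rate, **new)


def truncate(rec: TriaxialRecording, limit: float = DEFAULT_CLIP_G) -> TriaxialRecording:
    """Clip every axis into [-limit, +limit] g."""
    if limit <= 0:
        raise ConfigError("clip limit must be positive")
    return replace(rec, x=np.clip(rec.x, -limit, limit),
                   y=np.clip(rec.y, -limit, limit),
                   z=np.clip(rec.z, -limit, limit))


def design_bandpass(low: float, high: float, sample_rate: float) -> np.ndarray:
    """4th-order Butterworth band-pass in SOS form (two poles per skirt)."""
    nyq = sample_rate / 2.0
    if not 0 < low < high:
        raise InvalidBandError("need 0 < low < high")
    if high >= nyq:
        raise InvalidBandError(
            f"high corner {high} Hz >= Nyquist {nyq} Hz")
    return sps.butter(2, [low / nyq, high / nyq], btype="bandpass", output="sos")


def bandpass(rec: TriaxialRecording, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> TriaxialRecording:
    """Zero-phase (forward-backward) band-pass of each axis independently."""
    sos = design_bandpass(low, high, rec.sample_rate)
    new = {ax: sps.sosfiltfilt(sos, getattr(rec, ax)) for ax in "xyz"}
    return replace(rec, **new)


def _epoch_starts(rec: TriaxialRecording, epoch_length: float, n_epochs: int):
    if isinstance(rec.start_time, (int, float)):
        return np.asarray(rec.start_time) + epoch_length * np.arange(n_epochs)
    origin = pd.Timestamp(rec.start_time)
    return (origin + pd.to_timedelta(epoch_length * np.arange(n_epochs), unit="s")).values


def epoch_mg(rec: TriaxialRecording, epoch_length: float = 3.0) -> EpochSeries:
    """Mean per-epoch Euclidean norm of the (filtered) signal, in milli-g.

    The recording is expected to be truncated and band-pass filtered
    already. A trailing partial epoch is dropped, never padded.
    """
    spe = int(round(epoch_length * rec.sample_rate))
    if spe < 2:
        raise ConfigError(
            f"epoch of {epoch_length}s at {rec.sample_rate} Hz has <2 samples")
    n_epochs = len(rec) // spe
    norm = np.sqrt(rec.x ** 2 + rec.y ** 2 + rec.z ** 2)
    vals = norm[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1) * 1000.0
    return EpochSeries(epoch_length, _epoch_starts(rec, epoch_length, n_epochs), vals)


def epoch_enmo(rec: TriaxialRecording, epoch_length: float = 3.0) -> EpochSeries:
    """Euclidean-norm-minus-one metric on the *raw* (gravity-bearing) signal.

    Per sample max(||v|| - 1, 0); epoch value is the mean in milli-g.
    """
    spe = int(round(epoch_length * rec.sample_rate))
    if spe < 2:
        raise ConfigError("epoch shorter than 2 samples")
    n_epochs = len(rec) // spe
    enmo = np.maximum(np.sqrt(rec.x ** 2 + rec.y ** 2 + rec.z ** 2) - 1.0, 0.0)
    vals = enmo[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1) * 1000.0
    return EpochSeries(epoch_length, _epoch_starts(rec, epoch_length, n_epochs), vals)


#: Steady-state window relative to a stage start: [2:45, 3:45).
STAGE_WINDOW = (165.0, 225.0)


def calibration_window(times_s: np.ndarray, values: np.ndarray,
                       stage_start: float = 0.0,
                       window: tuple[float, float] = STAGE_WINDOW) -> float:
    """Mean of samples with stage-relative time in the steady-state window.

    ``times_s`` are elapsed seconds on the same clock as ``stage_start``;
    the window is half-open [start, end).
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    rel = times_s - stage_start
    lo, hi = window
    if rel.max() < hi - 1e-9:
        raise DataError(
            f"stage ends at {rel.max():.1f}s; window extends to {hi}s")
    mask = (rel >= lo) & (rel < hi)
    if not mask.any():
        raise DataError("no samples inside the steady-state window")
    return float(values[mask].mean())
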