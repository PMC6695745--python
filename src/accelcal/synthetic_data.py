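"""Synthetic lab-protocol and free-living data with known ground truth.

The generating model encodes the structural assumptions the analysis is
built to detect, so pipeline recovery of them is a meaningful test:

* hip mg vs absolute speed follows one shared power curve across groups;
* thigh mg is inflated in younger (shorter) groups via a group scale;
* net VO2 is a single shared linear function of equivalent speed
  (``vo2net = A * speed_eq``), identical across groups;
* MET separates groups because resting VO2 per kg declines with age;
* consequently mg cut-points at fixed net VO2 are ordered
  children < adolescents < adults.

All group differences are configuration parameters, never hard-coded, so
"no group difference" null configurations are available for falsification.

Raw lab signals are synthesized as three phase-balanced sinusoids (phases
0/120/240 degrees) riding on 1 g of gravity: the vector norm of the
band-passed carrier is constant, so the post-filter epoch intensity equals
the target curve value exactly once the amplitude is pre-compensated by the
processing chain's measured gain at the carrier frequency. The signal stage
is thereby exercised, not bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ConfigError
from .physiology import (GRAVITY, MOVING_STAGES, STAGE_SPEEDS_KMH,
                         SubjectProfile, VO2Trace, kmh_to_ms)
from .signal_processing import (EpochSeries, TriaxialRecording, bandpass,
                                epoch_mg, resample, truncate)
from .calibration import LEVELS, MET_CUTPOINTS

STATES = ("SED", "LPA", "MPA", "VPA", "VVPA")


# --------------------------------------------------------------------------
# configuration blocks
# --------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Per-age-group anthropometry and metabolic parameters."""

    n: int = 10
    age_range: tuple[float, float] = (23, 44)
    height_mean: float = 1.78
    height_sd: float = 0.04
    weight_mean: float = 75.0
    weight_sd: float = 8.0
    vo2rest_per_kg_mean: float = 2.90  # mL/min/kg
    vo2rest_per_kg_sd: float = 0.10
    thigh_scale: float = 1.0  # thigh mg inflation (internal limb work)


@dataclass
class SignalParams:
    """mg-vs-speed generating curves and raw-signal synthesis settings."""

    hip_coef: float = 139.4  # mg at 1 m/s, tuned so adult MPA lands near 167 mg
    hip_power: float = 2.2
    thigh_coef: float = 230.7
    thigh_power: float = 2.054
    stand_mg: float = 7.0
    carrier_hz: float = 2.0  # inside the pass band
    sample_rate: float = 100.0

    def mg_at_speed(self, speed_ms: float, placement: str,
                    thigh_scale: float = 1.0) -> float:
        if speed_ms <= 0:
            return self.stand_mg
        if placement == "hip":
            return self.hip_coef * speed_ms ** self.hip_power
        return thigh_scale * self.thigh_coef * speed_ms ** self.thigh_power


@dataclass
class MetabolicParams:
    """Shared net-VO2 model and oxygen-uptake kinetics."""

    vo2net_per_speedeq: float = 81.5  # mL/min/kg per unit equivalent speed
    stand_ratio: float = 1.103  # standing / resting VO2
    rise_tau_s: float = 30.0  # kinetics time constant
    rise_settle_s: float = 150.0  # plateau reached exactly here
    rest_elev_frac: float = 0.08  # initial settling elevation above true rest
    rest_tau_s: float = 240.0
    rest_settle_s: float = 1050.0  # resting floor reached exactly here
    vo2_bin_s: float = 5.0
    rest_duration_s: float = 1200.0
    stage_duration_s: float = 240.0


@dataclass
class NoiseParams:
    vo2_rel_sd: float = 0.02  # multiplicative, per 5-s bin
    mg_rel_sd: float = 0.03  # multiplicative, per subject x stage (log-normal)


@dataclass
class ActivityProfile:
    """Semi-Markov free-living behaviour for one reporting category."""

    transition: np.ndarray  # 5x5, rows sum to 1, order = STATES
    dwell_mean_s: tuple[float, ...] = (300.0, 120.0, 90.0, 45.0, 30.0)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (5, 5):
            raise ConfigError("transition matrix must be 5x5")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ConfigError("transition matrix rows must sum to 1")
        if any(d <= 0 for d in self.dwell_mean_s):
            raise ConfigError("dwell means must be positive")


def _uniform_rows(p: tuple[float, ...]) -> np.ndarray:
    """Transition matrix whose every row is the state probability vector."""
    p = np.asarray(p, dtype=float)
    return np.tile(p / p.sum(), (5, 1))


@dataclass
class FreeLivingParams:
    n_days: int = 7
    epoch_length: float = 3.0
    start: str = "2024-05-06 00:00:00"
    night: tuple[int, int] = (23, 6)
    nonwear_bouts_per_day: float = 1.5
    nonwear_bout_minutes: tuple[float, float] = (60.0, 100.0)
    vvpa_band_top: float = 1.3  # VVPA emission band: [cut, top*cut)
    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "children": 10, "adolescents": 10, "adults_lt50": 10, "adults_ge50": 10})
    age_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "children": (4, 12), "adolescents": (13, 16),
        "adults_lt50": (21, 49), "adults_ge50": (50, 67)})
    profiles: dict[str, ActivityProfile] = field(default_factory=lambda: {
        "children": ActivityProfile(_uniform_rows((0.42, 0.26, 0.21, 0.07, 0.04))),
        "adolescents": ActivityProfile(_uniform_rows((0.55, 0.25, 0.15, 0.03, 0.02))),
        "adults_lt50": ActivityProfile(_uniform_rows((0.68, 0.22, 0.09, 0.007, 0.003)),
                                       (400.0, 120.0, 60.0, 30.0, 20.0)),
        "adults_ge50": ActivityProfile(_uniform_rows((0.72, 0.20, 0.07, 0.007, 0.003)),
                                       (400.0, 120.0, 60.0, 30.0, 20.0)),
    })


@dataclass
class GeneratorConfig:
    """Complete, seeded description of a synthetic study."""

    seed: int
    groups: dict[str, GroupParams] = field(default_factory=lambda: {
        "children": GroupParams(age_range=(9, 11), height_mean=1.45,
                                height_sd=0.04, weight_mean=38.0, weight_sd=4.0,
                                vo2rest_per_kg_mean=4.34, vo2rest_per_kg_sd=0.12,
                                thigh_scale=1.35),
        "adolescents": GroupParams(age_range=(14, 16), height_mean=1.68,
                                   height_sd=0.04, weight_mean=60.0, weight_sd=6.0,
                                   vo2rest_per_kg_mean=3.52, vo2rest_per_kg_sd=0.11,
                                   thigh_scale=1.12),
        "adults": GroupParams(),
    })
    signal: SignalParams = field(default_factory=SignalParams)
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    free_living: FreeLivingParams = field(default_factory=FreeLivingParams)
    target_rate: float = 30.0
    band: tuple[float, float] = (0.29, 10.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def expected_met(self, group: str, speed_kmh: float) -> float:
        """MET at group-mean parameters (generator calibration check)."""
        g = self.groups[group]
        seq = kmh_to_ms(speed_kmh) ** 2 / (GRAVITY * g.height_mean)
        net = self.metabolic.vo2net_per_speedeq * seq
        return self.metabolic.stand_ratio + net / g.vo2rest_per_kg_mean


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    """A simulated participant plus their generating parameters."""

    profile: SubjectProfile
    vo2rest_per_kg: float
    thigh_scale: float

    @property
    def vo2rest_ml_min(self) -> float:
        return self.vo2rest_per_kg * self.profile.weight_kg

    def vo2stand_ml_min(self, stand_ratio: float) -> float:
        return stand_ratio * self.vo2rest_ml_min


@dataclass
class GroundTruth:
    """Generator-side truth used as the parameter-recovery oracle."""

    vo2net_cutpoints: dict[str, float]
    mg_cutpoints: dict[tuple[str, str, str], dict[str, float]]
    subjects: list[SyntheticSubject] = field(default_factory=list)
    free_living: dict[str, dict] = field(default_factory=dict)  # sid -> arrays


# --------------------------------------------------------------------------
# cohort & lab session
# --------------------------------------------------------------------------

def simulate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> list[SyntheticSubject]:
    """Reproducible calibration cohort (default 10 per age group)."""
    rng = config.rng() if rng is None else rng
    out = []
    for group in ("children", "adolescents", "adults"):
        gp = config.groups[group]
        for i in range(gp.n):
            height = gp.height_mean + gp.height_sd * rng.standard_normal()
            weight = max(15.0, gp.weight_mean + gp.weight_sd * rng.standard_normal())
            rpk = max(1.0, gp.vo2rest_per_kg_mean
                      + gp.vo2rest_per_kg_sd * rng.standard_normal())
            age = rng.uniform(*gp.age_range)
            sid = f"{group[:2]}{i + 1:02d}"
            prof = SubjectProfile(sid, float(age), group, float(height),
                                  float(weight), sex=("F" if i % 2 else "M"))
            out.append(SyntheticSubject(prof, float(rpk), gp.thigh_scale))
    return out


@lru_cache(maxsize=8)
def _pipeline_gain(sample_rate: float, target_rate: float,
                   low: float, high: float, carrier_hz: float) -> float:
    """Measured end-to-end vector-norm gain of resample+band-pass at the carrier.

    A unit-amplitude phase-balanced probe is pushed through the same chain
    the pipeline applies; the interior vector-norm plateau (sqrt(3/2) times
    the per-axis gain) is returned, so a per-axis amplitude of
    ``target / gain`` yields a post-filter norm of exactly ``target``.
    """
    t = np.arange(int(60 * sample_rate)) / sample_rate
    phases = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    axes = [np.sin(2 * np.pi * carrier_hz * t + ph) for ph in phases]
    rec = TriaxialRecording("probe", "hip", sample_rate, 0.0, *axes)
    rec = bandpass(resample(rec, target_rate), low, high)
    norm = np.sqrt(rec.x ** 2 + rec.y ** 2 + rec.z ** 2)
    interior = norm[int(20 * target_rate): int(40 * target_rate)]
    return float(interior.mean())


def _balanced_carrier(t: np.ndarray, amp: np.ndarray, carrier_hz: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three sinusoids 120 degrees apart: vector norm == amp * sqrt(3/2)."""
    w = 2 * np.pi * carrier_hz
    return (amp * np.sin(w * t),
            amp * np.sin(w * t + 2 * np.pi / 3),
            amp * np.sin(w * t + 4 * np.pi / 3))


def lab_stage_schedule(config: GeneratorConfig) -> list[tuple[str, float, float]]:
    """(stage, start_s, end_s) on the session clock; rest starts at 0."""
    met = config.metabolic
    sched = [("rest", 0.0, met.rest_duration_s)]
    t = met.rest_duration_s
    for stage in ("stand",) + MOVING_STAGES:
        sched.append((stage, t, t + met.stage_duration_s))
        t += met.stage_duration_s
    return sched


def _stage_rise(rel_t: np.ndarray, prev: float, plateau: float,
                tau: float, settle: float) -> np.ndarray:
    """Mono-exponential rise scaled to reach the plateau exactly at ``settle``."""
    if tau <= 0:
        return np.full_like(rel_t, plateau)
    frac = np.minimum((1 - np.exp(-rel_t / tau)) / (1 - np.exp(-settle / tau)), 1.0)
    return prev + (plateau - prev) * frac


def simulate_lab_session(subject: SyntheticSubject, config: GeneratorConfig,
                         rng: np.random.Generator
                         ) -> tuple[dict[str, TriaxialRecording], VO2Trace]:
    """One treadmill session: hip & thigh raw recordings plus the VO2 trace.

    The accelerometer recordings start at the stand stage (session clock
    ``start_time`` in elapsed seconds); the VO2 trace covers the 20-min rest
    as well.
    """
    met, sig, noise = config.metabolic, config.signal, config.noise
    sched = lab_stage_schedule(config)
    vo2stand = subject.vo2stand_ml_min(met.stand_ratio)
    h = subject.profile.height_m
    w = subject.profile.weight_kg

    plateaus = {"rest": subject.vo2rest_ml_min, "stand": vo2stand}
    for stage in MOVING_STAGES:
        seq = kmh_to_ms(STAGE_SPEEDS_KMH[stage]) ** 2 / (GRAVITY * h)
        plateaus[stage] = vo2stand + w * met.vo2net_per_speedeq * seq

    # ---- VO2 trace on a regular bin grid --------------------------------
    times, values, labels = [], [], []
    prev = plateaus["rest"]
    for stage, t0, t1 in sched:
        tt = np.arange(t0, t1 - 1e-9, met.vo2_bin_s)
        if stage == "rest":
            # settling decline that reaches the true resting floor exactly
            # at rest_settle_s (the REE rule finds the floor, not a fluke)
            rel = tt - t0
            if met.rest_tau_s > 0 and met.rest_settle_s > 0:
                decay = np.exp(-rel / met.rest_tau_s) - np.exp(
                    -met.rest_settle_s / met.rest_tau_s)
                decay = np.maximum(decay, 0.0) / (
                    1.0 - np.exp(-met.rest_settle_s / met.rest_tau_s))
            else:
                decay = np.zeros_like(rel)
            vv = plateaus["rest"] * (1.0 + met.rest_elev_frac * decay)
        else:
            vv = _stage_rise(tt - t0, prev, plateaus[stage],
                             met.rise_tau_s, met.rise_settle_s)
        if noise.vo2_rel_sd > 0:
            vv = vv * (1.0 + noise.vo2_rel_sd * rng.standard_normal(len(vv)))
        times.append(tt)
        values.append(np.maximum(vv, 1.0))
        labels.append(np.full(len(tt), stage, dtype=object))
        prev = plateaus[stage]
    trace = VO2Trace(np.concatenate(times), np.concatenate(values),
                     np.concatenate(labels))

    # ---- raw accelerometer signals (stand onward) -----------------------
    gain = _pipeline_gain(sig.sample_rate, config.target_rate,
                          config.band[0], config.band[1], sig.carrier_hz)
    accel_start = sched[1][1]  # stand start
    n = int(round((sched[-1][2] - accel_start) * sig.sample_rate))
    t = accel_start + np.arange(n) / sig.sample_rate

    recs: dict[str, TriaxialRecording] = {}
    for placement in ("hip", "thigh"):
        amp = np.zeros(n)
        for stage, t0, t1 in sched[1:]:
            target = sig.mg_at_speed(kmh_to_ms(STAGE_SPEEDS_KMH[stage]),
                                     placement, subject.thigh_scale)
            if noise.mg_rel_sd > 0 and stage != "stand":
                target *= float(np.exp(noise.mg_rel_sd * rng.standard_normal()))
            m = (t >= t0) & (t < t1)
            amp[m] = (target / 1000.0) / gain
        x, y, z = _balanced_carrier(t, amp, sig.carrier_hz)
        recs[placement] = TriaxialRecording(
            subject.profile.subject_id, placement, sig.sample_rate,
            float(accel_start), x, y, z + 1.0)  # gravity on z
    return recs, trace


# --------------------------------------------------------------------------
# analytic (closed-form) cut-points
# --------------------------------------------------------------------------

def analytic_cutpoints(config: GeneratorConfig,
                       cohort: list[SyntheticSubject] | None = None) -> GroundTruth:
    """Closed-form mg cut-points from the generating curves.

    The adult regression implied by the generating model is
    ``vo2net = rpk * MET - rpk * stand_ratio``; net-VO2 cut-points follow
    from the adult MET cut-points, and mg values from inverting the
    mg-vs-speed power curves. With ``cohort`` given, group parameters are
    the cohort's realized harmonic means (what a pooled per-group fit
    encodes, since net VO2 at fixed mg averages 1/height and MET averages
    1/resting-VO2); otherwise the configured population means are used.
    """
    met = config.metabolic
    sig = config.signal
    if sig.hip_power <= 0 or sig.thigh_power <= 0:
        raise ConfigError("generating curves must be monotone (positive powers)")

    def group_params(group: str) -> tuple[float, float]:
        gp = config.groups[group]
        if cohort is None:
            return gp.height_mean, gp.vo2rest_per_kg_mean
        subs = [s for s in cohort if s.profile.age_group == group]
        if not subs:
            return gp.height_mean, gp.vo2rest_per_kg_mean
        h = 1.0 / np.mean([1.0 / s.profile.height_m for s in subs])
        rpk = 1.0 / np.mean([1.0 / s.vo2rest_per_kg for s in subs])
        return float(h), float(rpk)

    _, rpk_adult = group_params("adults")
    vo2net_cuts = {lv: rpk_adult * (m - met.stand_ratio)
                   for lv, m in MET_CUTPOINTS.items()}

    mg: dict[tuple[str, str, str], dict[str, float]] = {}
    for group, gp in config.groups.items():
        h_grp, rpk_grp = group_params(group)
        met_equiv = {lv: rpk_grp * (m - met.stand_ratio)
                     for lv, m in MET_CUTPOINTS.items()}
        for method, net_cuts in (("vo2net", vo2net_cuts), ("met", met_equiv)):
            speeds = {lv: np.sqrt(max(v, 0.0) * GRAVITY * h_grp
                                  / met.vo2net_per_speedeq)
                      for lv, v in net_cuts.items()}
            mg[("hip", group, method)] = {
                lv: sig.hip_coef * s ** sig.hip_power for lv, s in speeds.items()}
            mg[("thigh", group, method)] = {
                lv: gp.thigh_scale * sig.thigh_coef * s ** sig.thigh_power
                for lv, s in speeds.items()}
    for cuts in mg.values():
        vals = [cuts[lv] for lv in LEVELS]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ConfigError("analytic cut-points not strictly increasing")
    return GroundTruth(vo2net_cuts, mg)


# --------------------------------------------------------------------------
# free-living weeks
# --------------------------------------------------------------------------

def simulate_free_living_subjects(config: GeneratorConfig,
                                  rng: np.random.Generator | None = None
                                  ) -> list[tuple[str, float, str]]:
    """(subject_id, age, category) roster for the free-living sub-study."""
    rng = config.rng() if rng is None else rng
    fl = config.free_living
    out = []
    for cat, n in fl.group_sizes.items():
        lo, hi = fl.age_ranges[cat]
        for i in range(n):
            out.append((f"fl_{cat}_{i + 1:02d}", float(rng.uniform(lo, hi)), cat))
    return out


def _state_sequence(n_epochs: int, profile: ActivityProfile, epoch_s: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov state index per epoch (exponential dwells)."""
    states = np.empty(n_epochs, dtype=np.int8)
    pos = 0
    current = 0  # start sedentary
    while pos < n_epochs:
        dwell_s = rng.exponential(profile.dwell_mean_s[current])
        k = max(1, int(round(dwell_s / epoch_s)))
        states[pos: pos + k] = current
        pos += k
        current = int(rng.choice(5, p=profile.transition[current]))
    return states


def simulate_free_living_week(subject_id: str, age: float, category: str,
                              config: GeneratorConfig,
                              rng: np.random.Generator,
                              truth: GroundTruth | None = None
                              ) -> tuple[EpochSeries, dict]:
    """One multi-day 3-s epoch series plus its ground-truth slice.

    Epoch intensities are drawn uniformly inside the generator-truth hip
    net-VO2 cut-point band of the planted state, so classification with
    generator-matched cut-points recovers the states exactly. Sleep epochs
    (night window) are near zero; planted daytime non-wear bouts are
    flagged in both the series and the truth slice.
    """
    from .free_living import cutpoint_group_for_age

    truth = analytic_cutpoints(config) if truth is None else truth
    fl = config.free_living
    group = cutpoint_group_for_age(age)
    cuts = truth.mg_cutpoints[("hip", group, "vo2net")]
    edges = np.array([0.0] + [cuts[lv] for lv in LEVELS]
                     + [fl.vvpa_band_top * cuts["VVPA"]])

    epd = int(round(86400.0 / fl.epoch_length))  # epochs per day
    n = fl.n_days * epd
    states = _state_sequence(n, fl.profiles[category], fl.epoch_length, rng)
    mg = rng.uniform(edges[states], np.nextafter(edges[states + 1],
                                                 edges[states]))

    start = pd.Timestamp(fl.start)
    times = (start + pd.to_timedelta(fl.epoch_length * np.arange(n), unit="s")).values
    seconds = (np.arange(n) * fl.epoch_length) % 86400.0

    night_lo, night_hi = fl.night[0] * 3600.0, fl.night[1] * 3600.0
    asleep = (seconds >= night_lo) | (seconds < night_hi)
    mg[asleep] = 0.0

    nonwear = np.zeros(n, dtype=bool)
    per_epoch_min = fl.epoch_length / 60.0
    for day in range(fl.n_days):
        for _ in range(rng.poisson(fl.nonwear_bouts_per_day)):
            dur = rng.uniform(*fl.nonwear_bout_minutes)
            k = int(round(dur / per_epoch_min))
            day_lo = day * epd + int(night_hi / fl.epoch_length)
            day_hi = day * epd + int(night_lo / fl.epoch_length) - k
            if day_hi <= day_lo:
                continue
            s = int(rng.integers(day_lo, day_hi))
            nonwear[s: s + k] = True
    mg[nonwear] = 0.0

    series = EpochSeries(fl.epoch_length, times, mg, ~nonwear)
    slice_truth = {"states": np.asarray(STATES, dtype=object)[states],
                   "nonwear": nonwear, "asleep": asleep,
                   "age": age, "category": category}
    return series, slice_truth
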