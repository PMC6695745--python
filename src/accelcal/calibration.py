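"""Anchored smoothing-spline calibration of mg output to criterion intensity.

Two calibration routes are supported:

* **net-VO2 route** — adult MET cut-points are translated to net-VO2 values
  by linear regression on adult stage records; the same net-VO2 cut-points
  are then applied to every age group via the group's fitted mg -> VO2net
  curve.
* **MET route** — the standard MET cut-points (1.5/3.0/6.0/9.0) applied per
  group via the group's fitted mg -> MET curve.

Because the net-VO2 cut-points are defined from the adult MET values, the
two routes coincide for adults *by construction*; the table builder encodes
that identity directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import isotonic_regression

from .errors import ConfigError, DataError, ExtrapolationError

#: Intensity levels above sedentary, lowest first.
LEVELS = ("LPA", "MPA", "VPA", "VVPA")
#: Standard MET cut-points per level.
MET_CUTPOINTS = {"LPA": 1.5, "MPA": 3.0, "VPA": 6.0, "VVPA": 9.0}

AGE_GROUPS = ("children", "adolescents", "adults")
PLACEMENTS = ("hip", "thigh")


@dataclass
class CalibrationPoint:
    """One subject x stage x placement record."""

    subject_id: str
    age_group: str
    placement: str
    stage: str
    speed_kmh: float
    speed_eq: float
    mg: float
    vo2_net: float
    met: float


@dataclass
class MetVo2netRegression:
    """OLS line mapping MET to net VO2 (mL/min/kg), fitted on adult records."""

    slope: float
    intercept: float
    n: int
    r2: float

    def predict(self, met: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(met, dtype=float) + self.intercept


def fit_met_vo2net_regression(points: Iterable[CalibrationPoint],
                              adults_only: bool = True,
                              include_stand: bool = True,
                              on: str = "group_means") -> MetVo2netRegression:
    """Ordinary least squares of vo2_net on met over adult stage records.

    ``on="group_means"`` (default) regresses on per-stage means, which is
    robust to between-subject spread in resting metabolism acting as
    regressor noise; ``on="points"`` uses every subject x stage record.
    """
    pts = [p for p in points
           if (p.age_group == "adults" or not adults_only)
           and (include_stand or p.stage != "stand")]
    if on == "group_means":
        by_stage: dict[str, list[CalibrationPoint]] = {}
        for p in pts:
            by_stage.setdefault(p.stage, []).append(p)
        met = np.array([np.mean([p.met for p in v]) for v in by_stage.values()])
        vo2 = np.array([np.mean([p.vo2_net for p in v]) for v in by_stage.values()])
    elif on == "points":
        met = np.array([p.met for p in pts], dtype=float)
        vo2 = np.array([p.vo2_net for p in pts], dtype=float)
    else:
        raise ConfigError(f"unknown regression mode {on!r}")
    if len(met) < 2 or np.ptp(met) < 1e-12:
        raise DataError("need >= 2 distinct MET values for the regression")
    slope, intercept = np.polyfit(met, vo2, 1)
    resid = vo2 - (slope * met + intercept)
    ss_tot = float(np.sum((vo2 - vo2.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return MetVo2netRegression(float(slope), float(intercept), len(pts), r2)


def _round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (14.15 -> 14.2), not banker's rounding.

    The value is first quantized to 9 decimals so binary-float artifacts
    (2.9*6 - 3.25 == 14.149999...) do not flip the half-way case.
    """
    d = Decimal(repr(x)).quantize(Decimal(1).scaleb(-9), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def derive_vo2net_cutpoints(regression: MetVo2netRegression,
                            met_cutpoints: Mapping[str, float] = MET_CUTPOINTS,
                            decimals: int | None = 1) -> dict[str, float]:
    """Net-VO2 cut-point per level = regression evaluated at the MET cut-point.

    ``decimals`` controls reporting precision (1 decimal, half-up, by
    default); pass None to keep full precision.
    """
    out = {}
    for level, met in met_cutpoints.items():
        v = float(regression.predict(met))
        out[level] = _round_half_up(v, decimals) if decimals is not None else v
    return out


@dataclass
class IntensityCurve:
    """Monotone fitted curve mg -> response (net VO2 or MET), anchored at 0 mg.

    The fitted smoothing spline is evaluated on a 1-mg grid, the anchor is
    pinned exactly, the grid predictions are projected to the nearest
    monotone non-decreasing sequence, and predictions interpolate that grid.
    """

    age_group: str
    placement: str
    response: str  # "vo2_net" | "met"
    grid: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)
    anchor: float = 0.0
    r2: float = float("nan")

    def predict(self, mg: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(mg, dtype=float), self.grid, self.predictions)

    @property
    def max_response(self) -> float:
        return float(self.predictions[-1])


def _isotonic(y: np.ndarray) -> np.ndarray:
    """L2 isotonic (non-decreasing) projection (pool-adjacent-violators)."""
    return np.asarray(isotonic_regression(np.asarray(y, dtype=float)).x)


def _merge_duplicates(x: np.ndarray, y: np.ndarray, w: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort and collapse duplicate abscissas to their weighted mean."""
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    ux, inv = np.unique(np.round(xs, 9), return_inverse=True)
    wsum = np.bincount(inv, weights=ws)
    ymean = np.bincount(inv, weights=ws * ys) / wsum
    return ux, ymean, wsum


def _fit_spline_weighted(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                         anchor: float, anchor_weight: float, lam: float | None):
    x_all = np.concatenate([[0.0], x])
    y_all = np.concatenate([[anchor], y])
    w_all = np.concatenate([[anchor_weight], w])
    ux, ymean, wsum = _merge_duplicates(x_all, y_all, w_all)
    return make_smoothing_spline(ux, ymean, w=wsum, lam=lam)


def _fit_spline(mg: np.ndarray, y: np.ndarray, anchor: float,
                anchor_weight: float, lam: float | None):
    return _fit_spline_weighted(mg, y, np.ones_like(mg), anchor,
                                anchor_weight, lam)


#: Candidate smoothing parameters for cross-validated selection.
LAM_GRID = np.logspace(2.0, 7.0, 11)


def _select_lam(mg: np.ndarray, y: np.ndarray, stages: np.ndarray,
                anchor: float, anchor_weight: float) -> float | None:
    """Deterministic leave-one-stage-out choice of the smoothing parameter.

    Protocol replicates make the abscissas strongly clustered, which
    defeats point-wise generalized cross-validation (it happily
    interpolates between cluster means, oscillating in the gaps where
    cut-points are inverted). Holding out one whole interior stage at a
    time scores exactly that between-cluster behaviour. Returns None
    (= scipy's internal GCV) when there are too few stages to fold.
    """
    order = np.argsort([float(np.median(mg[stages == s])) for s in np.unique(stages)])
    stage_names = np.unique(stages)[order]
    interior = stage_names[1:-1]
    if len(interior) < 2:
        return None
    best_lam, best_score = None, np.inf
    for lam in LAM_GRID:
        score = 0.0
        try:
            for stage in interior:
                held = stages == stage
                spl = _fit_spline(mg[~held], y[~held], anchor, anchor_weight, lam)
                scale = max(abs(float(np.mean(y[held]))), 1e-3)
                score += float(np.sum(((y[held] - spl(mg[held])) / scale) ** 2))
        except Exception:
            continue
        if score < best_score - 1e-12:
            best_score, best_lam = score, float(lam)
    return best_lam


def fit_intensity_curve(points: Iterable[CalibrationPoint], response: str,
                        anchor_weight: float = 1e3,
                        grid_step: float = 1.0,
                        include_stand: bool = False,
                        fit_on: str = "stage_means") -> IntensityCurve:
    """Anchored cubic smoothing spline of ``response`` against mg.

    A pseudo-observation at (0 mg, anchor) carries ``anchor_weight`` times
    the maximum data weight. By default the spline is fitted to per-stage
    weighted means (``fit_on="stage_means"``) with the smoothing parameter
    chosen by generalized cross-validation; ``fit_on="points"`` fits all
    records with the smoothing parameter chosen by deterministic
    leave-one-stage-out cross-validation instead. The stand stage is
    excluded by default: its intensity is postural, not locomotor, and the
    zero-intensity anchor already encodes the resting end of the curve.
    R-squared is always reported against the raw (per-record) points.
    """
    pts = list(points)
    if not pts:
        raise DataError("no calibration points")
    groups = {p.age_group for p in pts}
    placements = {p.placement for p in pts}
    if len(groups) != 1 or len(placements) != 1:
        raise DataError("points must come from a single group x placement")
    if response not in ("vo2_net", "met"):
        raise ConfigError(f"unknown response {response!r}")
    if fit_on not in ("stage_means", "points"):
        raise ConfigError(f"unknown fit_on mode {fit_on!r}")
    anchor = 0.0 if response == "vo2_net" else 1.0

    fit_pts = [p for p in pts if include_stand or p.stage != "stand"]
    mg = np.array([p.mg for p in fit_pts], dtype=float)
    y = np.array([getattr(p, response) for p in fit_pts], dtype=float)
    stages = np.array([p.stage for p in fit_pts])
    if len(np.unique(np.round(mg, 6))) < 5:
        raise DataError("need >= 5 distinct mg values to fit a spline")

    if fit_on == "stage_means":
        names = np.unique(stages)
        fx = np.array([mg[stages == s].mean() for s in names])
        fy = np.array([y[stages == s].mean() for s in names])
        fw = np.array([float(np.sum(stages == s)) for s in names])
        aw = anchor_weight * float(fw.max())
        lam = None  # GCV on the collapsed data
    else:
        fx, fy, fw = mg, y, np.ones_like(mg)
        aw = anchor_weight * 1.0
        lam = _select_lam(mg, y, stages, anchor, aw)
    try:
        spl = _fit_spline_weighted(fx, fy, fw, anchor, aw, lam)
    except Exception:  # GCV failure: deterministic light smoothing fallback
        spl = _fit_spline_weighted(fx, fy, fw, anchor, aw,
                                   1e-3 * float(np.ptp(fx)) ** 3 / max(len(fx), 1))

    grid = np.arange(0.0, float(mg.max()) + grid_step, grid_step)
    pred = np.asarray(spl(grid), dtype=float)
    pred[0] = anchor  # pin the anchor exactly
    pred = np.concatenate([[anchor], _isotonic(np.maximum(pred[1:], anchor))])
    pred = np.maximum.accumulate(pred)

    mg_all = np.array([p.mg for p in pts], dtype=float)
    y_all = np.array([getattr(p, response) for p in pts], dtype=float)
    fitted = np.interp(mg_all, grid, pred)
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y_all - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0

    return IntensityCurve(pts[0].age_group, pts[0].placement, response,
                          grid, pred, anchor, r2)


def invert_to_mg(curve: IntensityCurve, cutpoint_value: float) -> int:
    """Smallest grid mg whose predicted response reaches ``cutpoint_value``."""
    if cutpoint_value > curve.max_response + 1e-12:
        raise ExtrapolationError(
            f"cut-point {cutpoint_value} above fitted maximum "
            f"{curve.max_response:.3f} for {curve.age_group}/{curve.placement}")
    idx = int(np.searchsorted(curve.predictions, cutpoint_value, side="left"))
    return int(round(curve.grid[min(idx, len(curve.grid) - 1)]))


@dataclass
class CutPointTable:
    """mg thresholds per placement x age group x level, both calibration routes."""

    vo2net_cutpoints: dict[str, float]
    met_cutpoints: dict[str, float]
    mg_cutpoints: dict[tuple[str, str, str], dict[str, int]]  # (placement, group, method)
    r2: dict[tuple[str, str, str], float] = field(default_factory=dict)
    errors: dict[tuple[str, str, str], str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors

    def cell(self, placement: str, group: str, method: str) -> dict[str, int]:
        return self.mg_cutpoints[(placement, group, method)]

    def to_dict(self) -> dict:
        return {
            "vo2net_cutpoints": self.vo2net_cutpoints,
            "met_cutpoints": self.met_cutpoints,
            "mg_cutpoints": {
                f"{p}/{g}/{m}": cuts for (p, g, m), cuts in self.mg_cutpoints.items()
            },
            "r2": {f"{p}/{g}/{m}": v for (p, g, m), v in self.r2.items()},
            "errors": {f"{p}/{g}/{m}": v for (p, g, m), v in self.errors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutPointTable":
        def unkey(k: str) -> tuple[str, str, str]:
            p, g, m = k.split("/")
            return p, g, m

        return cls(
            vo2net_cutpoints=dict(d["vo2net_cutpoints"]),
            met_cutpoints=dict(d["met_cutpoints"]),
            mg_cutpoints={unkey(k): {lv: int(v) for lv, v in c.items()}
                          for k, c in d["mg_cutpoints"].items()},
            r2={unkey(k): float(v) for k, v in d.get("r2", {}).items()},
            errors={unkey(k): v for k, v in d.get("errors", {}).items()},
        )


def _check_ordered(cuts: dict[str, int]) -> bool:
    vals = [cuts[lv] for lv in LEVELS]
    return all(a < b for a, b in zip(vals, vals[1:]))


def build_cutpoint_table(curves: Iterable[IntensityCurve],
                         vo2net_cutpoints: Mapping[str, float],
                         met_cutpoints: Mapping[str, float] = MET_CUTPOINTS,
                         ) -> CutPointTable:
    """Invert fitted curves into the full placement x group x method table.

    Adult MET-route cells are copied from the adult net-VO2 route: the
    net-VO2 cut-points are defined from the adult MET values, so the two
    routes are identical for adults by construction.
    """
    by_key = {(c.placement, c.age_group, c.response): c for c in curves}
    table = CutPointTable(dict(vo2net_cutpoints), dict(met_cutpoints), {}, {}, {})

    for (placement, group, response), curve in by_key.items():
        method = "vo2net" if response == "vo2_net" else "met"
        if group == "adults" and method == "met":
            continue  # filled from the net-VO2 route below
        cuts_src = vo2net_cutpoints if method == "vo2net" else met_cutpoints
        cell: dict[str, int] = {}
        try:
            for level in LEVELS:
                cell[level] = invert_to_mg(curve, cuts_src[level])
            if not _check_ordered(cell):
                raise DataError(f"cut-points not strictly increasing: {cell}")
        except (ExtrapolationError, DataError) as exc:
            table.errors[(placement, group, method)] = str(exc)
            continue
        table.mg_cutpoints[(placement, group, method)] = cell
        table.r2[(placement, group, method)] = curve.r2

    # adult method equivalence, by construction
    for placement in PLACEMENTS:
        key_v = (placement, "adults", "vo2net")
        if key_v in table.mg_cutpoints:
            table.mg_cutpoints[(placement, "adults", "met")] = dict(
                table.mg_cutpoints[key_v])
            met_curve = by_key.get((placement, "adults", "met"))
            table.r2[(placement, "adults", "met")] = (
                met_curve.r2 if met_curve is not None else table.r2.get(key_v, float("nan")))
        elif key_v in table.errors:
            table.errors[(placement, "adults", "met")] = table.errors[key_v]

    return table
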