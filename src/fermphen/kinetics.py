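"""Fermentation CO2-release kinetics from vial weight-loss time series.

A fermenting vial loses weight as CO2 escapes; weighing it 2-3 times a day
yields a sparse, noisy cumulative-release curve.  The model here is the
classical loess local-polynomial smoother (degree 2, tricube weights,
span 0.45) evaluated on a fine regular grid, monotonized by running maximum,
from which six kinetic traits are read:

``lp``
    lag phase: time to release the first 2 g/L of CO2;
``t35, t50, t80``
    time to release 35/50/80 % of the theoretical CO2 maximum of the must,
    counted after subtracting ``lp``;
``v50_80``
    average hexose consumption rate (g/L/h) over the 50-80 % interval,
    obtained from CO2 via the 0.482 stoichiometric yield;
``co2max``
    maximal CO2 released (plateau of the smoothed curve).

The model/results split follows the statsmodels convention:
``Co2CurveModel(record).fit(tco2max)`` returns a :class:`KineticResults`
holding the smoothed curve, the extracted parameters and quality flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .must import CO2_YIELD

__all__ = [
    "FermentationRecord",
    "SmoothedCurve",
    "KineticParams",
    "Co2CurveModel",
    "KineticResults",
    "weights_to_co2",
    "loess_smooth",
    "smooth_curve",
    "extract_kinetic_params",
    "LAG_CO2_THRESHOLD",
]

#: CO2 release (g/L) defining the end of the lag phase.
LAG_CO2_THRESHOLD = 2.0


@dataclass(frozen=True)
class FermentationRecord:
    """One vial's weighing time series plus its design labels.

    ``times`` are hours since inoculation (strictly increasing, >= 0);
    ``weights`` are balance readings in grams; ``volume`` is the fermented
    volume in mL; ``shaking`` encodes the micro-oxygenation modality.
    """

    vial_id: str
    strain: str
    must_code: str
    shaking: bool
    volume: float
    replicate: int
    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        if t.ndim != 1 or t.shape != w.shape:
            raise ValueError(f"vial {self.vial_id}: times and weights must be 1-D and equal-length")
        if t.size < 4:
            raise ValueError(f"vial {self.vial_id}: need >= 4 time points, got {t.size}")
        if t[0] < 0:
            raise ValueError(f"vial {self.vial_id}: times must start at >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"vial {self.vial_id}: times must be strictly increasing")
        if not np.all(np.isfinite(w)):
            raise ValueError(f"vial {self.vial_id}: weights must be finite")
        if self.volume <= 0:
            raise ValueError(f"vial {self.vial_id}: volume must be > 0 mL, got {self.volume}")


@dataclass(frozen=True)
class SmoothedCurve:
    """Loess-smoothed cumulative CO2 release on a regular time grid.

    ``co2`` is clipped at zero and monotonized (running maximum), so it is a
    valid cumulative-release curve; ``span`` records the smoothing fraction.
    """

    grid_times: np.ndarray
    co2: np.ndarray
    span: float

    def __post_init__(self) -> None:
        if self.co2[0] < 0 or np.any(np.diff(self.co2) < 0):
            raise ValueError("smoothed CO2 must be non-negative and non-decreasing")


@dataclass(frozen=True)
class KineticParams:
    """The six kinetic traits of one fermentation (units: h, g/L, g/L/h).

    Threshold times that the curve never reaches are ``nan`` and flagged:
    ``STUCK`` when 80 % of tCO2max is not released, ``NO_LAG_REACHED`` when
    even the 2 g/L lag threshold is not crossed.
    """

    lp: float
    t35: float
    t50: float
    t80: float
    v50_80: float
    co2max: float
    tco2max: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def to_dict(self) -> dict:
        return {
            "lp": self.lp,
            "t35": self.t35,
            "t50": self.t50,
            "t80": self.t80,
            "v50_80": self.v50_80,
            "co2max": self.co2max,
            "tco2max": self.tco2max,
            "flags": ";".join(sorted(self.flags)),
        }


def weights_to_co2(record: FermentationRecord) -> np.ndarray:
    """Convert balance readings to cumulative CO2 released (g/L).

    ``co2(t_i) = (weight(t_0) - weight(t_i)) / volume_in_L``; the first value
    is exactly 0 and the series is returned as observed (not monotonized).
    """
    litres = record.volume / 1000.0
    return (record.weights[0] - record.weights) / litres


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.45,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights (loess).

    For each evaluation point the nearest ``floor(span * n)`` observations are
    weighted by the tricube kernel of their distance scaled to the farthest
    neighbour, and a degree-``degree`` polynomial is fitted by weighted least
    squares (the convention of the classical loess implementations, which this
    reproduces to ~1e-5).  All local fits are solved as one batched
    normal-equation system.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x.size
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    k = max(int(math.floor(span * n)), degree + 1)
    if n < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for degree {degree}, got {n}")
    k = min(k, n)

    # nearest-k neighbourhoods: distances (n_eval, n) -> indices of k smallest
    d = np.abs(x_eval[:, None] - x[None, :])
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    dk = np.take_along_axis(d, idx, axis=1)
    h = dk.max(axis=1, keepdims=True)  # bandwidth = distance to k-th neighbour
    h = np.where(h > 0, h, 1.0)
    w = np.clip(1.0 - (dk / h) ** 3, 0.0, None) ** 3
    # guard: if all weights vanish (duplicate x at boundary), fall back to uniform
    wsum = w.sum(axis=1, keepdims=True)
    w = np.where(wsum > 0, w, 1.0)

    # batched weighted polynomial fit, centred at each evaluation point for
    # conditioning; the fitted value is then the constant coefficient
    xc = np.take_along_axis(x[None, :].repeat(x_eval.size, axis=0), idx, axis=1)
    yk = np.take_along_axis(y[None, :].repeat(x_eval.size, axis=0), idx, axis=1)
    t = xc - x_eval[:, None]
    basis = np.stack([t**p for p in range(degree + 1)], axis=2)  # (m, k, deg+1)
    wb = w[:, :, None] * basis
    ata = np.einsum("mkp,mkq->mpq", wb, basis)
    aty = np.einsum("mkp,mk->mp", wb, yk)
    eye = np.eye(degree + 1) * 1e-12
    coef = np.linalg.solve(ata + eye, aty[:, :, None])[:, :, 0]
    fitted = coef[:, 0]

    # ties at exactly the bandwidth can zero out all but < degree+1 weights,
    # making the local system rank-deficient; refit those points at the
    # highest degree their effective support allows
    support = (w > 1e-9 * w.max(axis=1, keepdims=True)).sum(axis=1)
    for m in np.nonzero(support < degree + 1)[0]:
        deg = max(int(support[m]) - 1, 0)
        b = basis[m, :, : deg + 1]
        wm = w[m]
        g = (wm[:, None] * b).T @ b + np.eye(deg + 1) * 1e-12
        rhs = (wm[:, None] * b).T @ yk[m]
        fitted[m] = np.linalg.solve(g, rhs)[0]
    return fitted


def smooth_curve(
    times: np.ndarray,
    co2: np.ndarray,
    span: float = 0.45,
    grid_step: float = 0.1,
) -> SmoothedCurve:
    """Smooth an observed CO2 series onto a regular grid covering [0, t_max].

    Loess (degree 2, tricube) with the given span, then clipped at zero and
    made non-decreasing by running maximum — balance drift can make raw
    cumulative loss locally decrease, but release is cumulative by nature.
    Grid points before the first observation are held at the boundary fit
    rather than extrapolated (a local quadratic extrapolates poorly).
    """
    times = np.asarray(times, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    if times.size < 4:
        raise ValueError(f"need >= 4 points to smooth, got {times.size}")
    grid = np.arange(0.0, times[-1] + grid_step / 2, grid_step)
    inside = grid >= times[0]
    fitted = np.empty_like(grid)
    fitted[inside] = loess_smooth(times, co2, grid[inside], span=span, degree=2)
    if not inside.all():
        fitted[~inside] = loess_smooth(times, co2, times[:1], span=span, degree=2)[0]
    fitted = np.maximum.accumulate(np.clip(fitted, 0.0, None))
    return SmoothedCurve(grid_times=grid, co2=fitted, span=span)


def _cross_time(grid: np.ndarray, co2: np.ndarray, level: float) -> float:
    """First time the curve reaches ``level``, linearly interpolated; nan if never."""
    above = co2 >= level
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(grid[0])
    t0, t1 = grid[i - 1], grid[i]
    c0, c1 = co2[i - 1], co2[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (level - c0) / (c1 - c0) * (t1 - t0))


def extract_kinetic_params(curve: SmoothedCurve, tco2max: float) -> KineticParams:
    """Extract the six kinetic traits from a smoothed curve.

    ``lp`` is the interpolated crossing of 2 g/L; ``tX`` the interpolated
    crossing of X % of ``tco2max`` minus ``lp``; ``co2max`` the final value of
    the monotonized curve; ``v50_80 = (0.30 * tco2max / 0.482) / (t80 - t50)``,
    i.e. the hexose consumed between the two thresholds divided by the time
    taken.  Unreached thresholds yield ``nan`` plus a quality flag.
    """
    if tco2max <= 0:
        raise ValueError(f"tco2max must be > 0, got {tco2max}")
    grid, co2 = curve.grid_times, curve.co2
    flags: set[str] = set()

    lp = _cross_time(grid, co2, LAG_CO2_THRESHOLD)
    if math.isnan(lp):
        flags.add("NO_LAG_REACHED")
    t35 = _cross_time(grid, co2, 0.35 * tco2max)
    t50 = _cross_time(grid, co2, 0.50 * tco2max)
    t80 = _cross_time(grid, co2, 0.80 * tco2max)
    if math.isnan(t80):
        flags.add("STUCK")

    co2max = float(co2[-1])
    if not math.isnan(lp):
        t35, t50, t80 = t35 - lp, t50 - lp, t80 - lp
    if not (math.isnan(t50) or math.isnan(t80)) and t80 > t50:
        v50_80 = (0.30 * tco2max / CO2_YIELD) / (t80 - t50)
    else:
        v50_80 = float("nan")
    return KineticParams(
        lp=lp, t35=t35, t50=t50, t80=t80,
        v50_80=v50_80, co2max=co2max, tco2max=tco2max,
        flags=frozenset(flags),
    )


class Co2CurveModel:
    """Loess model of one vial's cumulative CO2 release.

    Parameters
    ----------
    record : FermentationRecord
        The vial's weighing time series and design labels.
    span : float
        Loess span (fraction of points per local fit), default 0.45.
    grid_step : float
        Evaluation grid resolution in hours, default 0.1.

    Examples
    --------
    >>> res = Co2CurveModel(record).fit(tco2max=must.tco2max)
    >>> res.params.t50, res.params.co2max  # doctest: +SKIP
    """

    def __init__(self, record: FermentationRecord, span: float = 0.45, grid_step: float = 0.1):
        self.record = record
        self.span = span
        self.grid_step = grid_step
        self.raw_co2 = weights_to_co2(record)

    def fit(self, tco2max: float) -> "KineticResults":
        """Smooth the curve and extract kinetic traits against ``tco2max``."""
        curve = smooth_curve(
            self.record.times, self.raw_co2, span=self.span, grid_step=self.grid_step
        )
        params = extract_kinetic_params(curve, tco2max)
        return KineticResults(model=self, curve=curve, params=params)


@dataclass(frozen=True)
class KineticResults:
    """Fitted CO2 curve plus extracted kinetic traits for one vial."""

    model: Co2CurveModel
    curve: SmoothedCurve
    params: KineticParams

    def summary(self) -> str:
        p = self.params
        rec = self.model.record
        lines = [
            f"Fermentation kinetics: vial {rec.vial_id} "
            f"(strain {rec.strain}, must {rec.must_code}, "
            f"{'shaken' if rec.shaking else 'still'}, {rec.volume:g} mL)",
            f"  observations: {rec.times.size}  span: {self.curve.span}",
            f"  lp      = {p.lp:8.2f} h",
            f"  t35     = {p.t35:8.2f} h",
            f"  t50     = {p.t50:8.2f} h",
            f"  t80     = {p.t80:8.2f} h",
            f"  v50_80  = {p.v50_80:8.3f} g/L/h",
            f"  CO2max  = {p.co2max:8.2f} g/L (tCO2max {p.tco2max:.2f})",
        ]
        if p.flags:
            lines.append(f"  flags: {', '.join(sorted(p.flags))}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and smoothed curve; threshold times if defined."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.record.times, self.model.raw_co2, "o", ms=4, label="observed")
        ax.plot(self.curve.grid_times, self.curve.co2, "-", label=f"loess (span {self.curve.span})")
        p = self.params
        for name, t in (("lp", p.lp), ("t50", p.t50 + p.lp), ("t80", p.t80 + p.lp)):
            if not math.isnan(t):
                ax.axvline(t, ls=":", lw=0.8, color="grey")
                ax.text(t, ax.get_ylim()[1] * 0.02, name, rotation=90, fontsize=8)
        ax.set_xlabel("time since inoculation (h)")
        ax.set_ylabel("CO$_2$ released (g/L)")
        ax.legend()
        return ax
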