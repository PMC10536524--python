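"""Schnute growth-curve fitting for seedling axis elongation.

A single seedling axis (radicle or hypocotyl) followed in the dark yields a
length/time trajectory ``y(t)`` in mm.  We fit the four-parameter Schnute
model, a flexible family that contains logistic, Gompertz, von Bertalanffy
and power-law growth as special cases:

    y(t) = [ y1^b + (y2^b - y1^b) * (1 - exp(-a (t - tau1)))
                                    / (1 - exp(-a (tau2 - tau1))) ]^(1/b)

with the reference times ``tau1`` and ``tau2`` pinned at the first and last
observation so that ``y1`` and ``y2`` are simply the (fitted) lengths at the
window endpoints.  ``a`` (per hour) sets the time scale and ``b``
(dimensionless) the shape; ``0 < b < 1`` gives sigmoid trajectories with an
interior inflection, ``b >= 1`` gives saturating, hyperbola-like paths whose
absolute elongation rate is largest at the start of the window.

From the fitted curve we extract, analytically,

* AER(t) = dy/dt — the absolute elongation rate (mm/h);
* RER(t) = AER(t)/y(t) — the relative elongation rate (mm/h/mm);
* MER — the maximum of AER on the window, located at the interior root of
  the second derivative when one exists;
* RER_max = MER / y(t*) — the relative rate at the time t* of MER.  When an
  interior inflection exists and 0 < b < 1 this equals a / (1 - b).

The module also provides plateau (final length) detection, shoot:root
ratios and the quadratic fit of final length against temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ElongationSeries",
    "SchnuteParams",
    "SchnuteFit",
    "GrowthRates",
    "FinalLengthRecord",
    "SRRatio",
    "ParabolaFit",
    "SchnuteDomainError",
    "predict_length",
    "aer",
    "rer",
    "fit_schnute",
    "elongation_rates",
    "detect_final_length",
    "shoot_root_ratio",
    "fit_final_length_parabola",
]

#: |b| below this is treated as the exact b -> 0 (Gompertz) limit.
B_EPS = 1e-6
#: |a| below this is treated as the exact a -> 0 (linear-in-t) limit.
A_EPS = 1e-9

MIN_OBS_FOR_FIT = 5


class SchnuteDomainError(ValueError):
    """Parameters put the prediction outside the model's valid domain."""


@dataclass(frozen=True)
class ElongationSeries:
    """One seedling axis's length/time trajectory at one temperature."""

    accession: str
    seedling_id: int
    axis: str  # "radicle" | "hypocotyl"
    temperature_set: float
    temperature_actual: float
    times: np.ndarray  # hours since transfer, strictly increasing
    lengths: np.ndarray  # mm, non-negative

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "lengths", lengths)
        if self.axis not in ("radicle", "hypocotyl"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if times.shape != lengths.shape or times.ndim != 1:
            raise ValueError("times and lengths must be 1-D and equally long")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(lengths < 0):
            raise ValueError("lengths must be non-negative")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SchnuteParams:
    """Schnute model parameters; tau1/tau2 are the fixed reference times."""

    a: float  # per hour
    b: float  # dimensionless shape
    y1: float  # mm, length at tau1
    y2: float  # mm, length at tau2
    tau1: float  # h
    tau2: float  # h

    def __post_init__(self):
        if not (self.tau2 > self.tau1):
            raise ValueError("tau2 must exceed tau1")
        if self.y1 <= 0 or self.y2 <= 0:
            raise ValueError("y1 and y2 must be positive")


def _frac(a: float, tau1: float, tau2: float, t: np.ndarray) -> np.ndarray:
    """(1 - e^{-a(t-tau1)}) / (1 - e^{-a(tau2-tau1)}), with the a->0 limit."""
    if abs(a) < A_EPS:
        return (t - tau1) / (tau2 - tau1)
    return np.expm1(-a * (t - tau1)) / np.expm1(-a * (tau2 - tau1))


def _dfrac(a: float, tau1: float, tau2: float, t: np.ndarray) -> np.ndarray:
    """d/dt of :func:`_frac`."""
    if abs(a) < A_EPS:
        return np.full_like(np.asarray(t, dtype=float), 1.0 / (tau2 - tau1))
    return a * np.exp(-a * (t - tau1)) / (-np.expm1(-a * (tau2 - tau1)))


def _predict(p: SchnuteParams, t: np.ndarray) -> np.ndarray:
    """Model value; returns NaN where the parameter region is invalid."""
    t = np.asarray(t, dtype=float)
    fr = _frac(p.a, p.tau1, p.tau2, t)
    if abs(p.b) < B_EPS:
        # Gompertz-type limit: log-linear interpolation between y1 and y2.
        return np.exp(np.log(p.y1) + (np.log(p.y2) - np.log(p.y1)) * fr)
    u = p.y1 ** p.b + (p.y2 ** p.b - p.y1 ** p.b) * fr
    with np.errstate(invalid="ignore"):
        out = np.where(u > 0, np.abs(u) ** (1.0 / p.b), np.nan)
    return out


def predict_length(params: SchnuteParams, t):
    """Predicted axis length (mm) at time ``t`` (hours).

    Raises :class:`SchnuteDomainError` if the parameters drive the model
    out of its valid domain at any requested time (non-finite result).
    """
    scalar = np.isscalar(t)
    out = _predict(params, np.atleast_1d(np.asarray(t, dtype=float)))
    if not np.all(np.isfinite(out)):
        raise SchnuteDomainError(
            "Schnute prediction is non-finite for these parameters"
        )
    return float(out[0]) if scalar else out


def aer(params: SchnuteParams, t):
    """Absolute elongation rate dy/dt (mm/h), from the analytic derivative."""
    p = params
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dfr = _dfrac(p.a, p.tau1, p.tau2, t)
    if abs(p.b) < B_EPS:
        y = _predict(p, t)
        out = y * (np.log(p.y2) - np.log(p.y1)) * dfr
    else:
        fr = _frac(p.a, p.tau1, p.tau2, t)
        d = p.y2 ** p.b - p.y1 ** p.b
        u = p.y1 ** p.b + d * fr
        with np.errstate(invalid="ignore"):
            out = np.where(
                u > 0, (1.0 / p.b) * np.abs(u) ** (1.0 / p.b - 1.0) * d * dfr, np.nan
            )
    if not np.all(np.isfinite(out)):
        raise SchnuteDomainError("AER is non-finite for these parameters")
    return float(out[0]) if scalar else out


def rer(params: SchnuteParams, t):
    """Relative elongation rate AER(t)/y(t) (mm/h/mm)."""
    return aer(params, t) / predict_length(params, t)


def _d2y(p: SchnuteParams, t):
    """Analytic second derivative d2y/dt2."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dfr = _dfrac(p.a, p.tau1, p.tau2, t)
    if abs(p.b) < B_EPS:
        y = _predict(p, t)
        c = np.log(p.y2) - np.log(p.y1)
        # y'' = y * c * fr' * (c * fr' - a)
        return y * c * dfr * (c * dfr - p.a)
    fr = _frac(p.a, p.tau1, p.tau2, t)
    d = p.y2 ** p.b - p.y1 ** p.b
    u = p.y1 ** p.b + d * fr
    up = d * dfr
    upp = -p.a * up
    with np.errstate(invalid="ignore"):
        return (1.0 / p.b) * np.abs(u) ** (1.0 / p.b - 2.0) * (
            (1.0 / p.b - 1.0) * up ** 2 + u * upp
        )


@dataclass(frozen=True)
class GrowthRates:
    """Rates derived from a fitted trajectory.

    ``aer_max`` is the maximum elongation rate (MER, mm/h) on the window,
    ``t_star`` its time, ``rer_max = aer_max / y(t_star)``.
    ``inflection_found`` is True only when MER sits at an interior root of
    the second derivative (a genuine sigmoid inflection).
    """

    aer_max: float
    t_star: float
    length_at_t_star: float
    rer_max: float
    inflection_found: bool
    rss: float = float("nan")
    n_obs: int = 0


def elongation_rates(
    params: SchnuteParams,
    window: tuple[float, float] | None = None,
    *,
    rss: float = float("nan"),
    n_obs: int = 0,
    n_grid: int = 512,
) -> GrowthRates:
    """Locate the maximum elongation rate and derive RER_max.

    Interior candidates are the bracketed roots of the analytic second
    derivative (found by scanning ``n_grid`` points and polishing with
    Brent's method); the window endpoints complete the candidate set, and
    the argmax of AER over all candidates wins.  For curves without an
    interior inflection (``b >= 1``, hyperbola-like radicle paths) this
    lands on the window start.
    """
    lo, hi = window if window is not None else (params.tau1, params.tau2)
    if not hi > lo:
        raise ValueError("window must have positive width")
    grid = np.linspace(lo, hi, n_grid)
    d2 = _d2y(params, grid)
    if not np.all(np.isfinite(d2)):
        raise SchnuteDomainError("second derivative non-finite on window")
    candidates = [lo, hi]
    interior: list[float] = []
    sign = np.sign(d2)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(lambda t: float(_d2y(params, t)[0]), grid[i], grid[i + 1])
        if lo < root < hi:
            interior.append(float(root))
    candidates.extend(interior)
    rates = [aer(params, t) for t in candidates]
    k = int(np.argmax(rates))
    t_star = candidates[k]
    aer_max = rates[k]
    y_star = predict_length(params, t_star)
    return GrowthRates(
        aer_max=float(aer_max),
        t_star=float(t_star),
        length_at_t_star=float(y_star),
        rer_max=float(aer_max / y_star),
        inflection_found=k >= 2,
        rss=rss,
        n_obs=n_obs,
    )


@dataclass(frozen=True)
class SchnuteFit:
    """Result of fitting one trajectory; ``converged`` False is a flagged
    failure record (e.g. no growth, or no start converged), not an error."""

    params: SchnuteParams | None
    converged: bool
    rss: float
    n_obs: int
    message: str = ""
    n_starts_tried: int = 0

    def rates(self) -> GrowthRates:
        if not self.converged or self.params is None:
            raise ValueError("cannot derive rates from a failed fit")
        return elongation_rates(self.params, rss=self.rss, n_obs=self.n_obs)


# Multi-start grid for (a, b); y1/y2 start at the observed endpoints.
A_STARTS = (0.005, 0.02, 0.05, 0.1)
B_STARTS = (-1.0, 0.25, 0.5, 1.5)


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray,
               tau1: float, tau2: float) -> np.ndarray:
    a, b, y1, y2 = theta
    try:
        p = SchnuteParams(a=a, b=b, y1=y1, y2=y2, tau1=tau1, tau2=tau2)
    except ValueError:
        return np.full_like(y, 1e6)
    pred = _predict(p, t)
    bad = ~np.isfinite(pred)
    if bad.any():
        pred = np.where(bad, 0.0, pred)
        return (pred - y) + bad * 1e6
    return pred - y


def fit_schnute(series: ElongationSeries) -> SchnuteFit:
    """Least-squares Schnute fit with tau1/tau2 fixed at the window ends.

    Deterministic multi-start over a coarse (a, b) grid; the best-RSS
    converged start wins, ties broken by smaller ``|b|``.  Fewer than
    5 observations is a refusal (ValueError); a series with no growth or
    with no converged start returns a flagged failure record.
    """
    t = series.times
    y = series.lengths
    if t.size < MIN_OBS_FOR_FIT:
        raise ValueError(
            f"need at least {MIN_OBS_FOR_FIT} observations, got {t.size}"
        )
    if np.ptp(y) <= 0:
        return SchnuteFit(None, False, float(np.sum((y - y.mean()) ** 2)),
                          t.size, message="no growth (constant series)")
    tau1, tau2 = float(t[0]), float(t[-1])
    y1_0 = max(float(y[0]), 0.05)
    y2_0 = max(float(y[-1]), y1_0 * 1.01)
    ymax = float(y.max())
    # y1 floored at the measurement resolution: a fitted start length far
    # below anything observable makes RER = AER/y explode
    lb = np.array([1e-4, -5.0, 0.05, 0.05])
    ub = np.array([2.0, 5.0, 4.0 * ymax + 1.0, 4.0 * ymax + 1.0])

    best = None  # (rss, abs(b), result)
    n_tried = 0
    for a0 in A_STARTS:
        for b0 in B_STARTS:
            x0 = np.clip(np.array([a0, b0, y1_0, y2_0]), lb, ub)
            n_tried += 1
            try:
                res = least_squares(
                    _residuals, x0, bounds=(lb, ub), args=(t, y, tau1, tau2),
                    xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun ** 2))
            if not math.isfinite(rss) or rss > 1e9:
                continue
            key = (rss, abs(res.x[1]))
            if best is None or key < best[0]:
                best = (key, res)
    if best is None:
        return SchnuteFit(None, False, float("nan"), t.size,
                          message="no start converged", n_starts_tried=n_tried)
    res = best[1]
    a, b, y1, y2 = (float(v) for v in res.x)
    if y2 <= y1:
        return SchnuteFit(None, False, best[0][0], t.size,
                          message="fitted y2 <= y1 (no net growth)",
                          n_starts_tried=n_tried)
    params = SchnuteParams(a=a, b=b, y1=y1, y2=y2, tau1=tau1, tau2=tau2)
    return SchnuteFit(params, True, best[0][0], t.size, message="ok",
                      n_starts_tried=n_tried)


@dataclass(frozen=True)
class FinalLengthRecord:
    final_length: float  # mm, last observed length
    plateau_confirmed: bool
    plateau_start_index: int  # -1 when no plateau found


def detect_final_length(series: ElongationSeries,
                        rel_tol: float = 0.02) -> FinalLengthRecord:
    """Confirm a growth plateau from at least three consecutive images.

    Scans for the earliest run of >= 3 consecutive lengths whose pairwise
    relative differences are all <= ``rel_tol``.  Always returns a record;
    the final length is the last observed length regardless.
    """
    y = series.lengths
    final = float(y[-1]) if y.size else float("nan")
    for i in range(y.size - 2):
        w = y[i:i + 3]
        scale = max(float(np.abs(w).max()), 1e-12)
        if (np.abs(w[:, None] - w[None, :]) / scale <= rel_tol).all():
            return FinalLengthRecord(final, True, i)
    return FinalLengthRecord(final, False, -1)


@dataclass(frozen=True)
class SRRatio:
    """Shoot-to-root ratio from the last image of a seedling."""

    seedling_id: int
    temperature: float
    sr: float
    defined: bool


def shoot_root_ratio(hypocotyl_last: float, radicle_last: float,
                     seedling_id: int = -1,
                     temperature: float = float("nan")) -> SRRatio:
    """Hypocotyl length / radicle length, both from the last image (mm)."""
    if hypocotyl_last < 0 or radicle_last < 0:
        raise ValueError("lengths must be non-negative")
    if radicle_last == 0:
        return SRRatio(seedling_id, temperature, float("nan"), False)
    return SRRatio(seedling_id, temperature,
                   hypocotyl_last / radicle_last, True)


@dataclass(frozen=True)
class ParabolaFit:
    """OLS quadratic of final length vs temperature."""

    coef: tuple[float, float, float]  # (beta0, beta1, beta2), ascending
    vertex_temperature: float  # -beta1 / (2 beta2); NaN when beta2 == 0
    concave: bool  # beta2 < 0
    rss: float
    n: int


def fit_final_length_parabola(
    points: Sequence[tuple[float, float]]
) -> ParabolaFit:
    """Quadratic (degree-2 OLS) fit of final length against temperature."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (temperature, final_length) pairs")
    temps, lengths = pts[:, 0], pts[:, 1]
    if np.unique(temps).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    coef = np.polynomial.polynomial.polyfit(temps, lengths, 2)
    b0, b1, b2 = (float(c) for c in coef)
    fitted = np.polynomial.polynomial.polyval(temps, coef)
    rss = float(np.sum((lengths - fitted) ** 2))
    # curvature indistinguishable from zero at the data's scale (collinear
    # points) must not be reported as concave
    scale = (float(np.abs(lengths).max()) + 1.0) / float(np.ptp(temps)) ** 2
    if abs(b2) < 1e-9 * scale:
        b2 = 0.0
    vertex = float("nan") if b2 == 0 else -b1 / (2.0 * b2)
    return ParabolaFit((b0, b1, b2), vertex, b2 < 0, rss, temps.size)
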