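"""Beta cardinal-temperature response curves and their comparison.

Biological rates (relative elongation rate of an embryo axis, or the
maximum germination rate alpha) respond to constant temperature in a
unimodal way bounded by cardinal temperatures: zero at Tmin, maximal (MR)
at Topt, zero again at Tmax.  We use the Beta response function

    r(T) = MR * [ ((Tmax - T) / (Tmax - Topt))
                  * ((T - Tmin) / (Topt - Tmin)) ** q ] ** delta,
    q = (Topt - Tmin) / (Tmax - Topt),

which equals MR exactly at Topt and 0 at both cardinals for every shape
delta > 0.  Following the convention that no vascular-plant growth occurs
below 0 degC and that 40 degC is lethal to seedlings, Tmin = 0 and
Tmax = 40 are fixed, leaving (MR, Topt, delta) free.

Accession response curves are compared with the extra-sum-of-squares
F-test on nested least-squares fits (one pooled curve vs one curve per
accession), and germination-rate responses are related to elongation-rate
responses by ordinary least-squares regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "BetaParams",
    "BetaFit",
    "CurveComparisonResult",
    "RateRegression",
    "beta_value",
    "fit_beta",
    "compare_curves",
    "correlate_rates",
]

TMIN_DEFAULT = 0.0
TMAX_DEFAULT = 40.0


@dataclass(frozen=True)
class BetaParams:
    """Beta thermal-response parameters; Tmin/Tmax are fixed cardinals."""

    mr: float  # maximum rate, in the rate's own units
    topt: float  # degC
    delta: float  # dimensionless shape
    tmin: float = TMIN_DEFAULT  # degC
    tmax: float = TMAX_DEFAULT  # degC

    def __post_init__(self):
        if not (self.tmin < self.topt < self.tmax):
            raise ValueError("need tmin < topt < tmax")
        if self.mr <= 0:
            raise ValueError("mr must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def _beta(mr, topt, delta, tmin, tmax, T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    q = (topt - tmin) / (tmax - topt)
    x1 = (tmax - T) / (tmax - topt)
    x2 = (T - tmin) / (topt - tmin)
    inside = (T >= tmin) & (T <= tmax)
    with np.errstate(invalid="ignore"):
        core = np.where(inside, x1 * np.where(inside, np.abs(x2), 0.0) ** q,
                        0.0)
        val = mr * np.where(core > 0, core, 0.0) ** delta
    return np.where(inside, val, 0.0)


def beta_value(params: BetaParams, T, *, warn_outside: bool = True):
    """Rate at temperature ``T``; 0 outside [Tmin, Tmax] (with a warning)."""
    p = params
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    if warn_outside and ((T_arr < p.tmin).any() or (T_arr > p.tmax).any()):
        warnings.warn("temperature outside [Tmin, Tmax]; returning 0",
                      stacklevel=2)
    out = _beta(p.mr, p.topt, p.delta, p.tmin, p.tmax, T_arr)
    return float(out[0]) if np.isscalar(T) else out


@dataclass(frozen=True)
class BetaFit:
    params: BetaParams | None
    converged: bool
    rss: float
    n: int
    n_temperatures: int
    message: str = ""


TOPT_STARTS = (20.0, 25.0, 30.0, 35.0)


def _beta_residuals(x, T, r, tmin, tmax, w):
    mr, topt, delta = x
    res = _beta(mr, topt, delta, tmin, tmax, T) - r
    return res if w is None else res * w


def fit_beta(temperatures, rates, *, tmin: float = TMIN_DEFAULT,
             tmax: float = TMAX_DEFAULT, weights=None) -> BetaFit:
    """Bounded least-squares Beta fit to pooled rate points.

    Fits (MR, Topt, delta) with the cardinals fixed, multi-starting on
    Topt in {20, 25, 30, 35}.  Requires rates at >= 4 distinct
    temperatures; an all-zero rate set returns a flagged failure record.
    Optional per-point ``weights`` multiply the residuals (the reported
    RSS is then the weighted RSS).
    """
    T = np.asarray(temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    if T.shape != r.shape or T.ndim != 1:
        raise ValueError("temperatures and rates must be equal-length 1-D")
    n_temps = np.unique(T).size
    if n_temps < 4:
        raise ValueError("need rates at >= 4 distinct temperatures")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    if np.all(r == 0):
        return BetaFit(None, False, 0.0, T.size, n_temps,
                       message="all rates zero")
    mr0 = float(r.max())
    lb = np.array([1e-12, tmin + 0.5, 0.05])
    ub = np.array([10.0 * mr0 + 1.0, tmax - 0.5, 20.0])
    best = None
    w = None if weights is None else np.asarray(weights, dtype=float)
    for topt0 in TOPT_STARTS:
        x0 = np.clip(np.array([mr0, topt0, 1.0]), lb, ub)
        try:
            res = least_squares(
                _beta_residuals, x0, bounds=(lb, ub),
                args=(T, r, tmin, tmax, w),
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if not np.isfinite(rss):
            continue
        if best is None or rss < best[0]:
            best = (rss, res.x.copy())
    if best is None:
        return BetaFit(None, False, float("nan"), T.size, n_temps,
                       message="no start converged")
    rss, x = best
    params = BetaParams(mr=float(x[0]), topt=float(x[1]), delta=float(x[2]),
                        tmin=tmin, tmax=tmax)
    return BetaFit(params, True, rss, T.size, n_temps, message="ok")


@dataclass(frozen=True)
class CurveComparisonResult:
    """Extra-sum-of-squares F-test of one pooled curve vs two curves."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    rss_pooled: float
    rss_separate: float
    different: bool  # verdict at the chosen alpha
    alpha: float


def _per_temperature_weights(T: np.ndarray, r: np.ndarray) -> np.ndarray:
    """1 / (within-temperature SD) weights, estimated from the pooled sample.

    Rate variability grows with the mean rate (multiplicative seedling
    noise), so unweighted residual sums of squares are dominated by the
    warm treatments and the nested F-test is anticonservative.  Weighting
    every point by the reciprocal of its temperature group's standard
    deviation standardizes the residual scale; the same weights are applied
    to the pooled and the separate fits, preserving nesting.
    """
    scale = max(float(np.max(np.abs(r))), 1e-30)
    w = np.empty_like(r)
    for u in np.unique(T):
        m = T == u
        sd = float(np.std(r[m], ddof=1)) if m.sum() > 1 else 0.0
        w[m] = 1.0 / max(sd, 1e-9 * scale)
    return w


def compare_curves(temps_a, rates_a, temps_b, rates_b, *,
                   alpha: float = 0.01,
                   tmin: float = TMIN_DEFAULT,
                   tmax: float = TMAX_DEFAULT) -> CurveComparisonResult:
    """Do two point sets share one Beta response curve?

    Nested-model comparison: the pooled fit (3 parameters) against
    independent fits to each set (6 parameters), on residuals weighted by
    the per-temperature scale of the combined sample.
    F = ((RSS_pooled - RSS_sep) / 3) / (RSS_sep / (n - 6)).
    Verdict "different" iff p < alpha.
    """
    Ta = np.asarray(temps_a, float)
    Tb = np.asarray(temps_b, float)
    ra = np.asarray(rates_a, float)
    rb = np.asarray(rates_b, float)
    Tp = np.concatenate([Ta, Tb])
    rp = np.concatenate([ra, rb])
    w = _per_temperature_weights(Tp, rp)
    wa, wb = w[:Ta.size], w[Ta.size:]
    fa = fit_beta(Ta, ra, tmin=tmin, tmax=tmax, weights=wa)
    fb = fit_beta(Tb, rb, tmin=tmin, tmax=tmax, weights=wb)
    fp = fit_beta(Tp, rp, tmin=tmin, tmax=tmax, weights=w)
    if not (fa.converged and fb.converged and fp.converged):
        raise ValueError("a component Beta fit failed; cannot compare")
    rss_sep = fa.rss + fb.rss
    rss_pooled = fp.rss
    n = Tp.size
    df_num = 3
    df_den = n - 6
    if df_den <= 0:
        raise ValueError("not enough points for the comparison test")
    f_stat = max(rss_pooled - rss_sep, 0.0) / df_num / (rss_sep / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return CurveComparisonResult(
        f_statistic=float(f_stat), df_num=df_num, df_den=df_den, p_value=p,
        rss_pooled=float(rss_pooled), rss_separate=float(rss_sep),
        different=p < alpha, alpha=alpha,
    )


@dataclass(frozen=True)
class RateRegression:
    axis: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def correlate_rates(germ_means: pd.DataFrame,
                    rer_means: pd.DataFrame) -> list[RateRegression]:
    """OLS of mean RER_max on mean germination rate alpha, per axis.

    ``germ_means`` has columns accession, temperature, alpha;
    ``rer_means`` has accession, temperature, axis, rer_max.  Cells are
    matched on (accession, temperature); each axis needs >= 3 matched
    cells with non-degenerate alpha values.
    """
    merged = rer_means.merge(germ_means[["accession", "temperature", "alpha"]],
                             on=["accession", "temperature"], how="inner")
    if merged.empty:
        raise ValueError("no matched accession x temperature cells")
    out = []
    for axis, grp in merged.groupby("axis"):
        x = grp["alpha"].to_numpy(float)
        y = grp["rer_max"].to_numpy(float)
        if x.size < 3:
            raise ValueError(f"axis {axis!r}: need >= 3 matched cells")
        if np.ptp(x) == 0:
            raise ValueError(f"axis {axis!r}: degenerate predictor")
        res = stats.linregress(x, y)
        out.append(RateRegression(axis=str(axis), slope=float(res.slope),
                                  intercept=float(res.intercept),
                                  r_squared=float(res.rvalue ** 2),
                                  p_value=float(res.pvalue), n=int(x.size)))
    return out
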