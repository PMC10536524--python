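"""Non-rectangular-hyperbola (NRH) kinetics for cumulative germination.

Cumulative germination of a seed lot at constant temperature follows a
lag-then-saturate time course.  We model the percentage germinated at time
``t`` (hours) as the lower root of

    theta * G^2 - (alpha * t' + Gmax) * G + alpha * t' * Gmax = 0,
    t' = max(t - tc, 0),

i.e.

    G(t) = 2 * alpha * t' * Gmax
           / (A + sqrt(A^2 - 4 * theta * alpha * t' * Gmax)),
    A = alpha * t' + Gmax,

which rises with initial slope ``alpha`` (% of seeds per hour) after a lag
``tc`` (hours) and saturates at the germinability ``Gmax`` (%).  The
curvature ``theta`` in (0, 1) interpolates between a rectangular hyperbola
(theta -> 0) and the bilinear ramp min(alpha t', Gmax) (theta -> 1).

Fitting is bounded least squares on percentages with a deterministic
multi-start grid; a replicate in which no seed ever germinates is recorded
as a sentinel with Gmax = 0 and no kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GerminationSeries",
    "NRHParams",
    "NRHFit",
    "nrh_value",
    "nrh_inverse",
    "fit_nrh",
    "germination_summary",
]

MIN_OBS_FOR_FIT = 5

# Fit bounds: Gmax in (0, 100] %, alpha in (0, 50] %/h, tc in [0, t_max] h,
# theta in [1e-3, 0.999].
ALPHA_MAX = 50.0
THETA_LO, THETA_HI = 1e-3, 0.999


@dataclass(frozen=True)
class GerminationSeries:
    """Cumulative germination (%) of one replicate at one temperature."""

    accession: str
    replicate: int
    temperature: float
    times: np.ndarray  # hours, strictly increasing
    cumulative_pct: np.ndarray  # %, non-decreasing, within [0, 100]
    n_seeds: int

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        pct = np.asarray(self.cumulative_pct, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cumulative_pct", pct)
        if times.shape != pct.shape or times.ndim != 1:
            raise ValueError("times and cumulative_pct must match in shape")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(pct) < 0):
            raise ValueError("cumulative_pct must be non-decreasing")
        if np.any(pct < 0) or np.any(pct > 100):
            raise ValueError("cumulative_pct must lie in [0, 100]")
        if self.n_seeds <= 0:
            raise ValueError("n_seeds must be positive")

    @classmethod
    def from_counts(cls, accession, replicate, temperature, times,
                    germinated, total) -> "GerminationSeries":
        germinated = np.asarray(germinated, dtype=float)
        return cls(accession, replicate, temperature, times,
                   100.0 * germinated / float(total), int(total))


@dataclass(frozen=True)
class NRHParams:
    gmax: float  # %, asymptotic germinability
    alpha: float  # %/h, initial slope (maximum germination rate)
    tc: float  # h, lag before onset
    theta: float  # curvature in (0, 1)

    def __post_init__(self):
        if not (0 < self.gmax <= 100):
            raise ValueError("gmax must be in (0, 100]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tc < 0:
            raise ValueError("tc must be non-negative")
        if not (0 < self.theta < 1):
            raise ValueError("theta must be in (0, 1)")


def _nrh(gmax: float, alpha: float, tc: float, theta: float, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t - tc, 0.0)
    c = alpha * tp * gmax
    A = alpha * tp + gmax
    disc = A * A - 4.0 * theta * c
    # disc >= (A - 2c/A)^2 >= 0 for theta <= 1; clip guards roundoff only.
    disc = np.maximum(disc, 0.0)
    return 2.0 * c / (A + np.sqrt(disc))


def nrh_value(params: NRHParams, t):
    """Cumulative germination (%) at time ``t`` (hours)."""
    out = _nrh(params.gmax, params.alpha, params.tc, params.theta,
               np.atleast_1d(np.asarray(t, dtype=float)))
    return float(out[0]) if np.isscalar(t) else out


def nrh_inverse(params: NRHParams, g):
    """Time (hours) at which the curve reaches ``g`` percent (g < Gmax).

    Closed form from the defining quadratic:
    t = tc + g (Gmax - theta g) / (alpha (Gmax - g)).
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g >= params.gmax):
        raise ValueError("g must lie in [0, Gmax)")
    tp = g * (params.gmax - params.theta * g) / (
        params.alpha * (params.gmax - g))
    return params.tc + tp


@dataclass(frozen=True)
class NRHFit:
    """Per-replicate fit; ``all_zero`` marks the Gmax = 0 sentinel."""

    params: NRHParams | None
    converged: bool
    rss: float
    n_obs: int
    all_zero: bool = False
    message: str = ""

    @property
    def gmax(self) -> float:
        if self.all_zero:
            return 0.0
        return self.params.gmax if self.params is not None else float("nan")


def _residuals(theta_vec, t, pct):
    gmax, alpha, tc, th = theta_vec
    return _nrh(gmax, alpha, tc, th, t) - pct


def fit_nrh(series: GerminationSeries) -> NRHFit:
    """Bounded least-squares NRH fit with a deterministic multi-start grid.

    Starts combine a crude slope estimate for alpha (x 0.5, 1, 2), the last
    all-zero observation time and 0 for tc, and three curvatures.  Requires
    at least 5 time points; an all-zero series short-circuits to the
    sentinel record.
    """
    t = series.times
    pct = series.cumulative_pct
    if t.size < MIN_OBS_FOR_FIT:
        raise ValueError(
            f"need at least {MIN_OBS_FOR_FIT} time points, got {t.size}"
        )
    if np.all(pct == 0):
        return NRHFit(None, True, 0.0, t.size, all_zero=True,
                      message="no germination (Gmax = 0)")
    tmax = float(t[-1])
    gmax0 = float(np.clip(pct.max(), 1.0, 100.0))
    dif = np.diff(pct)
    dts = np.diff(t)
    slope = float(np.max(dif / dts)) if dif.size else 1.0
    slope = float(np.clip(slope, 1e-3, ALPHA_MAX))
    zero_idx = np.nonzero(pct > 0)[0][0]
    tc0 = float(t[zero_idx - 1]) if zero_idx > 0 else 0.0

    lb = np.array([1e-6, 1e-6, 0.0, THETA_LO])
    ub = np.array([100.0, ALPHA_MAX, tmax, THETA_HI])
    best = None
    for amul in (0.5, 1.0, 2.0):
        for tc_start in (0.0, tc0):
            for th0 in (0.3, 0.7, 0.95):
                x0 = np.clip(
                    np.array([gmax0, slope * amul, tc_start, th0]), lb, ub)
                try:
                    res = least_squares(
                        _residuals, x0, bounds=(lb, ub), args=(t, pct),
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
        return NRHFit(None, False, float("nan"), t.size,
                      message="no start converged")
    rss, x = best
    gmax, alpha, tc, th = (float(v) for v in x)
    th = float(np.clip(th, THETA_LO, THETA_HI))
    params = NRHParams(gmax=gmax, alpha=alpha, tc=tc, theta=th)
    return NRHFit(params, True, rss, t.size, message="ok")


def germination_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean Gmax, alpha and tc per accession x temperature cell.

    ``fits`` is the long per-replicate table with columns
    accession, temperature, replicate, gmax, alpha, tc.  Returns one row
    per accession x temperature with arithmetic means over replicates and
    the replicate count ``n_reps``.  Raises on an empty input.
    """
    required = {"accession", "temperature", "gmax", "alpha", "tc"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    if fits.empty:
        raise ValueError("no replicate fits to summarize")
    out = (
        fits.groupby(["accession", "temperature"], as_index=False)
        .agg(gmax=("gmax", "mean"), alpha=("alpha", "mean"),
             tc=("tc", "mean"), n_reps=("gmax", "size"))
    )
    return out
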