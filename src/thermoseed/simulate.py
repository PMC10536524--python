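"""Synthetic germination / heterotrophic-growth experiments with known truth.

The generator emulates the structure of a constant-temperature dark-growth
experiment on alfalfa accessions: 8 temperature treatments from 5 to 40 degC
(set points; the chambers realise slightly different actual temperatures),
30 seedlings per accession x treatment photographed on a fixed schedule for
radicle and hypocotyl length, and 4 germination replicates per accession x
treatment with cumulative counts of germinated seeds.

Ground truth per accession:

* Beta thermal-response curves for radicle RER_max, hypocotyl RER_max and
  the germination rate alpha;
* a germinability (Gmax) response, itself a broad Beta curve on a wider
  temperature span (seeds germinate at temperatures where seedlings fail);
* a thermal-lag rule tc(T) = lag_degree_hours / T (a fixed heat sum before
  germination onset);
* final-length parabolas per axis with a vertex between 15 and 20 degC and
  a hypocotyl:radicle final-length ratio < 1 (shoot:root ratio below one);
* lognormal seedling-to-seedling variability on RER (larger for radicles
  than hypocotyls), Gaussian measurement noise on lengths, and a high
  mortality probability at 40 degC.

Elongation trajectories are Schnute curves constructed so that the
relative elongation rate at the inflection equals the drawn seedling RER:
with shape b, a = RER * (1 - b).  Germination times are drawn per seed by
inverse-transform sampling of the NRH curve treated as a CDF scaled by
Gmax/100, which makes every cumulative count series monotone by
construction.

The module also houses the treatment-accounting utilities: growing
degree-days and vapour-pressure deficit (Tetens) for the schedule table.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .germination import NRHParams, nrh_inverse
from .schnute import SchnuteParams, predict_length
from .thermal import BetaParams, beta_value

__all__ = [
    "Treatment",
    "AccessionTruth",
    "GroundTruth",
    "SimulationConfig",
    "default_treatments",
    "default_ground_truth",
    "archetype_truths",
    "accessions_from_archetypes",
    "degree_days",
    "vpd",
    "simulate_elongation",
    "simulate_germination",
    "simulate_rate_points",
    "simulate_germination_summaries",
    "simulate_experiment",
]

MIN_PICTURES = 15


@dataclass(frozen=True)
class Treatment:
    """One constant-temperature treatment and its sampling schedule."""

    temp_set: float  # degC, chamber set point
    temp_actual: float  # degC, realised mean
    rh: float  # %, relative humidity (midpoint when a range was logged)
    sampling_frequency: float  # h between pictures
    sampling_period: float  # h, total follow-up

    def __post_init__(self):
        if not (0 < self.rh <= 100):
            raise ValueError("rh must be in (0, 100]")
        if self.sampling_frequency <= 0 or self.sampling_period <= 0:
            raise ValueError("sampling schedule must be positive")

    @property
    def n_pictures(self) -> int:
        """Pictures taken: one at transfer plus one per interval."""
        return int(self.sampling_period // self.sampling_frequency) + 1

    @property
    def meets_min_pictures(self) -> bool:
        return self.n_pictures >= MIN_PICTURES

    def times(self) -> np.ndarray:
        return np.arange(self.n_pictures) * self.sampling_frequency


def default_treatments() -> list[Treatment]:
    """The eight constant-temperature treatments of the reference design.

    Set point, realised temperature, RH, picture frequency and follow-up
    period. The 40 degC chamber logged an RH range (55-100%); its midpoint
    is carried here.  All treatments except 40 degC yield >= 15 pictures.
    """
    rows = [
        (5, 5.0, 74, 48, 672),
        (10, 9.6, 84, 16, 224),
        (15, 14.3, 76, 12, 168),
        (20, 19.2, 74, 8, 112),
        (25, 25.0, 80, 8, 112),
        (30, 30.0, 50, 8, 112),
        (35, 34.2, 65, 12, 168),
        (40, 40.0, 77.5, 168, 1344),
    ]
    return [Treatment(*r) for r in rows]


def degree_days(temp_actual: float, period: float, base: float = 0.0) -> int:
    """Growing degree-days accumulated over ``period`` hours.

    max(T - base, 0) * period / 24, rounded to the nearest integer.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return int(round(max(temp_actual - base, 0.0) * period / 24.0))


def vpd(temp: float, rh: float) -> float:
    """Vapour-pressure deficit (kPa) from Tetens saturation pressure.

    es(T) = 0.6108 * exp(17.27 T / (T + 237.3)); VPD = es * (1 - RH/100).
    """
    if not (0 < rh <= 100):
        raise ValueError("rh must be in (0, 100]")
    es = 0.6108 * math.exp(17.27 * temp / (temp + 237.3))
    return es * (1.0 - rh / 100.0)


def treatments_table(treatments: list[Treatment] | None = None) -> pd.DataFrame:
    """Schedule table with degree-day and VPD accounting columns."""
    treatments = treatments or default_treatments()
    rows = []
    for tr in treatments:
        rows.append({
            "temp_set_c": tr.temp_set,
            "temp_actual_c": tr.temp_actual,
            "rh_pct": tr.rh,
            "vpd_kpa": round(vpd(tr.temp_actual, tr.rh), 2),
            "sampling_frequency_h": tr.sampling_frequency,
            "sampling_period_h": tr.sampling_period,
            "n_pictures": tr.n_pictures,
            "degree_days": degree_days(tr.temp_actual, tr.sampling_period),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AccessionTruth:
    """Generating parameters for one accession."""

    name: str
    archetype: str
    radicle_beta: BetaParams
    hypocotyl_beta: BetaParams
    germination_alpha_beta: BetaParams
    gmax_beta: BetaParams  # percent scale; broad cardinals
    lag_degree_hours: float  # tc(T) = lag_degree_hours / T
    theta: float  # NRH curvature
    radicle_peak_length: float  # mm, parabola peak
    length_vertex_temp: float  # degC, parabola vertex (15-20)
    length_curvature: float  # mm / degC^2
    sr_ratio: float  # hypocotyl:radicle final-length ratio (< 1)
    b_radicle: float = 0.6  # Schnute shape: concave, early inflection
    b_hypocotyl: float = 0.35  # Schnute shape: sigmoid
    cv_radicle: float = 0.25  # lognormal CV of seedling RER
    cv_hypocotyl: float = 0.12
    cv_length: float = 0.10  # lognormal CV of seedling final length
    noise_sigma: float = 0.3  # mm, measurement noise
    mortality_p40: float = 0.8  # P(death before 2nd picture) at 40 degC
    radicle_start: float = 1.5  # mm (selection: radicle > 1 mm)
    hypocotyl_start: float = 0.5  # mm

    def tc_at(self, temp: float) -> float:
        return self.lag_degree_hours / max(temp, 1.0)

    def gmax_at(self, temp: float) -> float:
        return float(np.clip(
            beta_value(self.gmax_beta, temp, warn_outside=False), 0.0, 100.0))

    def final_length_at(self, temp: float, axis: str) -> float:
        peak = self.radicle_peak_length
        if axis == "hypocotyl":
            peak = peak * self.sr_ratio
        val = peak - self.length_curvature * (temp - self.length_vertex_temp) ** 2
        floor = 2.0 if axis == "radicle" else 1.0
        return max(val, floor)

    def rer_beta(self, axis: str) -> BetaParams:
        return self.radicle_beta if axis == "radicle" else self.hypocotyl_beta


GroundTruth = list  # list[AccessionTruth]


def _acc(name, archetype, *, r_mr, r_topt, r_delta, h_mr, h_topt, h_delta,
         a_mr, a_topt, a_delta, g_peak, g_topt, lag, theta, peak_len,
         vertex, curv, sr) -> AccessionTruth:
    return AccessionTruth(
        name=name, archetype=archetype,
        radicle_beta=BetaParams(mr=r_mr, topt=r_topt, delta=r_delta),
        hypocotyl_beta=BetaParams(mr=h_mr, topt=h_topt, delta=h_delta),
        # truth germination-rate curve keeps a small rate at 40 degC: seeds
        # can germinate where seedlings die, so its Tmax sits above 40
        germination_alpha_beta=BetaParams(mr=a_mr, topt=a_topt, delta=a_delta,
                                          tmin=0.0, tmax=42.0),
        gmax_beta=BetaParams(mr=g_peak, topt=g_topt, delta=1.0,
                             tmin=-2.0, tmax=43.0),
        lag_degree_hours=lag, theta=theta, radicle_peak_length=peak_len,
        length_vertex_temp=vertex, length_curvature=curv, sr_ratio=sr,
    )


def default_ground_truth() -> list[AccessionTruth]:
    """Seven accessions spanning three response archetypes.

    The 'sativa' varieties have fast radicles and warm optima; the
    'falcata' variety is slow with a cool optimum and near-equal axes; the
    landraces are fast germinators with divergent optima.  Rates are in
    mm/h/mm for elongation and %/h for germination.
    """
    return [
        _acc("Flamande", "landrace", r_mr=0.054, r_topt=29.4, r_delta=0.55,
             h_mr=0.041, h_topt=28.0, h_delta=0.5, a_mr=3.4, a_topt=30.0,
             a_delta=0.9, g_peak=95.0, g_topt=26.0, lag=420.0, theta=0.75,
             peak_len=30.0, vertex=19.0, curv=0.050, sr=0.78),
        _acc("Demnate3", "landrace", r_mr=0.052, r_topt=32.0, r_delta=0.5,
             h_mr=0.043, h_topt=32.0, h_delta=0.45, a_mr=3.2, a_topt=31.0,
             a_delta=0.9, g_peak=93.0, g_topt=27.0, lag=450.0, theta=0.72,
             peak_len=29.0, vertex=18.5, curv=0.048, sr=0.80),
        _acc("Harpe", "sativa", r_mr=0.059, r_topt=31.0, r_delta=0.55,
             h_mr=0.040, h_topt=29.0, h_delta=0.5, a_mr=3.0, a_topt=27.0,
             a_delta=0.7, g_peak=92.0, g_topt=20.0, lag=500.0, theta=0.75,
             peak_len=32.0, vertex=17.5, curv=0.055, sr=0.80),
        _acc("Luzelle", "sativa", r_mr=0.057, r_topt=30.5, r_delta=0.5,
             h_mr=0.040, h_topt=29.0, h_delta=0.5, a_mr=2.9, a_topt=26.5,
             a_delta=0.7, g_peak=91.0, g_topt=20.5, lag=520.0, theta=0.74,
             peak_len=31.0, vertex=17.0, curv=0.055, sr=0.79),
        _acc("Orca", "sativa", r_mr=0.050, r_topt=35.0, r_delta=0.3,
             h_mr=0.038, h_topt=34.0, h_delta=0.3, a_mr=2.8, a_topt=27.5,
             a_delta=0.7, g_peak=90.0, g_topt=21.0, lag=510.0, theta=0.76,
             peak_len=30.5, vertex=17.5, curv=0.052, sr=0.81),
        _acc("Barmed", "sativa", r_mr=0.050, r_topt=30.0, r_delta=0.5,
             h_mr=0.040, h_topt=29.5, h_delta=0.5, a_mr=2.95, a_topt=27.0,
             a_delta=0.7, g_peak=92.5, g_topt=20.0, lag=495.0, theta=0.75,
             peak_len=31.5, vertex=17.5, curv=0.054, sr=0.80),
        _acc("Krasnokutskaya", "falcata", r_mr=0.042, r_topt=27.0,
             r_delta=0.6, h_mr=0.041, h_topt=26.0, h_delta=0.55, a_mr=2.2,
             a_topt=22.0, a_delta=0.8, g_peak=88.0, g_topt=16.0, lag=650.0,
             theta=0.70, peak_len=28.0, vertex=15.5, curv=0.050, sr=0.95),
    ]


def archetype_truths() -> dict[str, AccessionTruth]:
    """The three generating archetypes, keyed by name."""
    accs = default_ground_truth()
    return {
        "sativa": next(a for a in accs if a.name == "Harpe"),
        "falcata": next(a for a in accs if a.name == "Krasnokutskaya"),
        "landrace": next(a for a in accs if a.name == "Flamande"),
    }


def accessions_from_archetypes(assignment: dict[str, str],
                               rng: np.random.Generator,
                               jitter_cv: float = 0.04
                               ) -> list[AccessionTruth]:
    """Draw accession truths around the named archetypes.

    ``assignment`` maps accession name -> archetype name.  Each rate-like
    parameter is multiplied by an independent lognormal factor with CV
    ``jitter_cv``, keeping accessions of one archetype similar but not
    identical.
    """
    arch = archetype_truths()
    out = []

    def ln(rng):
        sigma = math.sqrt(math.log(1.0 + jitter_cv ** 2))
        return float(rng.lognormal(-0.5 * sigma ** 2, sigma))

    for name, a_name in assignment.items():
        base = arch[a_name]
        out.append(replace(
            base, name=name, archetype=a_name,
            radicle_beta=replace(base.radicle_beta,
                                 mr=base.radicle_beta.mr * ln(rng)),
            hypocotyl_beta=replace(base.hypocotyl_beta,
                                   mr=base.hypocotyl_beta.mr * ln(rng)),
            germination_alpha_beta=replace(
                base.germination_alpha_beta,
                mr=base.germination_alpha_beta.mr * ln(rng)),
            gmax_beta=replace(
                base.gmax_beta,
                mr=float(np.clip(base.gmax_beta.mr * ln(rng), 1.0, 100.0))),
            lag_degree_hours=base.lag_degree_hours * ln(rng),
        ))
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Size and noise knobs for one synthetic experiment."""

    n_seedlings: int = 30  # per accession x treatment (x 2 axes)
    n_replicates: int = 4  # germination replicates
    n_seeds: int = 50  # seeds per germination replicate
    seed: int = 0
    treatments: tuple = tuple(default_treatments())
    noiseless: bool = False  # zero CV and measurement noise (round trips)

    def __post_init__(self):
        if min(self.n_seedlings, self.n_replicates, self.n_seeds) <= 0:
            raise ValueError("all counts must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _seedling_trajectory(truth: AccessionTruth, axis: str, temp: float,
                         rer_target: float, length_mult: float,
                         window: float) -> SchnuteParams | None:
    """Schnute parameters whose inflection RER equals ``rer_target``.

    The accession's final length at this temperature is the curve's
    *asymptote*; the length actually reached by the end of the follow-up
    window is whatever the drawn rate allows (cold treatments end short of
    the ceiling, warm ones sit on it).  This keeps the rate truth and the
    final-length truth mutually consistent.
    """
    if rer_target <= 1e-6:
        return None
    b = truth.b_radicle if axis == "radicle" else truth.b_hypocotyl
    a = rer_target * (1.0 - b)
    y1 = truth.radicle_start if axis == "radicle" else truth.hypocotyl_start
    asym = truth.final_length_at(temp, axis) * length_mult
    if asym <= y1 * 1.05:
        asym = y1 * 1.05  # audit: asymptote at or below start, floored
    u_inf = asym ** b
    u_end = u_inf - (u_inf - y1 ** b) * math.exp(-a * window)
    y2 = u_end ** (1.0 / b)
    return SchnuteParams(a=a, b=b, y1=y1, y2=y2, tau1=0.0, tau2=window)


def simulate_elongation(truth: list[AccessionTruth],
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-seedling axis trajectories on the treatment schedule.

    Returns ``(elongation, ledger)``: the long-format measurement table
    (accession, seedling_id, axis, temp_set_c, temp_actual_c, time_h,
    length_mm) and the per-seedling truth ledger holding the drawn RER and
    the trajectory parameters actually used.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    ledger = []
    for acc in truth:
        for tr in config.treatments:
            times = tr.times()
            for axis in ("radicle", "hypocotyl"):
                beta = acc.rer_beta(axis)
                mean_rer = beta_value(beta, tr.temp_actual,
                                      warn_outside=False)
                cv = 0.0 if config.noiseless else (
                    acc.cv_radicle if axis == "radicle" else acc.cv_hypocotyl)
                for sid in range(1, config.n_seedlings + 1):
                    rer_i = mean_rer * _lognormal_factor(rng, cv)
                    lmult = (1.0 if config.noiseless
                             else _lognormal_factor(rng, acc.cv_length))
                    params = _seedling_trajectory(acc, axis, tr.temp_actual,
                                                  rer_i, lmult,
                                                  float(times[-1]))
                    # 40 degC mortality: most seedlings die before the
                    # second picture, truncating their series
                    t_use = times
                    died = False
                    if tr.temp_set >= 40.0 and not config.noiseless:
                        if rng.random() < acc.mortality_p40:
                            t_use = times[:2]
                            died = True
                    if params is None:
                        y = np.full(t_use.size,
                                    acc.radicle_start if axis == "radicle"
                                    else acc.hypocotyl_start)
                        true_rer = 0.0
                    else:
                        y = predict_length(params, t_use.astype(float))
                        true_rer = rer_i
                    if not config.noiseless and acc.noise_sigma > 0:
                        y = y + rng.normal(0.0, acc.noise_sigma, y.shape)
                        y = np.maximum(y, 0.0)
                    if axis == "radicle":
                        # selection rule: chosen radicles exceed 1 mm
                        y[0] = max(y[0], 1.0)
                    for t, L in zip(t_use, y):
                        rows.append((acc.name, sid, axis, tr.temp_set,
                                     tr.temp_actual, float(t), float(L)))
                    ledger.append({
                        "accession": acc.name, "archetype": acc.archetype,
                        "seedling_id": sid, "axis": axis,
                        "temp_set_c": tr.temp_set,
                        "temp_actual_c": tr.temp_actual,
                        "true_rer_max": float(true_rer),
                        "true_final_length": (
                            float(params.y2) if params is not None
                            else float("nan")),
                        "died": died,
                    })
    elong = pd.DataFrame(rows, columns=[
        "accession", "seedling_id", "axis", "temp_set_c", "temp_actual_c",
        "time_h", "length_mm"])
    return elong, pd.DataFrame(ledger)


def simulate_germination(truth: list[AccessionTruth],
                         config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate cumulative germination counts per replicate.

    Each seed germinates with probability Gmax/100; germination times are
    inverse-transform draws from the NRH curve normalised to a CDF, so
    every cumulative count series is monotone by construction.  Returns
    ``(germination, ledger)`` with the long count table (accession,
    replicate, temp_set_c, time_h, germinated, total) and the
    accession x temperature truth ledger.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    ledger = []
    for acc in truth:
        for tr in config.treatments:
            temp = tr.temp_actual
            alpha = beta_value(acc.germination_alpha_beta, temp,
                               warn_outside=False)
            gmax = acc.gmax_at(temp)
            tc = acc.tc_at(temp)
            # seeds are scored more often than seedlings are photographed:
            # twice per photographic interval, at least every 4 h
            f_g = max(4.0, tr.sampling_frequency / 2.0)
            times = np.arange(f_g, tr.sampling_period + 0.5 * f_g, f_g)
            ledger.append({"accession": acc.name, "archetype": acc.archetype,
                           "temp_set_c": tr.temp_set, "temp_actual_c": temp,
                           "true_gmax": gmax, "true_alpha": alpha,
                           "true_tc": tc, "true_theta": acc.theta})
            for rep in range(1, config.n_replicates + 1):
                if alpha <= 1e-9 or gmax <= 1e-9:
                    counts = np.zeros(times.size, dtype=int)
                else:
                    params = NRHParams(gmax=gmax, alpha=alpha, tc=tc,
                                       theta=acc.theta)
                    u = rng.random(config.n_seeds)
                    germinating = u < gmax / 100.0
                    w = rng.random(int(germinating.sum()))
                    # quantile of the normalised curve; cap away from 1
                    g_at = np.minimum(w, 1.0 - 1e-12) * gmax
                    t_germ = nrh_inverse(params, g_at)
                    counts = (t_germ[None, :] <=
                              times[:, None]).sum(axis=1).astype(int)
                for t, c in zip(times, counts):
                    rows.append((acc.name, rep, tr.temp_set, temp,
                                 float(t), int(c), config.n_seeds))
    germ = pd.DataFrame(rows, columns=[
        "accession", "replicate", "temp_set_c", "temp_actual_c", "time_h",
        "germinated", "total"])
    return germ, pd.DataFrame(ledger)


def simulate_rate_points(beta: BetaParams, temperatures, n_per_temp: int,
                         cv: float, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled individual rate points around a Beta response curve.

    ``n_per_temp`` seedlings at each temperature, each the curve value
    times a mean-1 lognormal factor with coefficient of variation ``cv``.
    """
    temps = np.repeat(np.asarray(temperatures, dtype=float), n_per_temp)
    mean = beta_value(beta, temps, warn_outside=False)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        factors = rng.lognormal(-0.5 * sigma * sigma, sigma, temps.size)
    else:
        factors = np.ones(temps.size)
    return temps, mean * factors


def simulate_germination_summaries(truth: list[AccessionTruth],
                                   treatments: list[Treatment],
                                   rng: np.random.Generator,
                                   n_replicates: int = 4,
                                   n_seeds: int = 50) -> pd.DataFrame:
    """Accession x temperature germination summaries without curve fitting.

    Emulates the output of per-replicate NRH fits followed by replicate
    averaging: Gmax via binomial sampling of n_seeds, alpha and tc via
    mean-1 lognormal estimation noise (CV 8%) per replicate.  Used where
    the multivariate stage is exercised many times and the kinetics stage
    is not under test.
    """
    rows = []
    for acc in truth:
        for tr in treatments:
            temp = tr.temp_actual
            gmax = acc.gmax_at(temp)
            alpha = beta_value(acc.germination_alpha_beta, temp,
                               warn_outside=False)
            tc = acc.tc_at(temp)
            g_hat = rng.binomial(n_seeds, gmax / 100.0,
                                 n_replicates) / n_seeds * 100.0
            sigma = math.sqrt(math.log(1.0 + 0.08 ** 2))
            a_hat = alpha * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                          n_replicates)
            tc_hat = tc * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                        n_replicates)
            rows.append({"accession": acc.name, "archetype": acc.archetype,
                         "temperature": temp,
                         "gmax": float(g_hat.mean()),
                         "alpha": float(a_hat.mean()),
                         "tc": float(tc_hat.mean())})
    return pd.DataFrame(rows)


def simulate_experiment(truth: list[AccessionTruth] | None = None,
                        config: SimulationConfig | None = None,
                        ) -> dict:
    """Full synthetic bundle: treatments, elongation, germination, truth.

    All randomness flows from ``config.seed``; identical configs give
    byte-identical tables.
    """
    truth = truth if truth is not None else default_ground_truth()
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_elong, rng_germ = (np.random.default_rng(s) for s in ss.spawn(2))
    elong, elong_ledger = simulate_elongation(truth, config, rng_elong)
    germ, germ_ledger = simulate_germination(truth, config, rng_germ)
    return {
        "treatments": treatments_table(list(config.treatments)),
        "elongation": elong,
        "elongation_truth": elong_ledger,
        "germination": germ,
        "germination_truth": germ_ledger,
        "truth": truth,
        "config": config,
    }


def truth_to_json(truth: list[AccessionTruth],
                  config: SimulationConfig | None = None) -> str:
    """Serialise the ground-truth ledger (and config) to JSON."""
    payload = {"accessions": [asdict(a) for a in truth]}
    if config is not None:
        cfg = asdict(config)
        cfg["treatments"] = [asdict(t) for t in config.treatments]
        payload["config"] = cfg
    return json.dumps(payload, indent=2, default=float)
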