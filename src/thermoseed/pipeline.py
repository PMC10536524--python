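"""End-to-end orchestration: kinetics fits -> thermal responses -> PCA/HCPC.

``run_pipeline`` consumes the two long-format input tables and writes every
stage product to the output directory:

* germination_fits.csv / germination_means.csv — per-replicate NRH fits and
  accession x temperature means (Gmax, alpha, tc);
* growth_fits.csv — per-seedling Schnute fits with MER, t*, RER_max, final
  length and plateau flag; sr_summary.csv — shoot:root ratios;
* beta_fits.csv — Beta thermal-response parameters per accession x process;
  comparisons.csv — pairwise extra-SS F-tests of radicle response curves;
* eigenvalues_*.csv, contributions_*.csv, clusters_*.csv and *.nwk — the
  multivariate stage for the germination (24-variable) and growth
  (14-variable) matrices;
* correlation.csv — OLS of mean RER_max on mean germination rate alpha;
* run_log.json — seed, package version, row counts, imputation audit.

Fits at the 40 degC treatment are attempted but excluded from the
rate-versus-temperature analyses (lethal temperature; the growth trait
matrix spans the 7 sub-lethal treatments only).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .germination import fit_nrh, germination_summary
from .io import (ensure_dir, iter_elongation_series, iter_germination_series,
                 read_elongation, read_germination)
from .multivariate import build_trait_matrix, linkage_to_newick, run_hcpc, run_pca
from .schnute import detect_final_length, fit_schnute, shoot_root_ratio
from .thermal import compare_curves, correlate_rates, fit_beta

__all__ = ["PipelineConfig", "run_pipeline", "fit_all_germination",
           "fit_all_growth", "fit_thermal_responses"]

log = logging.getLogger("thermoseed")

LETHAL_TEMP_SET = 40.0


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level options; defaults follow the reference analysis."""

    elongation_csv: str
    germination_csv: str
    out_dir: str
    plateau_rel_tol: float = 0.02
    comparison_alpha: float = 0.01
    hcpc_k: int = 3
    hcpc_n_components: int | None = None  # None -> 90% variance rule
    seed: int = 0
    rate_decimals: int = 3
    temp_decimals: int = 1

    def __post_init__(self):
        if not (0 < self.comparison_alpha < 1):
            raise ValueError("comparison_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def fit_all_germination(germ_df: pd.DataFrame) -> pd.DataFrame:
    """NRH fit for every replicate; one row per replicate."""
    rows = []
    for series in iter_germination_series(germ_df):
        fit = fit_nrh(series)
        p = fit.params
        rows.append({
            "accession": series.accession, "replicate": series.replicate,
            "temperature": series.temperature,
            "gmax": fit.gmax,
            "alpha": p.alpha if p else np.nan,
            "tc": p.tc if p else np.nan,
            "theta": p.theta if p else np.nan,
            "rss": fit.rss, "n_obs": fit.n_obs,
            "converged": fit.converged, "all_zero": fit.all_zero,
        })
    return pd.DataFrame(rows)


def fit_all_growth(elong_df: pd.DataFrame,
                   plateau_rel_tol: float = 0.02) -> pd.DataFrame:
    """Schnute fit + rate extraction for every seedling axis."""
    rows = []
    for series in iter_elongation_series(elong_df):
        rec = {
            "accession": series.accession,
            "seedling_id": series.seedling_id, "axis": series.axis,
            "temp_set_c": series.temperature_set,
            "temperature": series.temperature_actual,
            "n_obs": series.n_obs,
        }
        if series.n_obs < 5:
            rec.update(converged=False, message="too few observations")
            rows.append(rec)
            continue
        fit = fit_schnute(series)
        rec.update(converged=fit.converged, message=fit.message,
                   rss=fit.rss)
        if fit.converged and fit.params is not None:
            rates = fit.rates()
            final = detect_final_length(series, plateau_rel_tol)
            rec.update(
                a=fit.params.a, b=fit.params.b,
                y1=fit.params.y1, y2=fit.params.y2,
                mer=rates.aer_max, t_star=rates.t_star,
                rer_max=rates.rer_max,
                inflection_found=rates.inflection_found,
                final_length=final.final_length,
                plateau_confirmed=final.plateau_confirmed,
                last_length=float(series.lengths[-1]),
            )
        else:
            rec.update(last_length=float(series.lengths[-1]))
        rows.append(rec)
    return pd.DataFrame(rows)


def shoot_root_summary(growth_fits: pd.DataFrame) -> pd.DataFrame:
    """Per-seedling S:R ratios (last image) and accession means."""
    wide = growth_fits.pivot_table(
        index=["accession", "temp_set_c", "temperature", "seedling_id"],
        columns="axis", values="last_length", aggfunc="first").reset_index()
    records = []
    for _, row in wide.iterrows():
        if not np.isfinite(row.get("hypocotyl", np.nan)) or \
                not np.isfinite(row.get("radicle", np.nan)):
            continue
        sr = shoot_root_ratio(float(row["hypocotyl"]), float(row["radicle"]),
                              seedling_id=int(row["seedling_id"]),
                              temperature=float(row["temperature"]))
        records.append({"accession": row["accession"],
                        "temperature": row["temperature"],
                        "seedling_id": sr.seedling_id,
                        "sr": sr.sr, "defined": sr.defined})
    per_seedling = pd.DataFrame(records)
    if per_seedling.empty:
        return per_seedling
    means = (per_seedling[per_seedling["defined"]]
             .groupby(["accession", "temperature"], as_index=False)
             .agg(mean_sr=("sr", "mean"), n=("sr", "size")))
    return means


def fit_thermal_responses(growth_fits: pd.DataFrame,
                          germ_means: pd.DataFrame) -> pd.DataFrame:
    """Beta fits per accession x process (radicle, hypocotyl, germination).

    Elongation uses the pooled per-seedling RER_max below the lethal
    treatment; germination uses the replicate-mean alpha at every
    temperature.
    """
    rows = []
    ok = growth_fits[(growth_fits["converged"] == True)  # noqa: E712
                     & (growth_fits["temp_set_c"] < LETHAL_TEMP_SET)]
    for (acc, axis), grp in ok.groupby(["accession", "axis"]):
        fit = fit_beta(grp["temperature"].to_numpy(float),
                       grp["rer_max"].to_numpy(float))
        p = fit.params
        rows.append({"accession": acc, "process": axis,
                     "mr": p.mr if p else np.nan,
                     "topt": p.topt if p else np.nan,
                     "delta": p.delta if p else np.nan,
                     "tmin": p.tmin if p else 0.0,
                     "tmax": p.tmax if p else 40.0,
                     "rss": fit.rss, "n": fit.n,
                     "converged": fit.converged})
    for acc, grp in germ_means.groupby("accession"):
        # at T = Tmax the Beta value is identically zero, so cells at the
        # fixed upper cardinal cannot inform the fit; drop them
        sub = grp.dropna(subset=["alpha"])
        sub = sub[sub["temperature"] < 40.0]
        fit = fit_beta(sub["temperature"].to_numpy(float),
                       sub["alpha"].to_numpy(float))
        p = fit.params
        rows.append({"accession": acc, "process": "germination",
                     "mr": p.mr if p else np.nan,
                     "topt": p.topt if p else np.nan,
                     "delta": p.delta if p else np.nan,
                     "tmin": p.tmin if p else 0.0,
                     "tmax": p.tmax if p else 40.0,
                     "rss": fit.rss, "n": fit.n,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def pairwise_comparisons(growth_fits: pd.DataFrame, axis: str = "radicle",
                         alpha: float = 0.01) -> pd.DataFrame:
    """Extra-SS F-test for every accession pair on one axis."""
    ok = growth_fits[(growth_fits["converged"] == True)  # noqa: E712
                     & (growth_fits["axis"] == axis)
                     & (growth_fits["temp_set_c"] < LETHAL_TEMP_SET)]
    accs = sorted(ok["accession"].unique())
    rows = []
    for a, b in itertools.combinations(accs, 2):
        ga = ok[ok["accession"] == a]
        gb = ok[ok["accession"] == b]
        res = compare_curves(ga["temperature"].to_numpy(float),
                             ga["rer_max"].to_numpy(float),
                             gb["temperature"].to_numpy(float),
                             gb["rer_max"].to_numpy(float), alpha=alpha)
        rows.append({"accession_a": a, "accession_b": b, "axis": axis,
                     "f": res.f_statistic, "df_num": res.df_num,
                     "df_den": res.df_den, "p_value": res.p_value,
                     "different": res.different})
    return pd.DataFrame(rows)


def _growth_rate_means(growth_fits: pd.DataFrame) -> pd.DataFrame:
    ok = growth_fits[(growth_fits["converged"] == True)  # noqa: E712
                     & (growth_fits["temp_set_c"] < LETHAL_TEMP_SET)]
    return (ok.groupby(["accession", "temperature", "axis"], as_index=False)
            .agg(rer_max=("rer_max", "mean"), n=("rer_max", "size")))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns artifacts."""
    out = ensure_dir(config.out_dir)
    elong = read_elongation(config.elongation_csv)
    germ = read_germination(config.germination_csv)
    log.info("inputs: %d elongation rows, %d germination rows",
             len(elong), len(germ))

    germ_fits = fit_all_germination(germ)
    germ_fits.to_csv(out / "germination_fits.csv", index=False)
    germ_means = germination_summary(germ_fits)
    germ_means.to_csv(out / "germination_means.csv", index=False)

    growth_fits = fit_all_growth(elong, config.plateau_rel_tol)
    growth_fits.to_csv(out / "growth_fits.csv", index=False)
    sr = shoot_root_summary(growth_fits)
    sr.to_csv(out / "sr_summary.csv", index=False)

    beta_fits = fit_thermal_responses(growth_fits, germ_means)
    beta_fits.round(6).to_csv(out / "beta_fits.csv", index=False)
    comparisons = pairwise_comparisons(growth_fits,
                                       alpha=config.comparison_alpha)
    comparisons.to_csv(out / "comparisons.csv", index=False)

    # trait matrices; dead germination cells (Gmax = 0, no kinetics) are
    # imputed as alpha 0 and the longest follow-up as a censored lag
    tc_fill = float(germ["time_h"].max())
    gmat = build_trait_matrix(germ_means, "germination24",
                              fill_values={"alpha": 0.0, "tc": tc_fill})
    rer_means = _growth_rate_means(growth_fits)
    wmat = build_trait_matrix(rer_means, "growth14")

    artifacts = {"germination_fits": germ_fits, "germination_means": germ_means,
                 "growth_fits": growth_fits, "sr_summary": sr,
                 "beta_fits": beta_fits, "comparisons": comparisons,
                 "trait_germination": gmat, "trait_growth": wmat}

    for tag, mat in (("germination", gmat), ("growth", wmat)):
        pca = run_pca(mat)
        hcpc = run_hcpc(pca, k=config.hcpc_k,
                        n_components=config.hcpc_n_components)
        pca.eigenvalue_table().round(6).to_csv(
            out / f"eigenvalues_{tag}.csv", index=False)
        pca.contributions.round(6).to_csv(out / f"contributions_{tag}.csv")
        hcpc.labels.to_frame().to_csv(out / f"clusters_{tag}.csv")
        (out / f"dendrogram_{tag}.nwk").write_text(
            linkage_to_newick(hcpc.linkage_matrix, hcpc.labels.index) + "\n")
        artifacts[f"pca_{tag}"] = pca
        artifacts[f"hcpc_{tag}"] = hcpc

    regs = correlate_rates(germ_means, rer_means)
    corr = pd.DataFrame([{"axis": r.axis, "slope": r.slope,
                          "intercept": r.intercept,
                          "r_squared": r.r_squared, "p_value": r.p_value,
                          "n": r.n} for r in regs])
    corr.to_csv(out / "correlation.csv", index=False)
    artifacts["correlation"] = corr

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "rows": {"elongation": int(len(elong)), "germination": int(len(germ))},
        "n_germination_fits": int(len(germ_fits)),
        "n_growth_fits": int(len(growth_fits)),
        "imputed_cells": [list(c) for c in gmat.imputed],
        "config": {k: getattr(config, k) for k in (
            "plateau_rel_tol", "comparison_alpha", "hcpc_k",
            "hcpc_n_components", "rate_decimals", "temp_decimals")},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    artifacts["run_log"] = run_log
    return artifacts
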