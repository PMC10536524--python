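"""Synthetic-experiment generator: schedules, accounting, determinism."""

import numpy as np
import pytest
from dataclasses import replace

import thermoseed as ts
from thermoseed.germination import NRHParams, nrh_value
from thermoseed.io import iter_elongation_series
from thermoseed.simulate import (SimulationConfig, default_ground_truth,
                                 default_treatments, degree_days,
                                 simulate_elongation, simulate_experiment,
                                 simulate_germination, treatments_table, vpd)


def test_default_treatments_match_reference_schedule(treatments):
    assert len(treatments) == 8
    first = treatments[0]
    assert first.temp_actual == 5.0 and first.sampling_period == 672
    # every treatment yields >= 15 pictures except the lethal one
    flags = [t.meets_min_pictures for t in treatments]
    assert flags == [True] * 7 + [False]


@pytest.mark.parametrize(
    "temp,period,expected",
    [(5.0, 672, 140), (9.6, 224, 90), (14.3, 168, 100), (19.2, 112, 90),
     (25.0, 112, 117), (30.0, 112, 140), (34.2, 168, 239),
     (40.0, 1344, 2240)],
)
def test_degree_days_reproduce_schedule_accounting(temp, period, expected):
    assert degree_days(temp, period) == expected


def test_degree_days_edge_cases():
    assert degree_days(0.0, 500.0) == 0
    assert degree_days(-5.0, 500.0) == 0  # below base: no accumulation
    with pytest.raises(ValueError):
        degree_days(20.0, 0.0)


@pytest.mark.parametrize("temp,rh,expected",
                         [(30.0, 50.0, 2.12), (25.0, 80.0, 0.63)])
def test_vpd_matches_reference_rows(temp, rh, expected):
    assert round(vpd(temp, rh), 2) == expected


def test_vpd_saturation_and_range():
    assert vpd(22.0, 100.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        vpd(22.0, 0.0)
    with pytest.raises(ValueError):
        vpd(22.0, 120.0)


def test_treatments_table_carries_accounting_columns():
    tab = treatments_table()
    assert list(tab["degree_days"]) == [140, 90, 100, 90, 117, 140, 239,
                                        2240]
    assert tab.loc[5, "vpd_kpa"] == 2.12  # 30 degC row


def test_seeded_determinism_byte_identical():
    truth = default_ground_truth()[:2]
    cfg = SimulationConfig(n_seedlings=3, n_replicates=2, n_seeds=20,
                           seed=42)
    b1 = simulate_experiment(truth, cfg)
    b2 = simulate_experiment(truth, cfg)
    for key in ("elongation", "germination", "treatments"):
        assert b1[key].to_csv(index=False) == b2[key].to_csv(index=False)


def test_noiseless_round_trip_recovers_seedling_rer():
    """CV = 0, no noise: fitting the simulated trajectories returns each
    seedling's drawn RER_max to 1e-4 relative."""
    truth = default_ground_truth()[:1]
    trts = tuple(t for t in default_treatments()
                 if t.temp_set in (15, 25, 30))
    cfg = SimulationConfig(n_seedlings=2, treatments=trts, noiseless=True,
                           seed=1)
    elong, ledger = simulate_elongation(truth, cfg, np.random.default_rng(1))
    checked = 0
    for s in iter_elongation_series(elong):
        fit = ts.fit_schnute(s)
        assert fit.converged
        row = ledger[(ledger.seedling_id == s.seedling_id)
                     & (ledger.axis == s.axis)
                     & (ledger.temp_set_c == s.temperature_set)]
        true_rer = float(row.true_rer_max.iloc[0])
        assert fit.rates().rer_max == pytest.approx(true_rer, rel=1e-4)
        checked += 1
    assert checked == 12  # 2 seedlings x 2 axes x 3 treatments


def test_default_config_design_shape(default_bundle):
    """30 seedlings x 2 axes per accession x treatment; >= 15 time points
    below the lethal temperature."""
    elong = default_bundle["elongation"]
    counts = (elong.groupby(["accession", "temp_set_c", "axis"])
              ["seedling_id"].nunique())
    assert (counts == 30).all()
    sub = elong[elong.temp_set_c < 40]
    pictures = (sub.groupby(["accession", "temp_set_c", "axis",
                             "seedling_id"])["time_h"].size())
    assert (pictures >= 15).all()
    germ = default_bundle["germination"]
    reps = (germ.groupby(["accession", "temp_set_c"])["replicate"]
            .nunique())
    assert (reps == 4).all()


def test_mortality_truncates_most_series_at_lethal_temperature(
        default_bundle):
    elong = default_bundle["elongation"]
    at40 = elong[elong.temp_set_c == 40]
    pictures = (at40.groupby(["accession", "axis", "seedling_id"])
                ["time_h"].size())
    # death probability 0.8 before the second picture
    assert (pictures == 2).mean() == pytest.approx(0.8, abs=0.1)


def test_zero_germinability_means_zero_counts():
    acc = default_ground_truth()[0]
    dead = replace(acc, gmax_beta=replace(acc.gmax_beta, mr=1e-8))
    cfg = SimulationConfig(n_replicates=2, n_seeds=30, seed=3)
    germ, _ = simulate_germination([dead], cfg, np.random.default_rng(3))
    assert (germ["germinated"] == 0).all()


def test_large_sample_curve_approaches_nrh():
    """n = 1e5 seeds: the empirical cumulative percentage tracks the NRH
    curve to within half a point everywhere."""
    acc = default_ground_truth()[0]
    trt = tuple(t for t in default_treatments() if t.temp_set == 25)
    cfg = SimulationConfig(n_replicates=1, n_seeds=100_000,
                           treatments=trt, seed=5)
    germ, ledger = simulate_germination([acc], cfg, np.random.default_rng(5))
    row = ledger.iloc[0]
    params = NRHParams(gmax=row.true_gmax, alpha=row.true_alpha,
                       tc=row.true_tc, theta=row.true_theta)
    emp = germ["germinated"].to_numpy() / 100_000 * 100.0
    model = nrh_value(params, germ["time_h"].to_numpy(float))
    assert np.max(np.abs(emp - model)) < 0.5


def test_simulated_counts_are_monotone(small_bundle):
    germ = small_bundle["germination"]
    for _, grp in germ.groupby(["accession", "replicate", "temp_set_c"]):
        c = grp.sort_values("time_h")["germinated"].to_numpy()
        assert np.all(np.diff(c) >= 0)


def test_radicle_selection_rule_in_output(small_bundle):
    elong = small_bundle["elongation"]
    rad = elong[elong.axis == "radicle"].sort_values("time_h")
    firsts = rad.groupby(["accession", "temp_set_c", "seedling_id"]).first()
    assert (firsts["length_mm"] >= 1.0).all()
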