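"""Trait matrices, correlation-matrix PCA and HCPC clustering."""

import numpy as np
import pandas as pd
import pytest

from thermoseed.multivariate import (build_trait_matrix, linkage_to_newick,
                                     run_hcpc, run_pca)
from thermoseed.simulate import (accessions_from_archetypes,
                                 default_ground_truth, default_treatments,
                                 simulate_germination_summaries)

ARCHETYPE_ASSIGNMENT = {
    "A1": "sativa", "A2": "sativa", "A3": "sativa", "A4": "sativa",
    "A5": "landrace", "A6": "landrace", "A7": "falcata",
}


def _germ_summaries(rng):
    return simulate_germination_summaries(default_ground_truth(),
                                          default_treatments(), rng)


def _growth_summaries(rng):
    rows = []
    from thermoseed.thermal import beta_value
    for acc in default_ground_truth():
        for tr in default_treatments()[:-1]:  # exclude the lethal treatment
            for axis in ("radicle", "hypocotyl"):
                mean = beta_value(acc.rer_beta(axis), tr.temp_actual,
                                  warn_outside=False)
                rows.append({"accession": acc.name,
                             "temperature": tr.temp_actual, "axis": axis,
                             "rer_max": mean * rng.lognormal(0.0, 0.05)})
    return pd.DataFrame(rows)


def test_trait_matrix_shapes():
    rng = np.random.default_rng(0)
    g = build_trait_matrix(_germ_summaries(rng), "germination24")
    assert g.shape == (7, 24)
    w = build_trait_matrix(_growth_summaries(rng), "growth14")
    assert w.shape == (7, 14)
    # parameter-major, temperature-minor ordering
    assert list(g.data.columns[:3]) == ["gmax_5", "gmax_9.6", "gmax_14.3"]


def test_trait_matrix_single_accession_rejected():
    rng = np.random.default_rng(0)
    one = _germ_summaries(rng).query("accession == 'Harpe'")
    with pytest.raises(ValueError, match="at least 2"):
        build_trait_matrix(one, "germination24")


def test_trait_matrix_missing_cell_named_or_imputed():
    rng = np.random.default_rng(0)
    summ = _germ_summaries(rng)
    summ.loc[(summ.accession == "Harpe") & (summ.temperature == 40.0),
             "alpha"] = np.nan
    with pytest.raises(ValueError, match="Harpe.*alpha_40"):
        build_trait_matrix(summ, "germination24")
    mat = build_trait_matrix(summ, "germination24",
                             fill_values={"alpha": 0.0})
    assert ("Harpe", "alpha_40", 0.0) in mat.imputed
    assert mat.data.loc["Harpe", "alpha_40"] == 0.0


def test_pca_trace_conservation_and_contributions():
    rng = np.random.default_rng(1)
    mat = build_trait_matrix(_germ_summaries(rng), "germination24")
    pca = run_pca(mat)
    assert pca.eigenvalues.sum() == pytest.approx(24.0, abs=1e-9)
    assert np.all(np.diff(pca.eigenvalues) <= 1e-12)
    np.testing.assert_allclose(pca.contributions.sum(axis=0), 100.0,
                               atol=1e-8)
    # rank is limited by the 7 accessions
    assert np.count_nonzero(pca.eigenvalues > 1e-9) <= 6


def test_pca_identical_columns_collapse_to_one_component():
    base = np.random.default_rng(2).normal(size=7)
    df = pd.DataFrame({f"v{i}": base * (i + 1.0) for i in range(5)},
                      index=[f"acc{j}" for j in range(7)])
    pca = run_pca(df)
    assert pca.pct_variance[0] == pytest.approx(100.0, abs=1e-9)


def test_pca_eigenvalues_match_svd_oracle():
    """Eigenvalues agree with an independent SVD of the standardized data."""
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(7, 24)),
                      index=[f"a{i}" for i in range(7)],
                      columns=[f"v{j}" for j in range(24)])
    pca = run_pca(df)
    X = df.to_numpy()
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    sv = np.linalg.svd(Z, compute_uv=False)
    oracle = np.zeros(24)
    oracle[: sv.size] = sv ** 2 / (Z.shape[0] - 1)
    np.testing.assert_allclose(pca.eigenvalues, np.sort(oracle)[::-1],
                               atol=1e-8)


def test_pca_scores_reconstruct_standardized_data():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(7, 14)),
                      index=[f"a{i}" for i in range(7)],
                      columns=[f"v{j}" for j in range(14)])
    pca = run_pca(df)
    recon = pca.scores.to_numpy() @ pca.eigenvectors.to_numpy().T
    np.testing.assert_allclose(recon, pca.standardized.to_numpy(),
                               atol=1e-8)


def test_pca_zero_variance_column_named():
    df = pd.DataFrame({"v0": [1.0, 2.0, 3.0], "v1": [5.0, 5.0, 5.0],
                       "v2": [0.1, 0.4, 0.2]})
    with pytest.raises(ValueError, match="v1"):
        run_pca(df)


def test_hcpc_row_permutation_invariance():
    rng = np.random.default_rng(5)
    summ = _germ_summaries(rng)
    mat = build_trait_matrix(summ, "germination24")
    part1 = run_hcpc(run_pca(mat), k=3).partition()
    shuffled = mat.data.sample(frac=1.0, random_state=1)
    part2 = run_hcpc(run_pca(shuffled), k=3).partition()
    assert set(part1.values()) == set(part2.values())


def test_hcpc_degenerate_cuts():
    rng = np.random.default_rng(6)
    mat = build_trait_matrix(_germ_summaries(rng), "germination24")
    pca = run_pca(mat)
    singletons = run_hcpc(pca, k=7)
    assert sorted(singletons.labels) == list(range(1, 8))
    with pytest.raises(ValueError, match="exceeds"):
        run_hcpc(pca, k=8)


def test_hcpc_duplicated_rows_share_a_cluster():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(6, 8)),
                      index=[f"a{i}" for i in range(6)],
                      columns=[f"v{j}" for j in range(8)])
    df.loc["a5"] = df.loc["a0"] + rng.normal(0.0, 1e-9, 8)
    pca = run_pca(df)
    for k in (2, 3, 4, 5):
        labels = run_hcpc(pca, k=k).labels
        assert labels["a0"] == labels["a5"]


def test_hcpc_recovers_two_separated_groups():
    rng = np.random.default_rng(8)
    a = rng.normal(0.0, 0.1, size=(4, 6))
    b = rng.normal(8.0, 0.1, size=(3, 6))
    df = pd.DataFrame(np.vstack([a, b]),
                      index=[f"g1_{i}" for i in range(4)]
                      + [f"g2_{i}" for i in range(3)],
                      columns=[f"v{j}" for j in range(6)])
    labels = run_hcpc(run_pca(df), k=2).labels
    assert len({labels[f"g1_{i}"] for i in range(4)}) == 1
    assert len({labels[f"g2_{i}"] for i in range(3)}) == 1
    assert labels["g1_0"] != labels["g2_0"]


def test_hcpc_recovers_generating_archetypes():
    """Accessions drawn from three response archetypes cluster back into
    their generating groups in >= 90% of seeded runs (30 here)."""
    rng = np.random.default_rng(11)
    trts = default_treatments()
    ok = 0
    runs = 30
    for _ in range(runs):
        truths = accessions_from_archetypes(ARCHETYPE_ASSIGNMENT, rng)
        summ = simulate_germination_summaries(truths, trts, rng)
        mat = build_trait_matrix(
            summ[["accession", "temperature", "gmax", "alpha", "tc"]],
            "germination24")
        labels = run_hcpc(run_pca(mat), k=3).labels
        groups = {}
        for acc, lab in labels.items():
            groups.setdefault(lab, set()).add(ARCHETYPE_ASSIGNMENT[acc])
        ok += len(groups) == 3 and all(len(v) == 1 for v in groups.values())
    assert ok >= 0.9 * runs


def test_newick_export_contains_all_leaves():
    rng = np.random.default_rng(12)
    mat = build_trait_matrix(_germ_summaries(rng), "germination24")
    hcpc = run_hcpc(run_pca(mat), k=3)
    nwk = linkage_to_newick(hcpc.linkage_matrix, hcpc.labels.index)
    assert nwk.endswith(");")
    for name in mat.data.index:
        assert name in nwk
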