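#!/usr/bin/env python
"""PCA and hierarchical clustering of accession thermal-response profiles.

Builds the 7 x 24 germination and 7 x 14 growth trait matrices, runs
correlation-matrix PCA (eigenvalue tables, variable contributions) and cuts
the Ward tree on the leading components into three groups.
"""

from pathlib import Path

import pandas as pd

from thermoseed.multivariate import (build_trait_matrix, linkage_to_newick,
                                     run_hcpc, run_pca)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    germ_means = pd.read_csv(ROOT / "germination" / "germination_means.csv")
    growth_fits = pd.read_csv(ROOT / "growth" / "growth_fits.csv")
    germ_raw = pd.read_csv(ROOT / "simulation" / "germination.csv")
    out = ROOT / "multivariate"
    out.mkdir(parents=True, exist_ok=True)

    tc_fill = float(germ_raw["time_h"].max())
    gmat = build_trait_matrix(germ_means, "germination24",
                              fill_values={"alpha": 0.0, "tc": tc_fill})
    ok = growth_fits[(growth_fits["converged"])
                     & (growth_fits["temp_set_c"] < 40)]
    rer_means = (ok.groupby(["accession", "temperature", "axis"],
                            as_index=False)
                 .agg(rer_max=("rer_max", "mean")))
    wmat = build_trait_matrix(rer_means, "growth14")

    for tag, mat in (("germination", gmat), ("growth", wmat)):
        pca = run_pca(mat)
        hcpc = run_hcpc(pca, k=3)
        tab = pca.eigenvalue_table()
        tab.round(3).to_csv(out / f"eigenvalues_{tag}.csv", index=False)
        pca.contributions.round(3).to_csv(out / f"contributions_{tag}.csv")
        hcpc.labels.to_frame().to_csv(out / f"clusters_{tag}.csv")
        (out / f"dendrogram_{tag}.nwk").write_text(
            linkage_to_newick(hcpc.linkage_matrix, hcpc.labels.index) + "\n")
        head = tab.head(4).round(2)
        print(f"{tag}: {mat.shape[0]} accessions x {mat.shape[1]} variables; "
              f"clustering on the first {hcpc.n_components} components")
        print(head.to_string(index=False))
        print("three groups:", hcpc.partition(), "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
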