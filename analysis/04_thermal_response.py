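#!/usr/bin/env python
"""Beta cardinal-temperature responses, curve comparisons and correlations.

Fits the Beta model (Tmin = 0, Tmax = 40 fixed) to pooled radicle and
hypocotyl RER_max and to mean germination rates, tests all accession pairs
for distinct radicle response curves (extra-SS F, alpha = 0.01), and
regresses elongation on germination rates across matched cells.
"""

from pathlib import Path

import pandas as pd

from thermoseed.pipeline import (fit_thermal_responses, pairwise_comparisons,
                                 _growth_rate_means)
from thermoseed.thermal import correlate_rates

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    growth_fits = pd.read_csv(ROOT / "growth" / "growth_fits.csv")
    germ_means = pd.read_csv(ROOT / "germination" / "germination_means.csv")
    out = ROOT / "thermal"
    out.mkdir(parents=True, exist_ok=True)

    beta = fit_thermal_responses(growth_fits, germ_means)
    beta.to_csv(out / "beta_fits.csv", index=False)
    print("Beta fits (MR at Topt, cardinals fixed at 0/40 degC):")
    show = beta[["accession", "process", "mr", "topt", "delta"]].copy()
    show["mr"] = show["mr"].round(3)
    show[["topt", "delta"]] = show[["topt", "delta"]].round(1)
    print(show.to_string(index=False))

    comp = pairwise_comparisons(growth_fits, axis="radicle", alpha=0.01)
    comp.to_csv(out / "comparisons.csv", index=False)
    n_diff = int(comp["different"].sum())
    print(f"\nradicle response curves: {n_diff}/{len(comp)} accession pairs "
          f"significantly different at p < 0.01")

    rer_means = _growth_rate_means(growth_fits)
    regs = correlate_rates(germ_means, rer_means)
    corr = pd.DataFrame([{"axis": r.axis, "slope": r.slope,
                          "intercept": r.intercept,
                          "r_squared": r.r_squared, "p_value": r.p_value,
                          "n": r.n} for r in regs])
    corr.to_csv(out / "correlation.csv", index=False)
    print("\ngermination rate vs elongation rate (matched cells):")
    print(corr.round(4).to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
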