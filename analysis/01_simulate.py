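#!/usr/bin/env python
"""Generate the reference synthetic experiment.

Seven alfalfa accessions spanning three response archetypes, eight constant
temperatures (5-40 degC set points), 30 seedlings x 2 axes photographed on
the treatment schedule, and 4 germination replicates of 50 seeds.  Writes
the raw tables plus the ground-truth ledger under results/simulation/.
"""

from pathlib import Path

from thermoseed.simulate import (SimulationConfig, default_ground_truth,
                                 simulate_experiment, truth_to_json)

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"


def main() -> None:
    truth = default_ground_truth()
    cfg = SimulationConfig(seed=SEED)
    bundle = simulate_experiment(truth, cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    bundle["elongation"].to_csv(OUT / "elongation.csv", index=False)
    bundle["germination"].to_csv(OUT / "germination.csv", index=False)
    bundle["treatments"].to_csv(OUT / "treatments.csv", index=False)
    bundle["elongation_truth"].to_csv(OUT / "elongation_truth.csv",
                                      index=False)
    bundle["germination_truth"].to_csv(OUT / "germination_truth.csv",
                                       index=False)
    (OUT / "truth.json").write_text(truth_to_json(truth, cfg) + "\n")
    print(f"treatments:\n{bundle['treatments'].to_string(index=False)}\n")
    print(f"{len(bundle['elongation'])} elongation measurements, "
          f"{len(bundle['germination'])} germination counts -> {OUT}")


if __name__ == "__main__":
    main()
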