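#!/usr/bin/env python
"""Do within-sample gene-pair orderings survive amplification bias?

Builds the replicate-stable REO pair set from the paired high-input
replicates, then scores each low-input replicate by the fraction k/n of
those pairs whose ordering it maintains, sweeping the rank-difference
exclusion fraction from 0 to 30%.

Finding: REO consistency stays ~90% at the gentlest dilution, declines with
input mass, and excluding the pairs with the smallest rank differences
(the ones noise flips first) raises every score — orderings, unlike values,
degrade gracefully.
"""

import argparse
from pathlib import Path

import pandas as pd

from reosig import (
    SimulationConfig,
    consistency_score,
    exclude_small_rank_diff,
    simulate_high_input,
    simulate_low_input,
    stable_pairs_replicates,
    stage_rng,
)

ROOT = Path(__file__).resolve().parent.parent
FRACTIONS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.30)


def run(seed: int) -> None:
    config = SimulationConfig()
    rng = stage_rng(seed, "consistency-sweep")
    high, truth = simulate_high_input(config, rng)
    reference = stable_pairs_replicates(high.sample(high.sample_ids[0]),
                                        high.sample(high.sample_ids[1]))
    refs = {x: (reference if x == 0 else exclude_small_rank_diff(reference, x))
            for x in FRACTIONS}
    rows = []
    for level in config.dilution_levels:
        low = simulate_low_input(truth, level, config.n_technical_replicates, rng)
        for sample_id in low.sample_ids:
            for x in FRACTIONS:
                res = consistency_score(refs[x], low.sample(sample_id))
                rows.append({
                    "input_mass_pg": level.input_mass_pg,
                    "replicate": sample_id,
                    "excluded_fraction": x,
                    "n": res.n, "k": res.k, "score": res.score,
                })
    table = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "consistency_sweep.tsv", sep="\t", index=False)
    pivot = table.pivot_table(index="input_mass_pg", columns="excluded_fraction",
                              values="score").sort_index(ascending=False)
    print(f"stable high-input pairs: {reference.count:,}")
    print("mean consistency score by input mass (rows) and "
          "exclusion fraction (columns):")
    print(pivot.round(4).to_string())


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    run(parser.parse_args().seed)
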