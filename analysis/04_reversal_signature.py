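#!/usr/bin/env python
"""Discover a reversal gene-pair signature and validate it on held-out data.

Finds all gene pairs whose REO is unanimous within each of two simulated
tissue classes but reversed between them, ranks them by the reversal degree
R_ij (geometric mean of the class-wise mean absolute rank differences),
selects the smallest odd panel maximising the training geometric mean of
sensitivity and specificity, and applies the majority vote to a held-out
cohort.

Finding: all 50 planted reversal pairs are recovered and lead the R_ij
ordering (alongside swap-induced pairs of planted genes); a tiny panel
classifies held-out samples perfectly.
"""

import argparse
from pathlib import Path

import pandas as pd

from reosig import SimulationConfig, two_class_study

ROOT = Path(__file__).resolve().parent.parent


def run(seed: int) -> None:
    res = two_class_study(SimulationConfig(), master_seed=seed)
    table = pd.DataFrame([{
        "candidate_pairs": res.n_candidates,
        "planted_pairs": res.n_planted,
        "planted_recovered": res.n_planted_recovered,
        "selected_k": res.selected_k,
        "holdout_sensitivity": res.holdout_sensitivity,
        "holdout_specificity": res.holdout_specificity,
    }])
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "signature_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nrecovered {res.n_planted_recovered}/{res.n_planted} planted pairs "
          f"among {res.n_candidates} candidates; the selected {res.selected_k}-pair "
          f"signature reaches sensitivity {res.holdout_sensitivity:.0%} and "
          f"specificity {res.holdout_specificity:.0%} on held-out samples")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    run(parser.parse_args().seed)
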