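#!/usr/bin/env python
"""Generate the synthetic study the downstream analyses consume.

Writes a full dataset — paired high/low-input dilution ladder with metadata,
two-class cohorts with the planted reversal-pair manifest, dropout-heavy
single-cell matrices and gene lengths — under scratch/study/ (bulky, not a
deliverable), and a small design summary under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from reosig.cli import main as cli

ROOT = Path(__file__).resolve().parent.parent


def run(seed: int) -> None:
    out = ROOT / "scratch" / "study"
    cli.main(
        ["simulate", "--out-dir", str(out), "--seed", str(seed)],
        standalone_mode=False,
    )
    meta = pd.read_csv(out / "sample_metadata.tsv", sep="\t")
    design = (
        meta.groupby("input_mass_pg", as_index=False)
        .agg(n_replicates=("sample_id", "count"))
        .sort_values("input_mass_pg", ascending=False)
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    design.to_csv(results / "study_design.tsv", sep="\t", index=False)
    print("dilution design (input mass in pg, technical replicates):")
    print(design.to_string(index=False))


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    run(parser.parse_args().seed)
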