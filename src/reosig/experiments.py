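"""The three synthetic study designs, packaged as reusable experiments.

These functions wire the generators to the analysis stages exactly the way
the analysis drivers and the reproduction script run them:

* :func:`dilution_study` — paired high/low technical replicates across a
  dilution ladder; fold-change bias and REO consistency per input level.
* :func:`two_class_study` — reversal-pair discovery, signature selection and
  held-out validation on two planted-reversal cohorts.
* :func:`pooling_study` — the repeated pseudo-bulk single-cell experiment.

All randomness flows from one master seed through named stage streams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bias import summarize_bias
from .matrix import ExpressionMatrix
from .pooling import default_group_sizes, repeat_pooling_experiment
from .reo import consistency_score, exclude_small_rank_diff, stable_pairs_replicates
from .signature import classify_matrix, evaluate, find_reversal_pairs, make_signature, select_signature
from .simulate import (
    SimulationConfig,
    simulate_high_input,
    simulate_low_input,
    simulate_single_cells,
    simulate_two_class,
    simulate_two_class_truths,
    stage_rng,
)


def dilution_study(
    config: SimulationConfig,
    master_seed: int,
    n_seeds: int = 20,
    exclude_fraction: float = 0.10,
) -> pd.DataFrame:
    """Bias and consistency across the dilution ladder, median over seeds.

    For each seed: draw a ground truth with paired high-input replicates,
    then for every dilution level draw low-input replicates and record the
    fraction of genes at symmetric fold change >= 2, the CV of the fold
    changes, and the consistency score of the first low-input replicate
    against the high-input replicate-stable pairs, before and after
    excluding the pairs with the smallest rank differences.
    """
    rows = []
    for i in range(n_seeds):
        rng = stage_rng(master_seed, f"dilution-{i}")
        high, truth = simulate_high_input(config, rng)
        reference = stable_pairs_replicates(
            high.sample(high.sample_ids[0]), high.sample(high.sample_ids[1])
        )
        reduced = exclude_small_rank_diff(reference, exclude_fraction)
        for level in config.dilution_levels:
            low = simulate_low_input(truth, level, config.n_technical_replicates, rng)
            summary, _ = summarize_bias(
                low, high, condition="dilution", input_mass_pg=level.input_mass_pg
            )
            query = low.sample(low.sample_ids[0])
            plain = consistency_score(reference, query)
            excl = consistency_score(reduced, query)
            rows.append({
                "seed_index": i,
                "input_mass_pg": level.input_mass_pg,
                "prop_fc_ge_2": summary.prop_fc_ge_threshold,
                "cv_fc": summary.cv,
                "consistency": plain.score,
                "consistency_excluded": excl.score,
                "n_stable_pairs": reference.count,
            })
    per_seed = pd.DataFrame(rows)
    medians = (
        per_seed.groupby("input_mass_pg", as_index=False)
        .median(numeric_only=True)
        .sort_values("input_mass_pg", ascending=False)
        .drop(columns="seed_index")
        .reset_index(drop=True)
    )
    return medians


@dataclass
class TwoClassResult:
    n_candidates: int
    n_planted: int
    n_planted_recovered: int
    selected_k: int
    holdout_sensitivity: float
    holdout_specificity: float


def two_class_study(config: SimulationConfig, master_seed: int) -> TwoClassResult:
    """Discover, select and validate a signature on planted-reversal cohorts.

    Class A plays the positive class (e.g. tumor).  Held-out cohorts are
    drawn around the same class truths with fresh technical noise.
    """
    rng = stage_rng(master_seed, "two-class")
    train_a, train_b, planted = simulate_two_class(config, rng)
    candidates = find_reversal_pairs(train_a, train_b)
    planted_keys = {p.key for p in planted}
    recovered = sum(1 for c in candidates if c.key in planted_keys)
    sig = select_signature(candidates, train_a, train_b,
                           positive_class="A", negative_class="B")

    truth_a, truth_b, _ = simulate_two_class_truths(
        config, stage_rng(master_seed, "two-class")
    )
    rng_holdout = stage_rng(master_seed, "two-class-holdout")

    def cohort(truth: pd.Series, label: str) -> ExpressionMatrix:
        g = len(truth)
        cols = {
            f"{label}_h{s}": truth.to_numpy()
            * rng_holdout.lognormal(0.0, config.high_input_sigma, g)
            for s in range(1, config.n_samples_per_class + 1)
        }
        return ExpressionMatrix(pd.DataFrame(cols, index=truth.index))

    hold_a = cohort(truth_a, "A")
    hold_b = cohort(truth_b, "B")
    labels = pd.concat([
        classify_matrix(hold_a, sig)["label"],
        classify_matrix(hold_b, sig)["label"],
    ])
    truth_labels = pd.Series(
        ["A"] * hold_a.n_samples + ["B"] * hold_b.n_samples, index=labels.index
    )
    outcome = evaluate(labels, truth_labels, positive_class="A")
    return TwoClassResult(
        n_candidates=len(candidates),
        n_planted=len(planted),
        n_planted_recovered=recovered,
        selected_k=sig.k,
        holdout_sensitivity=float(outcome.sensitivity),
        holdout_specificity=float(outcome.specificity),
    )


def pooling_study(
    config: SimulationConfig,
    master_seed: int,
    n_tumor_cells: int = 272,
    n_normal_cells: int = 157,
    n_groups: int = 11,
    n_repeats: int = 100,
    filter_fractions=(0.0, 0.1, 0.2),
) -> tuple[pd.DataFrame, dict]:
    """The pseudo-bulk pooling experiment on planted-reversal single cells.

    The signature (all reversal pairs, as appropriate under heavy dropout) is
    discovered from high-input cohorts; tumor (class A) and normal cells are
    then drawn around the two class truths with the configured ~90% dropout,
    randomly partitioned into pseudo-bulk groups, summed, and classified.
    Returns the aggregate metric table plus a detail dict (group sizes, cell
    zero fractions, signature size).
    """
    rng = stage_rng(master_seed, "two-class")
    train_a, train_b, _ = simulate_two_class(config, rng)
    candidates = find_reversal_pairs(train_a, train_b)
    sig = make_signature(candidates, "tumor", "normal", k="all")

    truth_a, truth_b, _ = simulate_two_class_truths(
        config, stage_rng(master_seed, "two-class")
    )
    rng_cells = stage_rng(master_seed, "single-cells")
    tumor = simulate_single_cells(
        truth_a, n_tumor_cells, rng_cells,
        dropout_target=config.single_cell_dropout,
        sigma=config.single_cell_sigma, prefix="tumor",
    )
    normal = simulate_single_cells(
        truth_b, n_normal_cells, rng_cells,
        dropout_target=config.single_cell_dropout,
        sigma=config.single_cell_sigma, prefix="normal",
    )
    _, aggregate = repeat_pooling_experiment(
        tumor, normal, sig, n_repeats=n_repeats,
        seed=stage_rng(master_seed, "pooling"),
        filter_fractions=filter_fractions, n_groups=n_groups,
    )
    details = {
        "tumor_group_sizes": default_group_sizes(n_tumor_cells, n_groups),
        "normal_group_sizes": default_group_sizes(n_normal_cells, n_groups),
        "tumor_zero_fraction": float((tumor.values == 0).mean()),
        "normal_zero_fraction": float((normal.values == 0).mean()),
        "signature_pairs": sig.k,
    }
    return aggregate, details
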