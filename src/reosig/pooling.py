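"""Pseudo-bulk pooling of single cells and the repeated classification experiment.

Single-cell profiles are dominated by dropout (zero measurements for roughly
90% of genes), which makes within-cell REOs unreliable.  Summing the per-gene
measurements of a random group of cells emulates a low-input bulk sample
(~25 cells at ~10 pg RNA each is ~250 pg) whose REOs are far more stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .signature import ReoSignature, classify_matrix, evaluate, filter_signature_rank_diff


@dataclass
class PoolingPlan:
    """A seeded random partition of cells into pseudo-bulk groups."""

    group_sizes: list[int]
    assignment: np.ndarray  # group index per cell, in cell order

    def __post_init__(self) -> None:
        sizes = np.bincount(self.assignment, minlength=len(self.group_sizes))
        if list(sizes) != list(self.group_sizes):
            raise ValueError("assignment does not realise the declared group sizes")

    @property
    def n_cells(self) -> int:
        return int(self.assignment.size)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


def default_group_sizes(n_cells: int, n_groups: int) -> list[int]:
    """Approximately equal groups: n_groups-1 of size round(n/g), remainder last.

    Reproduces e.g. 272 cells / 11 groups -> 10x25 + 22 and
    157 / 11 -> 10x14 + 17.
    """
    if n_groups < 1:
        raise ValueError("need at least one group")
    if n_groups == 1:
        return [n_cells]
    base = round(n_cells / n_groups)
    remainder = n_cells - base * (n_groups - 1)
    if base < 1 or remainder < 1:
        raise ValueError(
            f"default sizing gives a non-positive group for n_cells={n_cells}, "
            f"n_groups={n_groups}; pass explicit sizes"
        )
    return [base] * (n_groups - 1) + [remainder]


def make_pooling_plan(
    n_cells: int,
    n_groups: int,
    rng: np.random.Generator | int,
    explicit_sizes: Sequence[int] | None = None,
) -> PoolingPlan:
    """Uniform random partition of cells into groups of fixed sizes."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if explicit_sizes is not None:
        sizes = [int(s) for s in explicit_sizes]
        if any(s < 1 for s in sizes):
            raise ValueError("explicit group sizes must be positive")
        if sum(sizes) != n_cells:
            raise ValueError("explicit group sizes must sum to n_cells")
        if len(sizes) != n_groups:
            raise ValueError("explicit_sizes length must equal n_groups")
    else:
        sizes = default_group_sizes(n_cells, n_groups)
    perm = rng.permutation(n_cells)
    assignment = np.empty(n_cells, dtype=np.int64)
    start = 0
    for g, size in enumerate(sizes):
        assignment[perm[start:start + size]] = g
        start += size
    return PoolingPlan(group_sizes=sizes, assignment=assignment)


def pool_sum(cells: ExpressionMatrix, plan: PoolingPlan,
             prefix: str = "pool") -> ExpressionMatrix:
    """Per-gene sum over each group's member cells; the grand total is conserved."""
    if plan.n_cells != cells.n_samples:
        raise ValueError(
            f"plan covers {plan.n_cells} cells but matrix has {cells.n_samples}"
        )
    X = cells.values
    out = np.zeros((cells.n_genes, plan.n_groups))
    for g in range(plan.n_groups):
        out[:, g] = X[:, plan.assignment == g].sum(axis=1)
    cols = [f"{prefix}_{g + 1}" for g in range(plan.n_groups)]
    return ExpressionMatrix(
        pd.DataFrame(out, index=cells.gene_ids, columns=cols), unit=cells.unit
    )


def repeat_pooling_experiment(
    tumor_cells: ExpressionMatrix,
    normal_cells: ExpressionMatrix,
    signature: ReoSignature,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
    filter_fractions: Sequence[float] = (0.0, 0.1, 0.2),
    n_groups: int = 11,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeatedly pool, classify and score pseudo-bulk samples.

    Each repeat draws fresh independent pooling plans for the two classes
    (separate deterministic seed streams), sums the member cells, classifies
    every pseudo-bulk sample against the signature — optionally after
    dropping the pairs most weakly separated in either class — and records
    sensitivity (tumor = positive) and specificity.

    Returns (per-repeat table, aggregate table of mean sensitivity and
    specificity per filter fraction).  Fully reproducible from the seed.
    """
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    if isinstance(seed, np.random.Generator):
        ss = seed.spawn(2)
        rng_t, rng_n = (np.random.default_rng(s) for s in ss)
    else:
        ss = np.random.SeedSequence(seed).spawn(2)
        rng_t = np.random.default_rng(ss[0])
        rng_n = np.random.default_rng(ss[1])

    sig = signature.restrict_to_genes(tumor_cells.gene_ids)
    filtered = {}
    for x in filter_fractions:
        filtered[x] = sig if x == 0 else filter_signature_rank_diff(sig, x)

    rows = []
    for rep in range(1, n_repeats + 1):
        plan_t = make_pooling_plan(tumor_cells.n_samples, n_groups, rng_t)
        plan_n = make_pooling_plan(normal_cells.n_samples, n_groups, rng_n)
        pooled_t = pool_sum(tumor_cells, plan_t, prefix="tumor")
        pooled_n = pool_sum(normal_cells, plan_n, prefix="normal")
        for x, sig_x in filtered.items():
            res_t = classify_matrix(pooled_t, sig_x)
            res_n = classify_matrix(pooled_n, sig_x)
            labels = pd.concat([res_t["label"], res_n["label"]])
            truth = pd.Series(
                [sig_x.positive_class] * pooled_t.n_samples
                + [sig_x.negative_class] * pooled_n.n_samples,
                index=labels.index,
            )
            out = evaluate(labels, truth, positive_class=sig_x.positive_class)
            rows.append({
                "repeat": rep,
                "filter_fraction": x,
                "n_pairs": sig_x.k,
                "sensitivity": out.sensitivity,
                "specificity": out.specificity,
            })
    per_repeat = pd.DataFrame(rows)
    aggregate = (
        per_repeat.groupby("filter_fraction", as_index=False)
        .agg(n_pairs=("n_pairs", "first"),
             mean_sensitivity=("sensitivity", "mean"),
             mean_specificity=("specificity", "mean"))
    )
    return per_repeat, aggregate
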