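"""Amplification-bias evaluation via fold changes.

Low-input RNA profiles are pre-amplified (PCR or IVT), which distorts
expression values relative to paired high-input profiles of the same
material.  The distortion is summarised here by (a) the fraction of genes
whose fold change between the replicate-averaged low- and high-input
profiles is at least 2, and (b) the coefficient of variation of the fold
changes computed over every (low replicate, high replicate) pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def replicate_average(
    matrix: ExpressionMatrix, groups: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Arithmetic mean of technical replicates, one output column per group.

    ``groups`` must partition the matrix's samples: every sample appears in
    exactly one group.
    """
    seen: dict[str, str] = {}
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"replicate group {name!r} is empty")
        for s in members:
            if s not in matrix.sample_ids:
                raise ValueError(f"group {name!r} references unknown sample {s!r}")
            if s in seen:
                raise ValueError(f"sample {s!r} appears in groups {seen[s]!r} and {name!r}")
            seen[s] = name
    orphans = [s for s in matrix.sample_ids if s not in seen]
    if orphans:
        raise ValueError(f"samples referenced in no group: {orphans}")
    cols = {
        name: matrix.data[list(members)].mean(axis=1)
        for name, members in groups.items()
    }
    return ExpressionMatrix(pd.DataFrame(cols), unit=matrix.unit)


def fold_change(
    low: ExpressionMatrix | pd.Series,
    high: ExpressionMatrix | pd.Series,
    zero_policy: str = "exclude",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene fold change of a low-input profile versus its paired high.

    Returns a DataFrame indexed by gene with columns:

    ``fc_directional``
        low / high ratio (NaN where undefined).
    ``fc_symmetric``
        max(ratio, 1/ratio) >= 1, so distortion in either direction counts.
    ``defined``
        False where the zero policy flagged the gene as undefined.

    ``zero_policy='exclude'`` (default) flags any gene with a zero in either
    profile; ``'pseudocount'`` computes (low + c) / (high + c) instead.
    """
    lo = low.data.iloc[:, 0] if isinstance(low, ExpressionMatrix) else low
    hi = high.data.iloc[:, 0] if isinstance(high, ExpressionMatrix) else high
    if isinstance(low, ExpressionMatrix) and low.n_samples != 1:
        raise ValueError("low profile must have exactly one column")
    if isinstance(high, ExpressionMatrix) and high.n_samples != 1:
        raise ValueError("high profile must have exactly one column")
    if list(lo.index) != list(hi.index):
        raise ValueError("low and high profiles must share the same gene universe")
    lo_v = lo.to_numpy(dtype=float)
    hi_v = hi.to_numpy(dtype=float)
    if zero_policy == "exclude":
        defined = (lo_v > 0) & (hi_v > 0)
        ratio = np.full(lo_v.shape, np.nan)
        ratio[defined] = lo_v[defined] / hi_v[defined]
    elif zero_policy == "pseudocount":
        defined = np.ones(lo_v.shape, dtype=bool)
        ratio = (lo_v + pseudocount) / (hi_v + pseudocount)
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        symmetric = np.maximum(ratio, 1.0 / ratio)
    return pd.DataFrame(
        {
            "fc_directional": ratio,
            "fc_symmetric": symmetric,
            "defined": defined,
        },
        index=lo.index,
    )


def proportion_fc_at_least(table: pd.DataFrame, threshold: float = 2.0) -> float:
    """Fraction of defined genes whose symmetric fold change is >= threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    fc = table.loc[table["defined"], "fc_symmetric"]
    if len(fc) == 0:
        raise ValueError("no defined fold changes to evaluate")
    return float((fc >= threshold).sum() / len(fc))


def coefficient_of_variation(values: np.ndarray | Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two values for a CV")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean is zero")
    return float(v.std(ddof=1) / mean)


def cv_of_fold_changes(
    per_pair_fcs: pd.DataFrame | np.ndarray | Sequence[float],
    axis: str = "over_genes",
) -> float:
    """Coefficient of variation of fold changes.

    ``per_pair_fcs`` is either a flat collection of fold changes or a
    gene-by-pairing table holding the directional FC of every
    (low replicate, high replicate) pairing.

    axis='over_genes' (default): CV across genes of each gene's mean FC over
    the replicate pairings — one number per condition/level.
    axis='over_replicate_pairs': mean across genes of each gene's CV over the
    replicate pairings, emphasising pairing-to-pairing variability.
    """
    arr = per_pair_fcs.to_numpy(dtype=float) if isinstance(
        per_pair_fcs, pd.DataFrame
    ) else np.asarray(per_pair_fcs, dtype=float)
    if arr.ndim == 1:
        return coefficient_of_variation(arr)
    if axis == "over_genes":
        has_value = np.isfinite(arr).any(axis=1)
        gene_means = np.nanmean(arr[has_value], axis=1)
        return coefficient_of_variation(gene_means)
    if axis == "over_replicate_pairs":
        cvs = []
        for row in arr:
            row = row[np.isfinite(row)]
            if row.size >= 2 and row.mean() != 0:
                cvs.append(row.std(ddof=1) / row.mean())
        if not cvs:
            raise ValueError("no gene had enough defined pairings for a CV")
        return float(np.mean(cvs))
    raise ValueError(f"unknown axis {axis!r}")


@dataclass
class BiasSummary:
    """Distortion summary for one condition at one input level."""

    condition: str
    input_mass_pg: float
    prop_fc_ge_threshold: float
    cv: float
    n_genes_evaluated: int
    n_genes_undefined: int
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_fc_ge_threshold <= 1.0:
            raise ValueError("prop_fc_ge_threshold must lie in [0, 1]")


def summarize_bias(
    low_reps: ExpressionMatrix,
    high_reps: ExpressionMatrix,
    condition: str,
    input_mass_pg: float,
    threshold: float = 2.0,
    zero_policy: str = "exclude",
    pseudocount: float = 1.0,
    cv_axis: str = "over_genes",
) -> tuple[BiasSummary, pd.DataFrame]:
    """Full bias evaluation for one (condition, input level).

    The headline fold change is computed on replicate-averaged low and high
    profiles; the CV uses the directional FCs of every (low replicate, high
    replicate) pairing.
    """
    low_mean = replicate_average(low_reps, {"low": low_reps.sample_ids})
    high_mean = replicate_average(high_reps, {"high": high_reps.sample_ids})
    table = fold_change(low_mean, high_mean, zero_policy=zero_policy,
                        pseudocount=pseudocount)
    prop = proportion_fc_at_least(table, threshold)

    pair_cols = {}
    for ls in low_reps.sample_ids:
        for hs in high_reps.sample_ids:
            fc = fold_change(low_reps.sample(ls), high_reps.sample(hs),
                             zero_policy=zero_policy, pseudocount=pseudocount)
            pair_cols[f"{ls}|{hs}"] = fc["fc_directional"]
    cv = cv_of_fold_changes(pd.DataFrame(pair_cols), axis=cv_axis)

    summary = BiasSummary(
        condition=condition,
        input_mass_pg=input_mass_pg,
        prop_fc_ge_threshold=prop,
        cv=cv,
        n_genes_evaluated=int(table["defined"].sum()),
        n_genes_undefined=int((~table["defined"]).sum()),
        threshold=threshold,
    )
    return summary, table
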