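"""Synthetic data with the statistical structure of low-input RNA studies.

The generators emulate the study designs the pipeline consumes, with no
download:

* paired high-input technical replicates plus a dilution ladder of low-input
  replicates carrying dilution-dependent multiplicative log-normal noise and
  expression-dependent dropout (lowly expressed genes drop out more);
* two tissue classes whose generative truths differ only in a set of planted
  gene pairs with swapped levels, i.e. guaranteed reversal pairs;
* single-cell matrices with a calibrated ~90% zero fraction per cell.

Every generator is a pure function of (config, rng): identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class DilutionLevel:
    """One rung of the dilution ladder."""

    input_mass_pg: float
    noise_sigma: float
    dropout_base: float

    def __post_init__(self) -> None:
        if self.input_mass_pg <= 0:
            raise ValueError("input mass must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0.0 <= self.dropout_base <= 1.0:
            raise ValueError("dropout base must lie in [0, 1]")


#: Default four-level ladder mirroring a 1000/100/50/25 pg dilution series.
#: The noise sigmas are calibrated so the fraction of genes at symmetric
#: fold change >= 2 (against the paired high-input profile) spans roughly
#: 0.1-0.65 across the ladder; dropout grows as input mass shrinks.
DEFAULT_LADDER = (
    DilutionLevel(1000.0, 0.60, 0.02),
    DilutionLevel(100.0, 1.00, 0.05),
    DilutionLevel(50.0, 1.35, 0.08),
    DilutionLevel(25.0, 1.80, 0.12),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for all generators.

    The log-normal baseline (location/scale on the natural-log scale)
    represents the wide dynamic range of transcript abundances; technical
    noise is multiplicative log-normal, the natural model for ratio-scale
    amplification distortion.
    """

    n_genes: int = 2000
    n_samples_per_class: int = 20
    log_loc: float = 4.0
    log_scale: float = 2.0
    dilution_levels: tuple[DilutionLevel, ...] = DEFAULT_LADDER
    n_technical_replicates: int = 2
    high_input_sigma: float = 0.05
    n_planted_reversal_pairs: int = 50
    planted_rank_separation: int = 200
    single_cell_dropout: float = 0.9
    single_cell_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.log_scale <= 0:
            raise ValueError("log-normal scale must be positive")
        if not 0.0 <= self.single_cell_dropout < 1.0:
            raise ValueError("single-cell dropout target must lie in [0, 1)")
        masses = [lv.input_mass_pg for lv in self.dilution_levels]
        if sorted(masses, reverse=True) != masses:
            raise ValueError("dilution levels must be ordered by decreasing mass")
        sigmas = [lv.noise_sigma for lv in self.dilution_levels]
        if sorted(sigmas) != sigmas:
            raise ValueError("noise sigma must be non-decreasing as mass decreases")
        drops = [lv.dropout_base for lv in self.dilution_levels]
        if sorted(drops) != drops:
            raise ValueError("dropout must be non-decreasing as mass decreases")
        if 2 * self.n_planted_reversal_pairs > self.n_genes:
            raise ValueError("too many planted pairs for the gene universe")


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """One deterministic stream per named stage of a run.

    Streams are derived from (master seed, stage name), so adding stages
    never shifts the randomness of existing ones.
    """
    tag = int.from_bytes(stage.encode("utf-8")[:8].ljust(8, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))


def _dropout_probs(truth: np.ndarray, base: float) -> np.ndarray:
    """Expression-dependent dropout: weight 1 at the lowest-expressed gene,
    linearly down to 0 at the highest (inverse rank)."""
    from scipy.stats import rankdata

    g = truth.size
    ranks = rankdata(truth, method="average")
    w = (g - ranks) / (g - 1)
    return np.clip(base * w, 0.0, 1.0)


def _calibrated_dropout_probs(truth: np.ndarray, target: float) -> np.ndarray:
    """Scale the inverse-rank weights so the mean dropout equals ``target``.

    With weights in [0, 1] averaging 1/2, targets above 0.5 need clipping at
    1, so the scale is found by bisection on mean(min(c*w, 1)) = target.
    """
    from scipy.stats import rankdata

    if target == 0:
        return np.zeros_like(truth)
    g = truth.size
    ranks = rankdata(truth, method="average")
    w = (g - ranks) / (g - 1)
    lo, hi = 0.0, 2.0
    while np.mean(np.minimum(hi * w, 1.0)) < target:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(np.minimum(mid * w, 1.0)) < target:
            lo = mid
        else:
            hi = mid
    return np.minimum(hi * w, 1.0)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_high_input(
    config: SimulationConfig, rng, n_replicates: int | None = None,
    prefix: str = "high",
) -> tuple[ExpressionMatrix, pd.Series]:
    """Reference high-input replicates around a log-normal ground truth.

    Each replicate is truth x exp(N(0, high_input_sigma)) — small technical
    noise, an order of magnitude below any dilution-level sigma.
    """
    rng = _rng(rng)
    n_rep = config.n_technical_replicates if n_replicates is None else n_replicates
    genes = _gene_ids(config.n_genes)
    truth = pd.Series(
        rng.lognormal(config.log_loc, config.log_scale, config.n_genes),
        index=genes, name="truth",
    )
    cols = {}
    for r in range(1, n_rep + 1):
        noise = rng.lognormal(0.0, config.high_input_sigma, config.n_genes) \
            if config.high_input_sigma > 0 else np.ones(config.n_genes)
        cols[f"{prefix}_rep{r}"] = truth.to_numpy() * noise
    mat = ExpressionMatrix(pd.DataFrame(cols, index=genes), unit="arbitrary")
    return mat, truth


def simulate_low_input(
    truth: pd.Series, level: DilutionLevel, n_replicates: int, rng,
    prefix: str | None = None,
) -> ExpressionMatrix:
    """Low-input replicates: multiplicative noise plus expression-dependent dropout."""
    rng = _rng(rng)
    t = truth.to_numpy(dtype=float)
    p_drop = _dropout_probs(t, level.dropout_base)
    prefix = prefix or f"low{level.input_mass_pg:g}pg"
    cols = {}
    for r in range(1, n_replicates + 1):
        noise = rng.lognormal(0.0, level.noise_sigma, t.size) \
            if level.noise_sigma > 0 else np.ones(t.size)
        vals = t * noise
        vals[rng.random(t.size) < p_drop] = 0.0
        cols[f"{prefix}_rep{r}"] = vals
    return ExpressionMatrix(pd.DataFrame(cols, index=truth.index),
                            unit="arbitrary")


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth for one planted reversal pair.

    ``gene_high_a`` is the higher gene in class A's truth; the two genes'
    levels are swapped in class B, so the strict ordering reverses.
    """

    gene_high_a: str
    gene_low_a: str
    rank_separation: int

    @property
    def key(self) -> tuple[str, str]:
        a, b = sorted((self.gene_high_a, self.gene_low_a))
        return (a, b)


def simulate_two_class(
    config: SimulationConfig, rng,
    separations: Sequence[int] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[PlantedPair]]:
    """Two cohorts whose truths differ only by planted level swaps.

    Each planted pair occupies truth-rank positions exactly
    ``planted_rank_separation`` apart (or the per-pair ``separations``), and
    no planted gene is reused.  Swapping the two genes' truth levels in class
    B guarantees opposite strict orderings between the classes.  Note the
    swap also reverses every (planted gene, bystander gene) pair whose
    bystander truth lies between the swapped levels; those induced reversals
    have smaller reversal degrees than the planted pair itself and can be
    enumerated exactly by running discovery on the two truth vectors.
    """
    rng = _rng(rng)
    g = config.n_genes
    p = config.n_planted_reversal_pairs
    seps = list(separations) if separations is not None else \
        [config.planted_rank_separation] * p
    if len(seps) != p:
        raise ValueError("need one separation per planted pair")
    if any(s < 1 or s >= g for s in seps):
        raise ValueError("rank separation infeasible for this gene universe")
    genes = _gene_ids(g)
    truth_a = rng.lognormal(config.log_loc, config.log_scale, g)
    order = np.argsort(truth_a)  # positions in ascending truth order

    used: set[int] = set()
    planted: list[PlantedPair] = []
    for sep in seps:
        placed = False
        for _ in range(10_000):
            lo_pos = int(rng.integers(0, g - sep))
            hi_pos = lo_pos + sep
            if lo_pos in used or hi_pos in used:
                continue
            used.update((lo_pos, hi_pos))
            gene_lo = genes[order[lo_pos]]
            gene_hi = genes[order[hi_pos]]
            planted.append(PlantedPair(gene_high_a=gene_hi, gene_low_a=gene_lo,
                                       rank_separation=sep))
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place planted pairs; reduce their number or separation"
            )

    truth_b = truth_a.copy()
    gene_index = {gid: idx for idx, gid in enumerate(genes)}
    for pp in planted:
        ia, ib = gene_index[pp.gene_high_a], gene_index[pp.gene_low_a]
        truth_b[ia], truth_b[ib] = truth_b[ib], truth_b[ia]

    def _samples(truth: np.ndarray, label: str) -> ExpressionMatrix:
        cols = {}
        for s in range(1, config.n_samples_per_class + 1):
            noise = rng.lognormal(0.0, config.high_input_sigma, g) \
                if config.high_input_sigma > 0 else np.ones(g)
            cols[f"{label}_s{s}"] = truth * noise
        return ExpressionMatrix(pd.DataFrame(cols, index=genes),
                                unit="arbitrary")

    return _samples(truth_a, "A"), _samples(truth_b, "B"), planted


def simulate_two_class_truths(
    config: SimulationConfig, rng,
    separations: Sequence[int] | None = None,
) -> tuple[pd.Series, pd.Series, list[PlantedPair]]:
    """Generate only the two class truth vectors plus the planted pairs."""
    cfg = replace(config, high_input_sigma=0.0, n_samples_per_class=1)
    mat_a, mat_b, planted = simulate_two_class(cfg, rng, separations=separations)
    ta = mat_a.data.iloc[:, 0].rename("truth_a")
    tb = mat_b.data.iloc[:, 0].rename("truth_b")
    return ta, tb, planted


def simulate_single_cells(
    truth: pd.Series, n_cells: int, rng,
    dropout_target: float = 0.9, sigma: float = 1.0,
    prefix: str = "cell",
) -> ExpressionMatrix:
    """Single cells around a bulk truth with a calibrated zero fraction.

    Each cell is truth x exp(N(0, sigma)) followed by independent
    expression-weighted zeroing whose expected per-cell zero fraction equals
    ``dropout_target``.
    """
    rng = _rng(rng)
    t = truth.to_numpy(dtype=float)
    p_drop = _calibrated_dropout_probs(t, dropout_target)
    cols = {}
    for c in range(1, n_cells + 1):
        noise = rng.lognormal(0.0, sigma, t.size) if sigma > 0 else np.ones(t.size)
        vals = t * noise
        vals[rng.random(t.size) < p_drop] = 0.0
        cols[f"{prefix}_{c}"] = vals
    return ExpressionMatrix(pd.DataFrame(cols, index=truth.index),
                            unit="arbitrary")


def simulate_gene_lengths(gene_ids: Sequence[str], rng,
                          low: int = 500, high: int = 20_000) -> pd.Series:
    """Plausible exon lengths (bp) for RPKM fixtures; only ratios matter downstream."""
    rng = _rng(rng)
    return pd.Series(rng.integers(low, high, len(gene_ids)),
                     index=list(gene_ids), name="exon_length_bp")
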