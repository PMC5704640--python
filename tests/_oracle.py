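"""Naive double-loop reference implementations used only as test oracles.

Deliberately simple and quadratic: every pair is visited explicitly, so the
production chunked/vectorized paths can be checked exactly against them at
small gene counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def naive_stable_pairs(df: pd.DataFrame, f: float, strict: bool):
    """All (gene_i, gene_j, direction) stable pairs by explicit counting.

    Genes are canonicalised lexicographically (i < j); direction is +1 when
    gene_i is the higher gene, -1 otherwise.  A pair is stable when one
    strict direction holds in more than f (strict) or at least f (non-strict)
    of the samples; ties never support a direction.
    """
    genes = sorted(str(g) for g in df.index)
    n_samples = df.shape[1]
    out = {}
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            gi, gj = genes[a], genes[b]
            up = down = 0
            for s in df.columns:
                vi, vj = df.at[gi, s], df.at[gj, s]
                if vi > vj:
                    up += 1
                elif vi < vj:
                    down += 1
            for count, direction in ((up, 1), (down, -1)):
                frac = count / n_samples
                if (frac > f) if strict else (frac >= f):
                    out[(gi, gj)] = direction
    return out


def naive_consistency(pairs: dict, query: pd.Series, tie_policy: str = "discordant"):
    """(n, k) by walking the reference pairs one at a time."""
    n = k = 0
    for (gi, gj), direction in pairs.items():
        vi, vj = query[gi], query[gj]
        s = 0 if vi == vj else (1 if vi > vj else -1)
        if s == 0 and tie_policy == "drop":
            continue
        n += 1
        if s == direction:
            k += 1
    return n, k


def naive_exclude(pairs: dict, rank_profiles: pd.DataFrame, x: float) -> dict:
    """Remove the floor(x*n) pairs with the smallest mean |rank_i - rank_j|,
    breaking ties at the cut by (gene_i, gene_j)."""
    scored = []
    for (gi, gj), direction in pairs.items():
        diff = float(np.mean([abs(rank_profiles.at[gi, s] - rank_profiles.at[gj, s])
                              for s in rank_profiles.columns]))
        scored.append((diff, gi, gj, direction))
    scored.sort()
    m = math.floor(x * len(scored))
    return {(gi, gj): d for _, gi, gj, d in scored[m:]}


def naive_reversal_pairs(df_a: pd.DataFrame, df_b: pd.DataFrame):
    """Reversal pairs under within-class unanimity, by explicit loops."""
    stable_a = naive_stable_pairs(df_a, f=1.0, strict=False)
    stable_b = naive_stable_pairs(df_b, f=1.0, strict=False)
    return {
        key: (da, stable_b[key])
        for key, da in stable_a.items()
        if key in stable_b and stable_b[key] == -da
    }
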