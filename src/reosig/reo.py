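"""Relative expression orderings (REOs): stable pairs and consistency scores.

The REO of a gene pair (Gi, Gj) within one profile is simply which of the
two genes is expressed higher.  REOs are invariant under any strictly
increasing per-sample transform, which is what makes them robust to
amplification distortion, batch effects and platform differences.

Two representations of a stable-pair set are provided:

* :class:`MaterializedPairSet` stores the pairs explicitly — exact, simple,
  and fine up to a few thousand genes (millions of pairs).
* :class:`ImplicitPairSet` stores only the defining profiles plus the
  stability rule and evaluates pairs in chunks, so that a 20,000-gene
  universe (~2x10^8 pairs) never has to be materialized.

Both agree exactly; the implicit path is validated against the materialized
one and against a naive double loop in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

#: above this many genes, stable-pair constructors switch to the implicit
#: chunked representation by default
MATERIALIZE_LIMIT = 3000

_EPS = 1e-9


def rank_profile(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Ascending ranks (1 = lowest expression) with average ranks at ties."""
    arr = values.to_numpy(dtype=float) if isinstance(values, pd.Series) else np.asarray(
        values, dtype=float
    )
    if arr.size < 2:
        raise ValueError("need at least two genes to rank")
    if not np.all(np.isfinite(arr)):
        raise ValueError("masked or NaN values must be filtered before ranking")
    ranks = rankdata(arr, method="average")
    if isinstance(values, pd.Series):
        return pd.Series(ranks, index=values.index)
    return ranks


@dataclass
class ConsistencyResult:
    """k of n reference pairs kept their REO direction in the query."""

    n: int
    k: int
    excluded_fraction: float = 0.0
    tie_policy: str = "discordant"

    @property
    def score(self) -> float:
        if self.n == 0:
            raise ValueError("consistency score undefined: no pairs evaluated")
        return self.k / self.n

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"invalid consistency counts k={self.k}, n={self.n}")


def _as_profile(query) -> pd.Series:
    if isinstance(query, ExpressionMatrix):
        if query.n_samples != 1:
            raise ValueError("query must be a single profile")
        return query.data.iloc[:, 0]
    if isinstance(query, pd.Series):
        return query
    return pd.Series(query)


def _align_query(genes: np.ndarray, query) -> np.ndarray:
    q = _as_profile(query).reindex(genes)
    if q.isna().any():
        missing = q.index[q.isna()].tolist()[:5]
        raise ValueError(
            f"reference genes absent from query: {missing}; intersect gene "
            "universes first"
        )
    return q.to_numpy(dtype=float)


def _stability_thresholds(n_samples: int, f: float, strict: bool) -> float:
    """Minimum agreeing-sample count (as a float threshold) for stability."""
    t = f * n_samples
    return t + _EPS if strict else t - _EPS


# ---------------------------------------------------------------------------
# Materialized representation
# ---------------------------------------------------------------------------

@dataclass
class MaterializedPairSet:
    """Explicit list of ordered gene pairs with a fixed REO direction.

    Pairs are stored canonically: genes sorted lexicographically, i < j,
    rows ordered by (gene_i, gene_j).  ``direction`` is +1 when gene_i is the
    higher-expressed gene, -1 when gene_j is.
    """

    genes: np.ndarray
    i: np.ndarray
    j: np.ndarray
    direction: np.ndarray
    mean_rank_diff: np.ndarray | None = None
    provenance: str = ""

    @property
    def count(self) -> int:
        return int(self.i.size)

    def pair_ids(self) -> list[tuple[str, str]]:
        return [(str(self.genes[a]), str(self.genes[b]))
                for a, b in zip(self.i, self.j)]

    def directions_by_pair(self) -> dict[tuple[str, str], int]:
        return {
            (str(self.genes[a]), str(self.genes[b])): int(d)
            for a, b, d in zip(self.i, self.j, self.direction)
        }

    def consistency(self, query, tie_policy: str = "discordant",
                    excluded_fraction: float = 0.0) -> ConsistencyResult:
        q = _align_query(self.genes, query)
        s = np.sign(q[self.i] - q[self.j]).astype(np.int8)
        k = int((s == self.direction).sum())
        if tie_policy == "discordant":
            n = self.count
        elif tie_policy == "drop":
            n = int((s != 0).sum())
        else:
            raise ValueError(f"unknown tie_policy {tie_policy!r}")
        return ConsistencyResult(n=n, k=k, excluded_fraction=excluded_fraction,
                                 tie_policy=tie_policy)

    def exclude_small_rank_diff(self, x: float) -> "MaterializedPairSet":
        if not 0.0 <= x < 1.0:
            raise ValueError("exclusion fraction must lie in [0, 1)")
        if self.mean_rank_diff is None:
            raise ValueError("pair set carries no rank differences")
        m = int(np.floor(x * self.count))
        if m == 0:
            return self
        # ties at the cut broken by canonical (gene_i, gene_j) order
        order = np.lexsort((self.j, self.i, self.mean_rank_diff))
        drop = np.zeros(self.count, dtype=bool)
        drop[order[:m]] = True
        keep = ~drop
        return MaterializedPairSet(
            genes=self.genes,
            i=self.i[keep],
            j=self.j[keep],
            direction=self.direction[keep],
            mean_rank_diff=self.mean_rank_diff[keep],
            provenance=self.provenance + f" | excluded bottom {x:g} by rank diff",
        )


# ---------------------------------------------------------------------------
# Implicit (chunked) representation
# ---------------------------------------------------------------------------

class ImplicitPairSet:
    """Stable-pair set represented by its defining profiles and rule.

    Pairs are never materialized; every query walks the upper triangle of the
    gene-pair lattice in fixed-size row chunks, so memory stays O(chunk x G).
    The rank-difference exclusion is represented by a cutoff value plus a
    deterministic tie budget consumed in canonical pair order.
    """

    def __init__(self, genes: np.ndarray, X: np.ndarray, f: float, strict: bool,
                 provenance: str = "", _excl: tuple[float, int] | None = None,
                 _base: "ImplicitPairSet | None" = None):
        self.genes = genes
        self.X = X
        self.f = f
        self.strict = strict
        self.provenance = provenance
        self.ranks = np.column_stack(
            [rankdata(X[:, s], method="average") for s in range(X.shape[1])]
        )
        self._excl = _excl
        self._count: int | None = None
        self._thr = _stability_thresholds(X.shape[1], f, strict)

    @property
    def excluded(self) -> bool:
        return self._excl is not None

    def _chunk_size(self) -> int:
        G = self.X.shape[0]
        return max(16, int(4_000_000 // max(G, 1)))

    def _chunks(self, q: np.ndarray | None):
        """Yield per-chunk (stable_up, stable_down, qd, rank_diff) arrays.

        The rank-difference exclusion is already applied to the stability
        masks; ``qd`` is the query difference matrix (or None).
        """
        G = self.X.shape[0]
        S = self.X.shape[1]
        step = self._chunk_size()
        col = np.arange(G)
        budget = self._excl[1] if self._excl is not None else 0
        for a in range(0, G, step):
            b = min(a + step, G)
            up = np.zeros((b - a, G), dtype=np.int32)
            down = np.zeros((b - a, G), dtype=np.int32)
            for s in range(S):
                d = self.X[a:b, s][:, None] - self.X[:, s][None, :]
                up += d > 0
                down += d < 0
            su = up > self._thr
            sd = down > self._thr
            tri = col[None, :] > np.arange(a, b)[:, None]
            su &= tri
            sd &= tri
            if self._excl is not None:
                cutoff, _ = self._excl
                md = self._rank_diff_chunk(a, b)
                stable = su | sd
                drop = stable & (md < cutoff)
                if budget > 0:
                    eq = (stable & (md == cutoff)).ravel()
                    idx = np.flatnonzero(eq)[:budget]
                    budget -= idx.size
                    flat = drop.ravel()
                    flat[idx] = True
                su = su & ~drop
                sd = sd & ~drop
            qd = None
            if q is not None:
                qd = q[a:b][:, None] - q[None, :]
            yield a, b, su, sd, qd

    def _rank_diff_chunk(self, a: int, b: int) -> np.ndarray:
        md = np.zeros((b - a, self.X.shape[0]), dtype=np.float64)
        for s in range(self.ranks.shape[1]):
            md += np.abs(self.ranks[a:b, s][:, None] - self.ranks[:, s][None, :])
        md /= self.ranks.shape[1]
        return md

    @property
    def count(self) -> int:
        if self._count is None:
            total = 0
            for _, _, su, sd, _ in self._chunks(None):
                total += int(su.sum()) + int(sd.sum())
            self._count = total
        return self._count

    def consistency(self, query, tie_policy: str = "discordant",
                    excluded_fraction: float | None = None) -> ConsistencyResult:
        if tie_policy not in ("discordant", "drop"):
            raise ValueError(f"unknown tie_policy {tie_policy!r}")
        q = _align_query(self.genes, query)
        n = 0
        k = 0
        ties = 0
        for _, _, su, sd, qd in self._chunks(q):
            stable = su | sd
            n += int(stable.sum())
            k += int((su & (qd > 0)).sum()) + int((sd & (qd < 0)).sum())
            if tie_policy == "drop":
                ties += int((stable & (qd == 0)).sum())
        if tie_policy == "drop":
            n -= ties
        if excluded_fraction is None:
            excluded_fraction = 0.0
        return ConsistencyResult(n=n, k=k, excluded_fraction=excluded_fraction,
                                 tie_policy=tie_policy)

    def exclude_small_rank_diff(self, x: float) -> "ImplicitPairSet":
        if not 0.0 <= x < 1.0:
            raise ValueError("exclusion fraction must lie in [0, 1)")
        if self.excluded:
            raise ValueError("pair set already carries an exclusion; start from "
                             "the unexcluded set")
        m = int(np.floor(x * self.count))
        if m == 0:
            return self
        diffs = []
        for a, b, su, sd, _ in self._chunks(None):
            md = self._rank_diff_chunk(a, b)
            diffs.append(md[su | sd])
        all_diffs = np.concatenate(diffs)
        cutoff = float(np.partition(all_diffs, m - 1)[m - 1])
        below = int((all_diffs < cutoff).sum())
        budget = m - below
        out = ImplicitPairSet(
            self.genes, self.X, self.f, self.strict,
            provenance=self.provenance + f" | excluded bottom {x:g} by rank diff",
            _excl=(cutoff, budget),
        )
        out._count = self.count - m
        return out

    def materialize(self) -> MaterializedPairSet:
        ii, jj, dd, md_list = [], [], [], []
        for a, b, su, sd, _ in self._chunks(None):
            md = self._rank_diff_chunk(a, b)
            for mask, direction in ((su, 1), (sd, -1)):
                r, c = np.nonzero(mask)
                ii.append(r + a)
                jj.append(c)
                dd.append(np.full(r.size, direction, dtype=np.int8))
                md_list.append(md[mask])
        i = np.concatenate(ii) if ii else np.empty(0, dtype=int)
        j = np.concatenate(jj) if jj else np.empty(0, dtype=int)
        d = np.concatenate(dd) if dd else np.empty(0, dtype=np.int8)
        md = np.concatenate(md_list) if md_list else np.empty(0)
        order = np.lexsort((j, i))
        return MaterializedPairSet(
            genes=self.genes, i=i[order], j=j[order], direction=d[order],
            mean_rank_diff=md[order], provenance=self.provenance,
        )


StablePairSet = MaterializedPairSet | ImplicitPairSet


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def _sorted_profiles(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    genes = df.index.to_numpy(dtype=str)
    order = np.argsort(genes, kind="stable")
    return genes[order], df.to_numpy(dtype=float)[order]


def _build_pair_set(df: pd.DataFrame, f: float, strict: bool,
                    materialize: bool | str, provenance: str) -> StablePairSet:
    genes, X = _sorted_profiles(df)
    implicit = ImplicitPairSet(genes, X, f, strict, provenance=provenance)
    if materialize == "auto":
        materialize = len(genes) <= MATERIALIZE_LIMIT
    return implicit.materialize() if materialize else implicit


def stable_pairs_replicates(
    rep1: pd.Series, rep2: pd.Series, materialize: bool | str = "auto",
) -> StablePairSet:
    """Pairs whose strict REO direction is identical in both replicates.

    Pairs tied in either replicate are excluded: a tie does not witness a
    direction.
    """
    if set(rep1.index) != set(rep2.index):
        raise ValueError("replicates must share the same gene universe")
    df = pd.DataFrame({"rep1": rep1, "rep2": rep2.reindex(rep1.index)})
    return _build_pair_set(df, f=1.0, strict=False, materialize=materialize,
                           provenance="replicate-identity")


def stable_pairs_frequency(
    samples: ExpressionMatrix | pd.DataFrame,
    f: float = 0.99,
    strict: bool = True,
    materialize: bool | str = "auto",
) -> StablePairSet:
    """Pairs with one REO direction in more than f (or >= f) of the samples.

    ``strict=True`` (default) implements "maintained in more than 99% of
    samples" as a strict inequality; ``f=1.0, strict=False`` is the
    unanimity rule ("identical REOs in all samples").  Ties count against
    stability.  f <= 0.5 is rejected because the majority direction would be
    ambiguous.
    """
    df = samples.data if isinstance(samples, ExpressionMatrix) else samples
    if df.shape[1] < 2:
        raise ValueError("need at least two samples; use all_pairs for one")
    if not 0.5 < f <= 1.0:
        raise ValueError("stability threshold f must lie in (0.5, 1]")
    rule = f"frequency f={f:g} ({'strict' if strict else 'non-strict'})"
    return _build_pair_set(df, f=f, strict=strict, materialize=materialize,
                           provenance=rule)


def all_pairs(sample: pd.Series, materialize: bool | str = "auto") -> StablePairSet:
    """Every non-tied pair of a single profile, directed by that profile."""
    df = _as_profile(sample).to_frame("sample")
    return _build_pair_set(df, f=1.0, strict=False, materialize=materialize,
                           provenance="all-pairs")


# ---------------------------------------------------------------------------
# Functional API mirroring the pipeline's vocabulary
# ---------------------------------------------------------------------------

def consistency_score(reference: StablePairSet, query,
                      tie_policy: str = "discordant") -> ConsistencyResult:
    """Fraction k/n of reference pairs whose REO the query maintains.

    n is the size of the reference set; a query tie counts as discordant by
    default (``tie_policy='drop'`` removes query-tied pairs from both k and
    n instead).
    """
    if reference.count == 0:
        raise ValueError("reference pair set is empty")
    return reference.consistency(query, tie_policy=tie_policy)


def exclude_small_rank_diff(reference: StablePairSet, x: float) -> StablePairSet:
    """Drop the floor(x*n) reference pairs with the smallest mean rank difference.

    The rank difference of a pair is the mean over the defining profiles of
    |rank_i - rank_j|; pairs with nearly equal expression are the ones whose
    REO flips under measurement noise.  Ties at the cut are broken by
    canonical (gene_i, gene_j) order so the result is deterministic.
    """
    return reference.exclude_small_rank_diff(x)
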