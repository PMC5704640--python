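"""Reversal gene-pair signatures and majority-vote classification.

A reversal pair is stable within each of two sample classes (tumor vs
normal, lymphoma vs breast cancer, ...) but points in opposite directions
between them.  Candidate pairs are ranked by the reversal degree

    R_ij = sqrt( mean|rank_i - rank_j| in class A  x  mean|rank_i - rank_j| in class B )

the geometric mean of the class-wise mean absolute rank differences, so a
pair must be well separated in *both* classes to score highly.  A signature
is the top-k pairs (k odd, chosen as the smallest k attaining the best
geometric mean of sensitivity and specificity on training data) — or all
reversal pairs when dropout-riddled queries make a small panel fragile.
Samples are labelled by majority vote over the measurable signature pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ReversalPair:
    """A gene pair with opposite stable REO directions in two classes.

    ``direction_a`` / ``direction_b`` are +1 when gene_i is the higher gene
    in that class, -1 when gene_j is; they must be opposite.  Genes are
    stored canonically with gene_i < gene_j lexicographically.
    """

    gene_i: str
    gene_j: str
    direction_a: int
    direction_b: int
    rank_diff_a: float
    rank_diff_b: float

    def __post_init__(self) -> None:
        if self.gene_i == self.gene_j:
            raise ValueError("self-pairs are not allowed")
        if self.gene_i > self.gene_j:
            raise ValueError("pair must be stored with gene_i < gene_j")
        if self.direction_a not in (-1, 1) or self.direction_b != -self.direction_a:
            raise ValueError("class directions must be opposite and nonzero")

    @property
    def degree(self) -> float:
        """Reversal degree R_ij (geometric mean of class rank differences)."""
        return reversal_degree(self.rank_diff_a, self.rank_diff_b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)


def reversal_degree(rank_diff_a: float, rank_diff_b: float) -> float:
    """Geometric mean of the two class-wise mean absolute rank differences."""
    if rank_diff_a < 0 or rank_diff_b < 0:
        raise ValueError("rank differences are magnitudes and must be >= 0")
    return math.sqrt(rank_diff_a * rank_diff_b)


def _sorted_candidates(pairs: Sequence[ReversalPair]) -> list[ReversalPair]:
    # descending degree; ties broken lexicographically by gene-id pair
    return sorted(pairs, key=lambda p: (-p.degree, p.gene_i, p.gene_j))


def rank_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-sample ascending average ranks over the matrix's gene universe."""
    X = matrix.values
    return np.column_stack(
        [rankdata(X[:, s], method="average") for s in range(X.shape[1])]
    )


def find_reversal_pairs(
    class_a: ExpressionMatrix,
    class_b: ExpressionMatrix,
    f: float = 1.0,
    strict: bool = False,
    chunk_elems: int = 4_000_000,
) -> list[ReversalPair]:
    """All pairs stable within each class but reversed between classes.

    The within-class rule defaults to unanimity (identical REO in every
    sample of the class); ``f``/``strict`` select a frequency rule instead
    for noisy cohorts.  Returns pairs sorted by descending reversal degree.
    """
    if set(class_a.gene_ids) != set(class_b.gene_ids):
        raise ValueError("classes must share a gene universe; intersect first")
    genes = np.array(sorted(class_a.gene_ids))
    A = class_a.data.loc[genes].to_numpy(dtype=float)
    B = class_b.data.loc[genes].to_numpy(dtype=float)
    if A.shape[1] < 1 or B.shape[1] < 1:
        raise ValueError("each class needs at least one sample")
    RA = np.column_stack([rankdata(A[:, s], method="average")
                          for s in range(A.shape[1])])
    RB = np.column_stack([rankdata(B[:, s], method="average")
                          for s in range(B.shape[1])])
    G = len(genes)
    thr_a = _freq_threshold(A.shape[1], f, strict)
    thr_b = _freq_threshold(B.shape[1], f, strict)
    step = max(16, chunk_elems // max(G, 1))
    col = np.arange(G)
    pairs: list[ReversalPair] = []
    for a0 in range(0, G, step):
        b0 = min(a0 + step, G)
        upA = np.zeros((b0 - a0, G), dtype=np.int32)
        dnA = np.zeros_like(upA)
        for s in range(A.shape[1]):
            d = A[a0:b0, s][:, None] - A[:, s][None, :]
            upA += d > 0
            dnA += d < 0
        upB = np.zeros((b0 - a0, G), dtype=np.int32)
        dnB = np.zeros_like(upB)
        for s in range(B.shape[1]):
            d = B[a0:b0, s][:, None] - B[:, s][None, :]
            upB += d > 0
            dnB += d < 0
        tri = col[None, :] > np.arange(a0, b0)[:, None]
        a_up = upA > thr_a
        a_dn = dnA > thr_a
        b_up = upB > thr_b
        b_dn = dnB > thr_b
        rev = ((a_up & b_dn) | (a_dn & b_up)) & tri
        if not rev.any():
            continue
        rr, cc = np.nonzero(rev)
        mda = np.abs(RA[rr + a0, :] - RA[cc, :]).mean(axis=1)
        mdb = np.abs(RB[rr + a0, :] - RB[cc, :]).mean(axis=1)
        dira = np.where(a_up[rr, cc], 1, -1)
        for r, c, da, ra_, rb_ in zip(rr, cc, dira, mda, mdb):
            pairs.append(ReversalPair(
                gene_i=str(genes[r + a0]), gene_j=str(genes[c]),
                direction_a=int(da), direction_b=int(-da),
                rank_diff_a=float(ra_), rank_diff_b=float(rb_),
            ))
    return _sorted_candidates(pairs)


def _freq_threshold(n_samples: int, f: float, strict: bool) -> float:
    if not 0.5 < f <= 1.0:
        raise ValueError("stability threshold f must lie in (0.5, 1]")
    t = f * n_samples
    return t + 1e-9 if strict else t - 1e-9


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

@dataclass
class ReoSignature:
    """An ordered reversal-pair panel with a majority-vote rule.

    ``pairs`` are sorted by descending reversal degree; ``direction_a`` of
    each pair is the REO pattern of the *positive* class.
    """

    pairs: list[ReversalPair]
    positive_class: str
    negative_class: str
    k_path: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("a signature needs at least one pair")
        seen = set()
        for p in self.pairs:
            if p.key in seen:
                raise ValueError(f"duplicate pair {p.key} in signature")
            seen.add(p.key)

    @property
    def k(self) -> int:
        return len(self.pairs)

    def restrict_to_genes(self, genes: Iterable[str]) -> "ReoSignature":
        """Drop pairs with a gene the target platform does not measure."""
        universe = set(genes)
        kept = [p for p in self.pairs
                if p.gene_i in universe and p.gene_j in universe]
        if not kept:
            raise ValueError("no signature pair is measured on this platform")
        return replace(self, pairs=kept, k_path=None)


def write_signature(signature: ReoSignature, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# positive_class: {signature.positive_class}\n")
        fh.write(f"# negative_class: {signature.negative_class}\n")
        fh.write("gene_i\tgene_j\tdirection_positive\trank_diff_positive\t"
                 "rank_diff_negative\tdegree\n")
        for p in signature.pairs:
            dir_label = "i_higher" if p.direction_a == 1 else "j_higher"
            ra = "NA" if np.isnan(p.rank_diff_a) else repr(float(p.rank_diff_a))
            rb = "NA" if np.isnan(p.rank_diff_b) else repr(float(p.rank_diff_b))
            deg = "NA" if np.isnan(p.degree) else repr(float(p.degree))
            fh.write(f"{p.gene_i}\t{p.gene_j}\t{dir_label}\t{ra}\t{rb}\t{deg}\n")


def read_signature(path: str | Path) -> ReoSignature:
    return _parse_signature(Path(path).read_text())


def _parse_signature(text: str) -> ReoSignature:
    positive = "positive"
    negative = "negative"
    rows = []
    for line in text.splitlines():
        if line.startswith("# positive_class:"):
            positive = line.split(":", 1)[1].strip()
        elif line.startswith("# negative_class:"):
            negative = line.split(":", 1)[1].strip()
        elif line.startswith("#") or line.startswith("gene_i\t") or not line:
            continue
        else:
            rows.append(line.split("\t"))
    pairs = []
    for gi, gj, dir_label, ra, rb, *_ in rows:
        da = 1 if dir_label == "i_higher" else -1
        pairs.append(ReversalPair(
            gene_i=gi, gene_j=gj, direction_a=da, direction_b=-da,
            rank_diff_a=float("nan") if ra == "NA" else float(ra),
            rank_diff_b=float("nan") if rb == "NA" else float(rb),
        ))
    return ReoSignature(pairs=pairs, positive_class=positive,
                        negative_class=negative)


def packaged_signature(name: str = "lymphoma_breast") -> ReoSignature:
    """Load a signature shipped with the package.

    ``lymphoma_breast`` is the published three-pair lymphoma vs breast-cancer
    panel (MMP3/RGS13, EPCAM/CD37, EPCAM/STAP1; the listed first gene of each
    pair is higher in breast cancer).  It carries no rank differences, so it
    supports classification but not rank-difference filtering.
    """
    from importlib.resources import files

    text = files("reosig.data").joinpath(f"{name}_signature.tsv").read_text()
    return _parse_signature(text)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class UnclassifiableError(ValueError):
    """Too few signature pairs are measurable in the sample."""


def classify(sample: pd.Series, signature: ReoSignature,
             min_evaluated: int = 1) -> tuple[str, int, int]:
    """Majority-vote label for one sample.

    A pair is measurable when both genes are present and their values are
    not tied (two zeros — the common single-cell dropout case — are a tie and
    never fabricate a vote; one zero against a positive value is a valid
    strict ordering).  Returns (label, votes_positive, votes_evaluated);
    label is ``'unclassified'`` on an exact split.
    """
    votes_pos = 0
    evaluated = 0
    for p in signature.pairs:
        try:
            vi = sample[p.gene_i]
            vj = sample[p.gene_j]
        except KeyError:
            continue
        if pd.isna(vi) or pd.isna(vj) or vi == vj:
            continue
        evaluated += 1
        s = 1 if vi > vj else -1
        if s == p.direction_a:
            votes_pos += 1
    if evaluated < max(min_evaluated, 1):
        raise UnclassifiableError(
            f"only {evaluated} signature pairs measurable "
            f"(min_evaluated={min_evaluated})"
        )
    if votes_pos * 2 > evaluated:
        label = signature.positive_class
    elif votes_pos * 2 < evaluated:
        label = signature.negative_class
    else:
        label = UNCLASSIFIED
    return label, votes_pos, evaluated


def classify_matrix(matrix: ExpressionMatrix, signature: ReoSignature,
                    min_evaluated: int = 1) -> pd.DataFrame:
    """Vectorized majority vote over all samples of a matrix.

    Signature pairs whose genes the matrix does not measure are dropped for
    all samples (platform restriction); per-sample ties are dropped per
    sample.  Agrees exactly with :func:`classify` column by column.
    """
    present = set(matrix.gene_ids)
    pairs = [p for p in signature.pairs
             if p.gene_i in present and p.gene_j in present]
    if not pairs:
        raise UnclassifiableError("no signature pair is measured in this matrix")
    gi = matrix.data.loc[[p.gene_i for p in pairs]].to_numpy(dtype=float)
    gj = matrix.data.loc[[p.gene_j for p in pairs]].to_numpy(dtype=float)
    dirs = np.array([p.direction_a for p in pairs])[:, None]
    s = np.sign(gi - gj)
    evaluated = (s != 0).sum(axis=0)
    votes_pos = (s == dirs).sum(axis=0)
    if (evaluated < max(min_evaluated, 1)).any():
        bad = [matrix.sample_ids[i]
               for i in np.nonzero(evaluated < max(min_evaluated, 1))[0]]
        raise UnclassifiableError(
            f"samples with too few measurable pairs: {bad[:5]}"
        )
    labels = np.where(
        votes_pos * 2 > evaluated, signature.positive_class,
        np.where(votes_pos * 2 < evaluated, signature.negative_class,
                 UNCLASSIFIED),
    )
    return pd.DataFrame(
        {
            "label": labels,
            "votes_positive": votes_pos,
            "votes_evaluated": evaluated,
        },
        index=matrix.sample_ids,
    )


@dataclass
class ClassificationOutcome:
    """Confusion counts with sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    An ``'unclassified'`` label counts as incorrect for its true class.  When
    a metric's denominator is zero the metric is None (flagged undefined,
    never fabricated).
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def geometric_mean(self) -> float | None:
        se, sp = self.sensitivity, self.specificity
        if se is None or sp is None:
            return None
        return math.sqrt(se * sp)


def evaluate(labels: pd.Series | Sequence[str], truth: pd.Series | Sequence[str],
             positive_class: str) -> ClassificationOutcome:
    """Confusion-matrix evaluation of predicted against true class labels."""
    lab = pd.Series(labels)
    tru = pd.Series(truth)
    if isinstance(labels, pd.Series) and isinstance(truth, pd.Series):
        tru = tru.reindex(lab.index)
        if tru.isna().any():
            raise ValueError("truth labels missing for some samples")
    elif len(lab) != len(tru):
        raise ValueError("labels and truth must align")
    is_pos = tru.to_numpy() == positive_class
    pred_pos = lab.to_numpy() == positive_class
    # an unclassified sample is wrong for its true class
    tp = int((is_pos & pred_pos).sum())
    fn = int((is_pos & ~pred_pos).sum())
    correct_neg = (~is_pos) & (lab.to_numpy() == tru.to_numpy())
    tn = int(correct_neg.sum())
    fp = int(((~is_pos) & ~correct_neg).sum())
    return ClassificationOutcome(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Signature selection and filtering
# ---------------------------------------------------------------------------

def make_signature(candidates: Sequence[ReversalPair], positive_class: str,
                   negative_class: str, k: int | str = "all") -> ReoSignature:
    """Top-k signature (or all candidates, for dropout-heavy applications)."""
    cand = _sorted_candidates(candidates)
    if not cand:
        raise ValueError("no candidate reversal pairs")
    if k == "all":
        chosen = cand
    else:
        if not (isinstance(k, int) and k >= 1):
            raise ValueError("k must be a positive integer or 'all'")
        chosen = cand[:k]
    return ReoSignature(pairs=list(chosen), positive_class=positive_class,
                        negative_class=negative_class)


def select_signature(
    candidates: Sequence[ReversalPair],
    train_a: ExpressionMatrix,
    train_b: ExpressionMatrix,
    positive_class: str = "A",
    negative_class: str = "B",
    k_max: int | None = None,
) -> ReoSignature:
    """Choose the smallest odd k maximising the training geometric mean.

    Walks k = 1, 3, 5, ... over the degree-sorted candidates, classifies the
    training samples of both classes by majority vote and records sensitivity,
    specificity and their geometric mean; the returned signature uses the
    smallest k attaining the maximum.  The k path is kept on the signature
    for inspection.  A geometric mean of 1.0 cannot be improved, so the walk
    stops there.
    """
    cand = _sorted_candidates(candidates)
    if not cand:
        raise ValueError("no candidate reversal pairs to select from")
    if k_max is None:
        k_max = len(cand)
    k_max = min(k_max, len(cand))
    if k_max % 2 == 0:
        k_max -= 1

    def _votes(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        gi = matrix.data.reindex([p.gene_i for p in cand]).to_numpy(dtype=float)
        gj = matrix.data.reindex([p.gene_j for p in cand]).to_numpy(dtype=float)
        s = np.sign(gi - gj)
        s[~np.isfinite(s)] = 0
        dirs = np.array([p.direction_a for p in cand])[:, None]
        pos = (s == dirs) & (s != 0)
        measurable = s != 0
        return np.cumsum(pos, axis=0), np.cumsum(measurable, axis=0)

    pos_a, eval_a = _votes(train_a)
    pos_b, eval_b = _votes(train_b)
    records = []
    best_gm = -1.0
    best_k = None
    for k in range(1, k_max + 1, 2):
        pa, ea = pos_a[k - 1], eval_a[k - 1]
        pb, eb = pos_b[k - 1], eval_b[k - 1]
        tp = int((pa * 2 > ea).sum())
        fn = train_a.n_samples - tp
        tn = int((pb * 2 < eb).sum())
        fp = train_b.n_samples - tn
        out = ClassificationOutcome(tp=tp, tn=tn, fp=fp, fn=fn)
        gm = out.geometric_mean
        gm_val = -1.0 if gm is None else gm
        records.append({"k": k, "sensitivity": out.sensitivity,
                        "specificity": out.specificity, "gm": gm})
        if gm_val > best_gm + 1e-12:
            best_gm = gm_val
            best_k = k
        if gm_val >= 1.0:
            break
    if best_k is None:
        raise ValueError("no k produced a defined geometric mean")
    return ReoSignature(pairs=cand[:best_k], positive_class=positive_class,
                        negative_class=negative_class,
                        k_path=pd.DataFrame.from_records(records))


def filter_signature_rank_diff(signature: ReoSignature, x: float) -> ReoSignature:
    """Drop pairs weakly separated in *either* class.

    Removes the union of the floor(x*n) pairs with the smallest mean absolute
    rank difference in the positive class and the floor(x*n) smallest in the
    negative class (ties broken by canonical pair order).  Weakly separated
    pairs are the ones whose votes flip under dropout and amplification
    noise.
    """
    if not 0.0 <= x < 1.0:
        raise ValueError("filter fraction must lie in [0, 1)")
    n = signature.k
    m = int(math.floor(x * n))
    if m == 0:
        return signature
    pairs = signature.pairs

    def bottom(keyfn) -> set[tuple[str, str]]:
        order = sorted(range(n), key=lambda idx: (keyfn(pairs[idx]),
                                                  pairs[idx].gene_i,
                                                  pairs[idx].gene_j))
        return {pairs[idx].key for idx in order[:m]}

    drop = bottom(lambda p: p.rank_diff_a) | bottom(lambda p: p.rank_diff_b)
    kept = [p for p in pairs if p.key not in drop]
    if not kept:
        raise ValueError("filtering removed every pair; use a smaller fraction")
    return replace(signature, pairs=kept, k_path=None)
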