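import numpy as np
import pandas as pd
import pytest

from reosig import (
    ReoSignature,
    ReversalPair,
    UnclassifiableError,
    classify,
    classify_matrix,
    evaluate,
    filter_signature_rank_diff,
    find_reversal_pairs,
    make_signature,
    packaged_signature,
    reversal_degree,
    select_signature,
    write_signature,
    read_signature,
)
from conftest import em
from _oracle import naive_reversal_pairs


def pair(gi, gj, da=1, ra=10.0, rb=10.0):
    return ReversalPair(gene_i=gi, gene_j=gj, direction_a=da, direction_b=-da,
                        rank_diff_a=ra, rank_diff_b=rb)


class TestFindReversalPairs:
    def test_constructed_reversal_found(self):
        a = em([[5, 6], [1, 2]], genes=["g1", "g2"])
        b = em([[1, 2], [5, 6]], genes=["g1", "g2"])
        out = find_reversal_pairs(a, b)
        assert len(out) == 1
        assert out[0].key == ("g1", "g2")
        assert out[0].direction_a == 1 and out[0].direction_b == -1

    def test_concordant_pair_not_reported(self):
        a = em([[5, 6], [1, 2]], genes=["g1", "g2"])
        b = em([[7, 8], [2, 3]], genes=["g1", "g2"])
        assert find_reversal_pairs(a, b) == []

    def test_six_gene_fixture_matches_brute_force(self):
        # two planted reversals (g1/g2, g3/g4); g5/g6 unstable inside class A
        # g5/g6 sit below every swap interval so they induce no reversal
        a = np.array([
            [9, 9, 9, 9],     # g1 high in A
            [1, 1, 1, 1],     # g2 low in A
            [20, 21, 22, 23],  # g3 high in A
            [11, 12, 13, 14],  # g4 low in A
            [0.30, 0.30, 0.35, 0.25],  # g5 flips against g6 within A
            [0.28, 0.32, 0.30, 0.33],
        ])
        b = np.array([
            [1, 1, 1, 1],      # g1 low in B
            [9, 9, 9, 9],
            [11, 12, 13, 14],  # g3 low in B
            [20, 21, 22, 23],
            [0.2, 0.2, 0.2, 0.2],
            [0.4, 0.4, 0.4, 0.4],
        ])
        genes = [f"g{i+1}" for i in range(6)]
        ma, mb = em(a, genes=genes), em(b, genes=genes)
        found = {p.key: (p.direction_a, p.direction_b)
                 for p in find_reversal_pairs(ma, mb)}
        expected = naive_reversal_pairs(ma.data, mb.data)
        assert found == expected
        assert set(found) == {("g1", "g2"), ("g3", "g4")}

    def test_class_swap_symmetry(self, rng):
        genes = [f"g{i:02d}" for i in range(12)]
        a = em(rng.lognormal(0, 1, size=(12, 4)), genes=genes)
        b = em(rng.lognormal(0, 1, size=(12, 4)), genes=genes)
        fwd = find_reversal_pairs(a, b)
        rev = find_reversal_pairs(b, a)
        assert [p.key for p in fwd] == [p.key for p in rev]
        for pf, pr in zip(fwd, rev):
            assert pf.degree == pytest.approx(pr.degree)
            assert pf.direction_a == pr.direction_b


class TestReversalDegree:
    def test_geometric_mean(self):
        assert reversal_degree(100.0, 400.0) == 200.0

    def test_zero_annihilates(self):
        assert reversal_degree(0.0, 123.0) == 0.0

    def test_fixed_point(self):
        assert reversal_degree(37.5, 37.5) == 37.5


class TestClassify:
    sig = ReoSignature(
        pairs=[pair("a", "b", 1), pair("c", "d", 1), pair("e", "f", -1)],
        positive_class="pos", negative_class="neg",
    )

    def test_two_of_three_votes_positive(self):
        sample = pd.Series({"a": 5, "b": 1, "c": 5, "d": 1, "e": 5, "f": 1})
        label, votes, evaluated = classify(sample, self.sig)
        assert (label, votes, evaluated) == ("pos", 2, 3)

    def test_unanimous_negative(self):
        sample = pd.Series({"a": 1, "b": 5, "c": 1, "d": 5, "e": 5, "f": 1})
        label, votes, evaluated = classify(sample, self.sig)
        assert (label, votes, evaluated) == ("neg", 0, 3)

    def test_even_split_is_unclassified(self):
        sig4 = ReoSignature(
            pairs=[pair("a", "b", 1), pair("c", "d", 1),
                   pair("e", "f", 1), pair("g", "h", 1)],
            positive_class="pos", negative_class="neg",
        )
        sample = pd.Series({"a": 5, "b": 1, "c": 5, "d": 1,
                            "e": 1, "f": 5, "g": 1, "h": 5})
        label, votes, evaluated = classify(sample, sig4)
        assert (label, votes, evaluated) == ("unclassified", 2, 4)

    def test_double_zero_is_unmeasurable_not_a_vote(self):
        sample = pd.Series({"a": 0, "b": 0, "c": 5, "d": 1, "e": 1, "f": 5})
        label, votes, evaluated = classify(sample, self.sig)
        assert evaluated == 2
        assert label == "pos"

    def test_one_zero_is_a_valid_ordering(self):
        sample = pd.Series({"a": 5, "b": 0, "c": 0, "d": 1, "e": 1, "f": 5})
        label, votes, evaluated = classify(sample, self.sig)
        assert (votes, evaluated) == (2, 3)

    def test_too_few_measurable_pairs_raises(self):
        sample = pd.Series({"a": 0, "b": 0})
        with pytest.raises(UnclassifiableError):
            classify(sample, self.sig)

    def test_vote_depends_only_on_pair_multiset(self, rng):
        sample = pd.Series(rng.lognormal(0, 1, 6),
                           index=["a", "b", "c", "d", "e", "f"])
        label, votes, evaluated = classify(sample, self.sig)
        shuffled = ReoSignature(pairs=[self.sig.pairs[i] for i in (2, 0, 1)],
                                positive_class="pos", negative_class="neg")
        assert classify(sample, shuffled) == (label, votes, evaluated)

    def test_classify_matrix_agrees_with_classify(self, rng):
        genes = ["a", "b", "c", "d", "e", "f"]
        mat = em(rng.lognormal(0, 1, size=(6, 8)), genes=genes)
        table = classify_matrix(mat, self.sig)
        for s in mat.sample_ids:
            label, votes, evaluated = classify(mat.sample(s), self.sig)
            assert table.at[s, "label"] == label
            assert table.at[s, "votes_positive"] == votes
            assert table.at[s, "votes_evaluated"] == evaluated

    def test_invariant_under_increasing_transform(self, rng):
        genes = ["a", "b", "c", "d", "e", "f"]
        mat = em(rng.lognormal(0, 1, size=(6, 5)), genes=genes)
        base = classify_matrix(mat, self.sig)["label"]
        transformed = em(np.sqrt(mat.values) * 3 + 1, genes=genes)
        assert (classify_matrix(transformed, self.sig)["label"] == base).all()


class TestEvaluate:
    def test_printed_style_confusion(self):
        labels = ["p"] * 10 + ["p"] * 2 + ["n"] * 8
        truth = ["p"] * 10 + ["n"] * 10
        out = evaluate(labels, truth, positive_class="p")
        assert (out.tp, out.fn, out.tn, out.fp) == (10, 0, 8, 2)
        assert out.sensitivity == 1.0
        assert out.specificity == pytest.approx(0.8)

    def test_perfect_labels(self):
        out = evaluate(["p", "n"], ["p", "n"], positive_class="p")
        assert out.sensitivity == 1.0 and out.specificity == 1.0

    def test_degenerate_all_positive(self):
        out = evaluate(["p", "p", "p"], ["p", "n", "n"], positive_class="p")
        assert out.sensitivity == 1.0 and out.specificity == 0.0

    def test_unclassified_counts_as_wrong(self):
        out = evaluate(["unclassified", "unclassified"], ["p", "n"],
                       positive_class="p")
        assert (out.fn, out.fp) == (1, 1)

    def test_missing_class_flagged_not_fabricated(self):
        out = evaluate(["p", "p"], ["p", "p"], positive_class="p")
        assert out.sensitivity == 1.0
        assert out.specificity is None


class TestSelectSignature:
    def _matrices(self, votes_a, votes_b, pairs):
        """Build class matrices realising the given per-pair vote patterns.

        A vote of 1 means the sample's REO for that pair matches its own
        class's pattern; 0 means it matches the other class.
        """
        genes = sorted({g for p in pairs for g in p.key})

        def build(vote_rows, positive, tag):
            cols = {}
            for s, sample_votes in enumerate(vote_rows):
                vals = {}
                for p, v in zip(pairs, sample_votes):
                    class_dir = p.direction_a if positive else p.direction_b
                    sign = class_dir if v else -class_dir
                    vi, vj = (2.0 + s, 1.0) if sign == 1 else (1.0, 2.0 + s)
                    vals[p.gene_i] = vi
                    vals[p.gene_j] = vj
                cols[f"{tag}{s}"] = [vals[g] for g in genes]
            return em(np.array(list(cols.values())).T, genes=genes,
                      samples=list(cols))

        return build(votes_a, True, "a"), build(votes_b, False, "b")

    def test_noiseless_top_pair_gives_k1(self):
        pairs = [pair("a", "b", 1, 100, 100), pair("c", "d", 1, 50, 50)]
        ma, mb = self._matrices([[1, 1]] * 4, [[1, 1]] * 4, pairs)
        sig = select_signature(pairs, ma, mb)
        assert sig.k == 1
        assert sig.pairs[0].key == ("a", "b")

    def test_smallest_k_reaching_best_geometric_mean(self):
        # top pair misvotes in one positive training sample; pairs 2 and 3
        # always vote correctly, so k=3 reaches gm=1.0 while k=1 does not
        pairs = [pair("a", "b", 1, 100, 100), pair("c", "d", 1, 50, 50),
                 pair("e", "f", 1, 40, 40)]
        votes_a = [[0, 1, 1], [1, 1, 1], [1, 1, 1], [1, 1, 1]]
        votes_b = [[1, 1, 1]] * 4
        ma, mb = self._matrices(votes_a, votes_b, pairs)
        sig = select_signature(pairs, ma, mb)
        assert sig.k == 3
        path = sig.k_path.set_index("k")
        assert path.at[1, "gm"] < 1.0
        assert path.at[3, "gm"] == 1.0

    def test_no_candidates_error(self):
        mat = em([[1], [2]], genes=["a", "b"])
        with pytest.raises(ValueError, match="no candidate"):
            select_signature([], mat, mat)


class TestFilterSignature:
    def test_zero_fraction_noop(self):
        sig = make_signature([pair("a", "b"), pair("c", "d")], "p", "n")
        assert filter_signature_rank_diff(sig, 0.0).k == 2

    def test_same_bottom_pair_in_both_classes(self):
        pairs = [pair(f"a{i}", f"b{i}", 1, 10.0 + i, 20.0 + i)
                 for i in range(10)]
        sig = make_signature(pairs, "p", "n")
        out = filter_signature_rank_diff(sig, 0.1)
        assert out.k == 9
        assert ("a0", "b0") not in {p.key for p in out.pairs}

    def test_disjoint_bottom_pairs_union_removed(self):
        # pair 0 weakest in class A, pair 9 weakest in class B
        pairs = [pair(f"a{i}", f"b{i}", 1, 10.0 + i, 30.0 - i)
                 for i in range(10)]
        sig = make_signature(pairs, "p", "n")
        out = filter_signature_rank_diff(sig, 0.1)
        assert out.k == 8
        removed = {("a0", "b0"), ("a9", "b9")}
        assert removed.isdisjoint({p.key for p in out.pairs})

    def test_emptying_filter_rejected(self):
        # disjoint per-class bottoms whose union is the whole signature
        sig = make_signature([pair("a", "b", 1, 1.0, 99.0),
                              pair("c", "d", 1, 99.0, 1.0)], "p", "n")
        with pytest.raises(ValueError, match="smaller fraction"):
            filter_signature_rank_diff(sig, 0.5)


class TestSignatureIO:
    def test_round_trip(self, tmp_path):
        sig = make_signature([pair("a", "b", 1, 100, 400),
                              pair("c", "d", -1, 10, 40)], "tumor", "normal")
        path = tmp_path / "sig.tsv"
        write_signature(sig, path)
        back = read_signature(path)
        assert back.positive_class == "tumor"
        assert [p.key for p in back.pairs] == [p.key for p in sig.pairs]
        assert [p.direction_a for p in back.pairs] == [1, -1]
        assert back.pairs[0].degree == pytest.approx(200.0)

    def test_packaged_lymphoma_breast_panel(self):
        sig = packaged_signature()
        assert sig.positive_class == "lymphoma"
        assert {p.key for p in sig.pairs} == {
            ("MMP3", "RGS13"), ("CD37", "EPCAM"), ("EPCAM", "STAP1")
        }
        # a breast-cancer-like sample: MMP3>RGS13, EPCAM above CD37 and STAP1
        breast = pd.Series({"MMP3": 9, "RGS13": 1, "EPCAM": 8,
                            "CD37": 2, "STAP1": 3})
        assert classify(breast, sig)[0] == "breast_cancer"
        lymphoma = pd.Series({"MMP3": 1, "RGS13": 9, "EPCAM": 2,
                              "CD37": 8, "STAP1": 7})
        assert classify(lymphoma, sig)[0] == "lymphoma"
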