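import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from scmimpute.io import Partition, ValidationError
from scmimpute.metrics import (
    ContingencyTable,
    adjusted_mutual_information,
    adjusted_rand_index,
    contingency,
    evaluate,
    expected_mutual_information,
    fowlkes_mallows_index,
    normalized_mutual_information,
)


def part(labels, ids=None):
    labels = list(labels)
    ids = ids or [f"c{i}" for i in range(len(labels))]
    return Partition(tuple(ids), tuple(labels))


def pair_counts(u, v):
    """Brute-force enumeration of all C(n,2) item pairs."""
    a = b = c = d = 0
    n = len(u)
    for i in range(n):
        for j in range(i + 1, n):
            same_u, same_v = u[i] == u[j], v[i] == v[j]
            if same_u and same_v:
                a += 1
            elif same_u:
                b += 1
            elif same_v:
                c += 1
            else:
                d += 1
    return a, b, c, d


def ari_from_pairs(u, v):
    a, b, c, d = pair_counts(u, v)
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0
    return 2.0 * (a * d - b * c) / denom


def fmi_from_pairs(u, v):
    a, b, c, _ = pair_counts(u, v)
    if a + b == 0 or a + c == 0:
        return 0.0
    return a / math.sqrt((a + b) * (a + c))


def nmi_by_explicit_summation(u, v):
    n = len(u)
    t = contingency(part(u), part(v)).counts
    hu = -sum(s / n * math.log(s / n) for s in t.sum(axis=1) if s)
    hv = -sum(s / n * math.log(s / n) for s in t.sum(axis=0) if s)
    mi = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            nij = t[i, j]
            if nij:
                mi += nij / n * math.log(n * nij / (t[i].sum() * t[:, j].sum()))
    if hu == 0.0 and hv == 0.0:
        return 1.0
    return mi / (0.5 * (hu + hv)) if (hu + hv) else 0.0


def random_labels(rng, n, kmax=4):
    return [int(x) for x in rng.integers(0, rng.integers(2, kmax + 1), size=n)]


class TestContingency:
    def test_crossed_partition_counts(self):
        t = contingency(part([0, 0, 1, 1]), part([0, 1, 0, 1]))
        assert np.array_equal(t.counts, [[1, 1], [1, 1]])
        assert t.n == 4

    def test_identical_partitions_give_diagonal(self):
        t = contingency(part(["a", "b", "a", "c"]), part(["a", "b", "a", "c"]))
        off = t.counts - np.diag(np.diag(t.counts))
        assert (off == 0).all()

    def test_alignment_by_cell_id(self):
        u = part([0, 0, 1, 1], ids=["w", "x", "y", "z"])
        v_shuffled = Partition(("z", "w", "y", "x"), (1, 0, 1, 0))
        v_in_order = Partition(("w", "x", "y", "z"), (0, 0, 1, 1))
        assert np.array_equal(
            contingency(u, v_shuffled).counts, contingency(u, v_in_order).counts
        )

    def test_mismatched_cells_list_difference(self):
        with pytest.raises(ValidationError, match="c9"):
            contingency(part([0, 1], ids=["c0", "c1"]), part([0, 1], ids=["c0", "c9"]))


class TestAgainstPairEnumeration:
    @pytest.mark.parametrize("seed", range(5))
    def test_ari_and_fmi_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(2, 13))
            u, v = random_labels(rng, n), random_labels(rng, n)
            t = contingency(part(u), part(v))
            assert adjusted_rand_index(t) == pytest.approx(ari_from_pairs(u, v), abs=1e-12)
            assert fowlkes_mallows_index(t) == pytest.approx(fmi_from_pairs(u, v), abs=1e-12)

    def test_specific_fmi_pair_count(self):
        # U=[0,0,0,1], V=[0,0,1,1]: TP=1, FP=2, FN=1 -> 1/sqrt(6)
        t = contingency(part([0, 0, 0, 1]), part([0, 0, 1, 1]))
        assert fowlkes_mallows_index(t) == pytest.approx(1 / math.sqrt(6), abs=1e-12)

    def test_no_shared_co_clustered_pair_is_zero(self):
        t = contingency(part([0, 0, 1, 1]), part([0, 1, 0, 1]))
        assert fowlkes_mallows_index(t) == 0.0


class TestInformationMetrics:
    def test_identical_partitions_score_one(self):
        t = contingency(part([0, 0, 1, 2]), part(["x", "x", "y", "z"]))
        assert adjusted_rand_index(t) == pytest.approx(1.0)
        assert normalized_mutual_information(t) == pytest.approx(1.0)
        assert adjusted_mutual_information(t) == pytest.approx(1.0)
        assert fowlkes_mallows_index(t) == pytest.approx(1.0)

    def test_single_cluster_vs_split_has_zero_nmi(self):
        t = contingency(part([0, 0, 0, 0]), part([0, 0, 1, 1]))
        assert normalized_mutual_information(t) == 0.0

    def test_both_single_cluster_defined_as_one(self):
        t = contingency(part([0, 0, 0]), part([1, 1, 1]))
        assert normalized_mutual_information(t) == 1.0
        assert adjusted_mutual_information(t) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_nmi_matches_explicit_entropy_summation(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(2, 20))
            u, v = random_labels(rng, n), random_labels(rng, n)
            t = contingency(part(u), part(v))
            assert normalized_mutual_information(t) == pytest.approx(
                nmi_by_explicit_summation(u, v), abs=1e-12
            )

    def test_emi_matches_exhaustive_permutation_average(self):
        # hypergeometric-model E[I] equals the average MI over all n!
        # relabelings of V with marginals fixed (n=4, a=b=(2,2))
        u = [0, 0, 1, 1]
        v = [0, 1, 0, 1]
        t = contingency(part(u), part(v))
        mis = []
        for perm in permutations(range(4)):
            v_perm = [v[i] for i in perm]
            tp = contingency(part(u), part(v_perm))
            n = tp.n
            mi = 0.0
            for i in range(tp.counts.shape[0]):
                for j in range(tp.counts.shape[1]):
                    nij = tp.counts[i, j]
                    if nij:
                        mi += nij / n * math.log(
                            n * nij / (tp.counts[i].sum() * tp.counts[:, j].sum())
                        )
            mis.append(mi)
        assert expected_mutual_information(t) == pytest.approx(np.mean(mis), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_all_four_match_scikit_learn(self, seed):
        # independent cross-check against an established implementation
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            u, v = random_labels(rng, n), random_labels(rng, n)
            t = contingency(part(u), part(v))
            assert adjusted_rand_index(t) == pytest.approx(skm.adjusted_rand_score(u, v), abs=1e-9)
            assert normalized_mutual_information(t) == pytest.approx(
                skm.normalized_mutual_info_score(u, v), abs=1e-9
            )
            assert adjusted_mutual_information(t) == pytest.approx(
                skm.adjusted_mutual_info_score(u, v), abs=1e-9
            )
            assert fowlkes_mallows_index(t) == pytest.approx(
                skm.fowlkes_mallows_score(u, v), abs=1e-9
            )


@st.composite
def labeled_pairs(draw):
    n = draw(st.integers(min_value=2, max_value=20))
    u = draw(st.lists(st.integers(0, 4), min_size=n, max_size=n))
    v = draw(st.lists(st.integers(0, 4), min_size=n, max_size=n))
    return u, v


class TestInvariances:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(labeled_pairs(), st.permutations(list(range(5))))
    def test_label_renaming_leaves_metrics_unchanged(self, pair, relabel):
        u, v = pair
        t1 = contingency(part(u), part(v))
        t2 = contingency(part(u), part([relabel[x] for x in v]))
        for metric in (
            adjusted_rand_index,
            normalized_mutual_information,
            adjusted_mutual_information,
            fowlkes_mallows_index,
        ):
            assert metric(t1) == pytest.approx(metric(t2), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(labeled_pairs())
    def test_evaluate_is_symmetric_and_consistent(self, pair):
        u, v = pair
        pu, pv = part(u), part(v)
        fwd, rev = evaluate(pu, pv), evaluate(pv, pu)
        assert fwd.ari == pytest.approx(rev.ari, abs=1e-12)
        assert fwd.ami == pytest.approx(rev.ami, abs=1e-12)
        assert fwd.nmi == pytest.approx(rev.nmi, abs=1e-12)
        assert fwd.fmi == pytest.approx(rev.fmi, abs=1e-12)
        t = contingency(pu, pv)
        assert fwd.ari == adjusted_rand_index(t)
        assert fwd.fmi == fowlkes_mallows_index(t)

    def test_single_item_rejected(self):
        t = ContingencyTable(np.array([[1]]))
        with pytest.raises(ValidationError):
            adjusted_rand_index(t)
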