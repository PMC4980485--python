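"""Clone-tree enumeration, exclusive fractions and collision detection."""

import itertools

import numpy as np
import pytest

from clonaldrift.cluster import ClusterSet
from clonaldrift.tree import (
    detect_collision,
    enumerate_trees,
    exclusive_fractions,
    prevalence_from_cluster,
)


def oracle_trees(prev, eps):
    """Independent exhaustive generator of feasible rooted labelled trees.

    Enumerates every parent map over every admissible root, keeps maps
    that form a tree (acyclic, all nodes reach the root) and satisfy the
    sum rule within eps in every sample.
    """
    prev = np.asarray(prev, float)
    n, S = prev.shape
    eps = np.broadcast_to(np.asarray(eps, float), (n, S))
    maxima = prev.max(axis=0)
    roots = [r for r in range(n) if np.all(prev[r] >= maxima - eps[r])]
    out = set()
    for root in roots:
        others = [i for i in range(n) if i != root]
        if not others:
            out.add((root, frozenset()))
            continue
        for combo in itertools.product(range(n), repeat=len(others)):
            parent = dict(zip(others, combo))
            if any(c == p for c, p in parent.items()):
                continue
            # connectivity to root
            ok = True
            for start in others:
                seen, node = set(), start
                while node != root:
                    if node in seen or node not in parent:
                        ok = False
                        break
                    seen.add(node)
                    node = parent[node]
                if not ok:
                    break
            if not ok:
                continue
            child_sum = np.zeros((n, S))
            for c, p in parent.items():
                child_sum[p] += prev[c]
            if np.all(child_sum <= prev + eps):
                out.add((root, frozenset(parent.items())))
    return out


class TestEnumerateTrees:
    def test_linear_and_branched_solutions_in_one_sample(self):
        prev = np.array([[1.0], [0.6], [0.3]])
        trees = enumerate_trees(prev, ["S1"], epsilon=0.05)
        parents = {tuple(sorted(t.parent.items())) for t in trees}
        assert parents == {
            ((0, None), (1, 0), (2, 0)),  # branched
            ((0, None), (1, 0), (2, 1)),  # chain through the subclone
        }

    def test_second_sample_disambiguates_topology(self):
        prev = np.array([[1.0, 1.0], [0.6, 0.1], [0.3, 0.5]])
        trees = enumerate_trees(prev, ["B1", "S1"], epsilon=0.05)
        assert [t.parent for t in trees] == [{0: None, 1: 0, 2: 0}]

    def test_rogue_cluster_above_founder_defeats_every_tree(self):
        # a cluster overtaking the founder at surgery only: no single
        # origin explains both samples
        prev = np.array([[1.0, 0.4], [0.5, 0.05], [0.01, 0.9]])
        assert enumerate_trees(prev, ["B1", "S1"], epsilon=0.05) == []

    def test_most_parsimonious_tree_is_first(self):
        # branched children sum to 1.05 (slack 0.05); the chain is exact
        prev = np.array([[1.0], [0.55], [0.5]])
        trees = enumerate_trees(prev, ["S1"], epsilon=0.1)
        assert trees[0].slack <= trees[-1].slack
        assert trees[0].parent == {0: None, 1: 0, 2: 1}
        assert trees[0].slack == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_agrees_with_independent_recursive_generator(self, n):
        rng = np.random.default_rng(n)
        for trial in range(4):
            prev = np.sort(rng.uniform(0, 1, size=(n, 2)), axis=0)[::-1]
            prev[0] = 1.0
            eps = 0.08
            got = {
                (t.root, frozenset((c, p) for c, p in t.parent.items() if p is not None))
                for t in enumerate_trees(prev, ["B1", "S1"], epsilon=eps)
            }
            assert got == oracle_trees(prev, eps)


class TestExclusiveFractions:
    def _tree(self, prev, parent):
        from clonaldrift.tree import CloneTree

        prev = np.asarray(prev, float)
        return CloneTree(
            parent=parent, root=0, nodes=list(range(len(prev))),
            sample_ids=["S1"], prevalence=prev,
            epsilon=np.full_like(prev, 0.05),
        )

    def test_residual_arithmetic(self):
        t = self._tree([[1.0], [0.6], [0.3]], {0: None, 1: 0, 2: 0})
        frac = exclusive_fractions(t)[:, 0]
        assert frac == pytest.approx([0.1, 0.6, 0.3])

    def test_monoclonal_founder_takes_all(self):
        t = self._tree([[1.0]], {0: None})
        assert exclusive_fractions(t)[:, 0] == pytest.approx([1.0])

    def test_negative_residual_is_clipped_then_renormalized(self):
        t = self._tree([[1.0], [0.7], [0.35]], {0: None, 1: 0, 2: 1})
        frac = exclusive_fractions(t)[:, 0]
        assert np.all(frac >= 0)
        assert frac.sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_on_random_feasible_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            prev = np.sort(rng.uniform(0, 1, size=(n, 3)), axis=0)[::-1]
            prev[0] = 1.0
            for t in enumerate_trees(prev, ["a", "b", "c"], epsilon=0.3)[:5]:
                frac = exclusive_fractions(t)
                assert np.allclose(frac.sum(axis=0), 1.0, atol=1e-9)
                assert np.all(frac >= 0)


def _cluster_set(median_vaf, sample_ids):
    median_vaf = np.asarray(median_vaf, float)
    k = median_vaf.shape[0]
    return ClusterSet(
        variant_keys=[("1", i, "A", "T") for i in range(k)],
        sample_ids=list(sample_ids),
        assignments=np.arange(k),
        outlier=np.zeros(k, bool),
        theta=median_vaf.copy(),
        median_vaf=median_vaf,
        counts=np.full(k, 50),
        k=k,
        log_likelihood=0.0,
        bic=0.0,
        total_depth=np.full_like(median_vaf, 50 * 150.0),
    )


TPS = {"B1": "baseline", "S1": "surgical"}
PUR = {"B1": 1.0, "S1": 1.0}


class TestDetectCollision:
    def test_disjoint_time_points_are_a_collision(self):
        cs = _cluster_set([[0.5, 0.0], [0.25, 0.0], [0.0, 0.5], [0.0, 0.3]], TPS)
        call = detect_collision(cs, PUR, TPS)
        assert call.is_collision and call.evidence == "disjoint_variants"
        assert call.shared_cluster_count == 0

    def test_rogue_cluster_with_shared_founder_is_a_collision(self):
        # founder shared, but one cluster rises from nothing to above the
        # founder's own surgical prevalence
        cs = _cluster_set([[0.5, 0.2], [0.25, 0.002], [0.004, 0.45]], TPS)
        call = detect_collision(cs, PUR, TPS)
        assert call.is_collision and call.evidence == "no_feasible_tree"
        assert call.shared_cluster_count >= 1

    def test_ordinary_nested_architecture_is_not_a_collision(self):
        cs = _cluster_set([[0.5, 0.5], [0.3, 0.2], [0.1, 0.25]], TPS)
        call = detect_collision(cs, PUR, TPS)
        assert not call.is_collision and call.evidence == "none"

    def test_single_time_point_not_evaluable(self):
        cs = _cluster_set([[0.5], [0.3]], {"B1": "baseline"})
        with pytest.raises(ValueError, match="both time points"):
            detect_collision(cs, {"B1": 1.0}, {"B1": "baseline"})


@pytest.mark.parametrize(
    "median_vaf, purity, expected",
    [
        (0.5, 1.0, 1.0),
        (0.25, 1.0, 0.5),
        (0.25, 0.5, 1.0),   # purity correction doubles the estimate
        (0.004, 1.0, 0.0),  # below detection -> absent
        (0.6, 1.0, 1.0),    # capped
    ],
)
def test_prevalence_from_cluster(median_vaf, purity, expected):
    assert prevalence_from_cluster(median_vaf, purity) == pytest.approx(expected)
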