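import itertools
import math
from collections import Counter

import numpy as np
import pytest

import mranet as m
from mranet.errors import InputError
from mranet.matrices import LabeledMatrix
from mranet.mi import BinnedExpression


def oracle_entropy(labels):
    counts = Counter(labels)
    total = sum(counts.values())
    return -sum(c / total * math.log(c / total) for c in counts.values())


def oracle_mi(x, y):
    """Plug-in MI from explicit joint-frequency counting."""
    return oracle_entropy(x) + oracle_entropy(y) - oracle_entropy(list(zip(x, y)))


class TestDiscretize:
    def test_default_bins_is_sqrt_of_samples(self):
        expr = np.arange(18, dtype=float).reshape(2, 9)
        binned = m.discretize(expr)
        assert binned.n_bins == 3

    def test_constant_gene_has_zero_entropy(self):
        expr = np.vstack([np.full(8, 3.0), np.arange(8, dtype=float)])
        binned = m.discretize(expr, n_bins=4)
        mi = m.mi_matrix(binned)
        assert mi.values[0, 0] == 0.0
        assert len(set(binned.labels[0])) == 1

    def test_equal_width_splits_range(self):
        expr = np.arange(1, 11, dtype=float).reshape(1, 10)
        expr = np.vstack([expr, expr])
        binned = m.discretize(expr, n_bins=2, method="equal_width")
        assert list(binned.labels[0]) == [1] * 5 + [2] * 5

    def test_equal_frequency_balances_counts(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(1, 30))
        expr = np.vstack([expr, expr])
        binned = m.discretize(expr, n_bins=3)
        counts = np.bincount(binned.labels[0])[1:]
        assert counts.max() - counts.min() <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            m.discretize(np.ones((2, 1)))


class TestMIMatrix:
    def test_diagonal_joint_counts_give_ln2(self):
        # joint table [[2, 0], [0, 2]] over 4 samples
        labels = np.array([[1, 1, 2, 2], [1, 1, 2, 2]])
        mi = m.mi_matrix(BinnedExpression(labels, 2, "equal_frequency", ["a", "b"]))
        assert mi.values[0, 1] == pytest.approx(math.log(2))

    def test_relabeling_gives_marginal_entropy(self):
        labels = np.array([[1, 2, 3, 1, 2, 3], [3, 1, 2, 3, 1, 2]])  # deterministic map
        mi = m.mi_matrix(BinnedExpression(labels, 3, "equal_frequency", ["a", "b"]))
        assert mi.values[0, 1] == pytest.approx(mi.values[0, 0])

    def test_matches_plugin_oracle_on_small_panel(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 4, size=(4, 12))
        mi = m.mi_matrix(BinnedExpression(labels, 3, "equal_frequency", list("abcd")))
        for i, j in itertools.combinations(range(4), 2):
            expected = oracle_mi(list(labels[i]), list(labels[j]))
            assert mi.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_entropy_bound(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 5, size=(5, 20))
        mi = m.mi_matrix(BinnedExpression(labels, 4, "equal_frequency", list("abcde")))
        np.testing.assert_allclose(mi.values, mi.values.T)
        h = np.diag(mi.values)
        for i, j in itertools.combinations(range(5), 2):
            assert 0.0 <= mi.values[i, j] <= min(h[i], h[j]) + 1e-12


class TestClrMi:
    def test_uniform_background_gives_zero_scores(self):
        values = np.full((4, 4), 0.3)
        np.fill_diagonal(values, 1.0)
        scores = m.clr_mi(m.MIMatrix(values, list("abcd")))
        assert np.all(scores.values == 0.0)

    def test_outstanding_pair_ranks_first(self):
        values = np.full((4, 4), 0.1)
        np.fill_diagonal(values, 1.0)
        values[0, 1] = values[1, 0] = 0.9
        scores = m.clr_mi(m.MIMatrix(values, list("abcd")))
        assert scores.values[0, 1] == np.max(scores.values)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        half = rng.uniform(0, 1, size=(4, 4))
        values = (half + half.T) / 2
        np.fill_diagonal(values, 2.0)
        scores = m.clr_mi(m.MIMatrix(values, list("abcd")))
        n = 4
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                zs = []
                for g in (i, j):
                    other = j if g == i else i
                    background = [values[g][k] for k in range(n) if k != g]
                    mean = sum(background) / len(background)
                    sd = math.sqrt(
                        sum((v - mean) ** 2 for v in background) / (len(background) - 1)
                    )
                    zs.append(max(0.0, (values[g][other] - mean) / sd))
                expected[i, j] = math.hypot(*zs)
        np.testing.assert_allclose(scores.values, expected, atol=1e-12)


def oracle_mrnet(values):
    """Explicit forward-selection trace, one target at a time."""
    n = len(values)
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        remaining = [j for j in range(n) if j != i]
        selected = []
        while remaining:
            best_j, best_u = None, -math.inf
            for j in remaining:
                redundancy = (
                    sum(values[j][k] for k in selected) / len(selected) if selected else 0.0
                )
                u = values[i][j] - redundancy
                if u > best_u:
                    best_j, best_u = j, u
            if best_u <= 0.0:
                break
            scores[i][best_j] = best_u
            selected.append(best_j)
            remaining.remove(best_j)
    return np.maximum(np.array(scores), np.array(scores).T)


class TestMrnet:
    def test_two_genes_single_edge(self):
        values = np.array([[1.0, 0.4], [0.4, 1.0]])
        scores = m.mrnet(m.MIMatrix(values, ["a", "b"]))
        assert scores.values[0, 1] == pytest.approx(0.4)

    def test_redundant_third_gene_dropped(self):
        # gene 3 fully redundant with gene 2 from target 1's viewpoint
        values = np.array(
            [[1.0, 0.8, 0.5], [0.8, 1.0, 0.9], [0.5, 0.9, 1.0]]
        )
        scores = m.mrnet(m.MIMatrix(values, ["a", "b", "c"]))
        np.testing.assert_allclose(scores.values, oracle_mrnet(values), atol=1e-12)
        # from either endpoint the (a, c) MRMR score goes nonpositive once b is in
        assert scores.values[0, 2] == 0.0
        assert scores.values[0, 1] == pytest.approx(0.8)

    def test_star_topology_hub_selected_first(self):
        values = np.full((5, 5), 0.05)
        values[0, 1:] = values[1:, 0] = 0.8  # gene 0 is the hub
        np.fill_diagonal(values, 1.0)
        scores = m.mrnet(m.MIMatrix(values, list("abcde")))
        for leaf in range(1, 5):
            assert scores.values[0, leaf] == pytest.approx(0.8)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_bruteforce_trace(self, n):
        rng = np.random.default_rng(n)
        half = rng.uniform(0, 0.5, size=(n, n))
        values = half + half.T
        np.fill_diagonal(values, 1.0)
        scores = m.mrnet(m.MIMatrix(values, [f"g{i}" for i in range(n)]))
        np.testing.assert_allclose(scores.values, oracle_mrnet(values), atol=1e-12)


def oracle_aracne(values, tau=0.0, eps=0.0):
    """Exhaustive all-triplets data-processing-inequality pruning."""
    n = len(values)
    w = np.array(values, dtype=float)
    np.fill_diagonal(w, 0.0)
    w[w < tau] = 0.0
    remove = set()
    for i, j, k in itertools.permutations(range(n), 3):
        if i < j and w[i, j] and w[i, k] and w[k, j]:
            lo = min(w[i, k], w[k, j])
            if w[i, j] < lo and w[i, j] <= lo - eps:
                remove.add((i, j))
    out = w.copy()
    for i, j in remove:
        out[i, j] = out[j, i] = 0.0
    return out


class TestAracne:
    def test_weakest_of_triplet_removed(self):
        values = np.array([[0, 0.2, 0.5], [0.2, 0, 0.4], [0.5, 0.4, 0]], dtype=float)
        pruned = m.aracne(m.MIMatrix(values, list("abc")))
        assert pruned.values[0, 1] == 0.0
        assert pruned.values[0, 2] == pytest.approx(0.5)
        assert pruned.values[1, 2] == pytest.approx(0.4)

    def test_three_way_tie_survives_at_zero_eps(self):
        values = np.full((3, 3), 0.3)
        np.fill_diagonal(values, 0.0)
        pruned = m.aracne(m.MIMatrix(values, list("abc")))
        assert np.count_nonzero(pruned.values) == 6

    def test_pruning_only_removes(self):
        rng = np.random.default_rng(9)
        half = rng.uniform(0, 1, size=(6, 6))
        values = half + half.T
        np.fill_diagonal(values, 0.0)
        pruned = m.aracne(m.MIMatrix(values, [f"g{i}" for i in range(6)]), tau=0.3)
        thresholded = values.copy()
        thresholded[thresholded < 0.3] = 0.0
        assert np.all((pruned.values == 0) | (pruned.values == thresholded))

    @pytest.mark.parametrize("seed,tau,eps", [(1, 0.0, 0.0), (2, 0.2, 0.0), (3, 0.0, 0.05)])
    def test_matches_exhaustive_triplet_oracle(self, seed, tau, eps):
        rng = np.random.default_rng(seed)
        half = rng.uniform(0, 1, size=(5, 5))
        values = half + half.T
        np.fill_diagonal(values, 0.0)
        pruned = m.aracne(m.MIMatrix(values, [f"g{i}" for i in range(5)]), tau=tau, eps=eps)
        np.testing.assert_allclose(pruned.values, oracle_aracne(values, tau, eps))


def test_independent_noise_gene_leaves_existing_mi_stable():
    rng = np.random.default_rng(12)
    expr = rng.normal(size=(4, 60))
    base = m.mi_matrix(m.discretize(expr, n_bins=4))
    extended = np.vstack([expr, rng.normal(size=(1, 60))])
    augmented = m.mi_matrix(m.discretize(extended, n_bins=4))
    np.testing.assert_allclose(augmented.values[:4, :4], base.values)
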