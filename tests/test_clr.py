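import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mranet as m
from mranet.clr import Edge, EdgeSet
from mranet.errors import InputError


def oracle_clr(values):
    """Spreadsheet-style two-pass recomputation of the signed z-scores."""
    n = len(values)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            row = [values[i][k] for k in range(n)]
            col = [values[k][j] for k in range(n)]
            sr, sc = statistics.stdev(row), statistics.stdev(col)
            zr = (values[i][j] - statistics.mean(row)) / sr if sr else 0.0
            zc = (values[i][j] - statistics.mean(col)) / sc if sc else 0.0
            out[i][j] = np.sign(values[i][j]) * np.hypot(zr, zc)
    return out


class TestClrTransform:
    def test_3x3_against_independent_oracle(self):
        values = [[-1.0, 2.0, 0.0], [0.0, -1.0, 1.0], [-2.0, 0.0, -1.0]]
        r = m.LocalResponseMatrix(values, ["a", "b", "c"])
        z = m.clr_transform(r)
        np.testing.assert_allclose(z.values, oracle_clr(values), atol=1e-12)

    def test_sign_preserved(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(6, 6))
        np.fill_diagonal(values, -1.0)
        z = m.clr_transform(m.LocalResponseMatrix(values, [f"g{i}" for i in range(6)]))
        nz = (z.values != 0) & (values != 0)
        assert np.all(np.sign(z.values[nz]) == np.sign(values[nz]))

    def test_zero_variance_row_contributes_zero(self):
        # a constant matrix has sd 0 everywhere except through the -1 diagonal
        values = np.full((3, 3), -1.0)
        z = m.clr_transform(m.LocalResponseMatrix(values, ["a", "b", "c"]))
        assert np.all(z.values == 0.0)
        assert np.all(np.isfinite(z.values))

    def test_combined_score_dominates_components(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 5))
        np.fill_diagonal(values, -1.0)
        mean_r = values.mean(axis=1, keepdims=True)
        sd_r = values.std(axis=1, ddof=1, keepdims=True)
        z_row = (values - mean_r) / sd_r
        z = m.clr_transform(m.LocalResponseMatrix(values, [f"g{i}" for i in range(5)]))
        assert np.all(np.abs(z.values) >= np.abs(z_row) - 1e-12)

    def test_row_shift_leaves_row_zscores_unchanged(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(4, 4))
        np.fill_diagonal(values, -1.0)
        shifted = values.copy()
        shifted[1, :] += 5.0
        shifted[1, 1] = values[1, 1] + 5.0
        row = lambda v: (v[1] - v[1].mean()) / v[1].std(ddof=1)
        np.testing.assert_allclose(row(values), row(shifted), atol=1e-12)

    def test_clamped_variant_is_nonnegative_z(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 5))
        np.fill_diagonal(values, -1.0)
        r = m.LocalResponseMatrix(values, [f"g{i}" for i in range(5)])
        z_plain = m.clr_transform(r, clamp=False)
        z_clamped = m.clr_transform(r, clamp=True)
        assert not np.array_equal(z_plain.values, z_clamped.values)
        assert np.all(np.abs(z_clamped.values) <= np.abs(z_plain.values) + 1e-12)

    def test_single_module_rejected(self):
        with pytest.raises(InputError):
            m.clr_transform(m.LocalResponseMatrix([[-1.0]], ["a"]))


class TestSymmetrize:
    def test_pair_takes_dominant_direction(self):
        values = np.array([[0.0, 0.2], [-0.9, 0.0]])
        edges = m.symmetrize_scores(values, ["a", "b"])
        (edge,) = edges
        assert edge.score == pytest.approx(0.9)
        assert edge.sign == -1

    def test_symmetric_matrix_scores_are_absolute_values(self):
        values = np.array([[0.0, -0.4, 0.1], [-0.4, 0.0, 0.3], [0.1, 0.3, 0.0]])
        edges = m.symmetrize_scores(values, ["a", "b", "c"])
        scores = {(e.module_a, e.module_b): e.score for e in edges}
        assert scores[("a", "b")] == pytest.approx(0.4)

    def test_pair_count_is_n_choose_2(self):
        n = 61
        values = np.zeros((n, n))
        edges = m.symmetrize_scores(values, [f"g{i:02d}" for i in range(n)])
        assert len(edges) == n * (n - 1) // 2 == 1830

    def test_non_square_rejected(self):
        with pytest.raises(InputError):
            m.symmetrize_scores(np.zeros((2, 3)))


class TestThreshold:
    def test_zero_threshold_keeps_everything(self):
        values = np.array([[0.0, 0.1], [-0.5, 0.0]])
        edges = m.threshold_absolute(values, 0.0, ["a", "b"])
        assert [e.score for e in edges] == [0.5]

    def test_above_max_empties_scores(self):
        values = np.array([[0.0, 0.1], [-0.5, 0.0]])
        edges = m.threshold_absolute(values, 0.6, ["a", "b"])
        assert all(e.score == 0.0 for e in edges)

    def test_boundary_inclusive(self):
        values = np.array([[0.0, 0.1, -0.5], [0.0, 0.0, 0.3], [0.0, 0.0, 0.0]])
        edges = m.threshold_absolute(values, 0.3, ["a", "b", "c"])
        kept = {e.score for e in edges if e.score != 0.0}
        assert kept == {0.5, 0.3}

    def test_negative_tau_rejected(self):
        with pytest.raises(InputError):
            m.threshold_absolute(np.zeros((2, 2)), -0.1, ["a", "b"])


def edge_set(scores, n=10):
    ids = [f"g{i:02d}" for i in range(n)]
    edges, idx = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            s = scores[idx] if idx < len(scores) else 0.0
            edges.append(Edge(ids[i], ids[j], s, 1))
            idx += 1
    return EdgeSet(edges, ids)


class TestTopFraction:
    def test_ceiling_count(self):
        edges = edge_set(list(np.linspace(1, 45, 45)), n=10)  # universe 45
        top = m.select_top_fraction(edges, 0.20)
        assert len(top) == 9  # ceil(0.2 * 45)

    def test_tie_break_is_lexicographic(self):
        edges = edge_set([1.0] * 45, n=10)
        top = m.select_top_fraction(edges, 0.10)
        pairs = [(e.module_a, e.module_b) for e in top]
        assert pairs == sorted(pairs)
        assert len(top) == 5

    def test_shortfall_flagged(self):
        edges = edge_set([1.0] * 10 + [0.0] * 35, n=10)
        top = m.select_top_fraction(edges, 0.45)  # requests 21, only 10 nonzero
        assert top.shortfall and len(top) == 10

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**20),
        f1=st.floats(0.01, 1.0),
        f2=st.floats(0.01, 1.0),
    )
    def test_selection_nesting(self, seed, f1, f2):
        if f1 > f2:
            f1, f2 = f2, f1
        rng = np.random.default_rng(seed)
        edges = edge_set(list(rng.uniform(0, 1, 45)), n=10)
        small = m.select_top_fraction(edges, f1).pairs()
        large = m.select_top_fraction(edges, f2).pairs()
        assert small <= large

    def test_fraction_bounds_enforced(self):
        edges = edge_set([1.0], n=3)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(InputError):
                m.select_top_fraction(edges, bad)


class TestEdgeSetInvariants:
    def test_self_edges_rejected(self):
        with pytest.raises(InputError):
            EdgeSet([Edge("a", "a", 1.0, 1)], ["a", "b"])

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(InputError):
            EdgeSet([Edge("a", "b", 1.0, 1), Edge("a", "b", 0.5, 1)], ["a", "b"])
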