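"""Association matrix, top-fraction thresholding, degree-preserving nulls."""

import numpy as np
import pytest

from temposeq.data_io import ImageSeries
from temposeq.temporal_graph import (
    AdjacencyGraph,
    AssociationMatrix,
    compute_association_matrix,
    make_surrogate_ensemble,
    rewire_preserving_degree,
    threshold_top_fraction,
)


def _series(data, tr=1.0):
    return ImageSeries(data=np.asarray(data, dtype=float), tr_seconds=tr)


def partial_corr_oracle(data):
    """Two-stage oracle: per-row least-squares residualization against the
    mean image, then the textbook Pearson formula, row pair by row pair."""
    from scipy import stats

    T, V = data.shape
    m = data.mean(axis=0)
    resid = np.empty_like(data)
    for t in range(T):
        slope, intercept, *_ = stats.linregress(m, data[t])
        resid[t] = data[t] - (intercept + slope * m)
    out = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            r, _ = stats.pearsonr(resid[i], resid[j])
            out[i, j] = out[j, i] = r
    return out


class TestAssociationMatrix:
    def test_matches_two_stage_oracle(self):
        data = np.array(
            [
                [1.0, 4.2, -3.0, 0.5, 2.2, 7.1],
                [2.0, -1.0, 0.3, 4.4, -2.5, 1.0],
                [0.1, 0.2, 5.5, -1.2, 3.3, -0.7],
                [-2.0, 1.5, 2.5, 2.0, 0.0, 4.0],
            ]
        )
        got = compute_association_matrix(_series(data)).values
        want = partial_corr_oracle(data)
        assert np.allclose(got, want, atol=1e-12)

    def test_identical_rows_correlate_at_one(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=20)
        other = rng.normal(size=20)
        data = np.vstack([row, row, other])
        vals = compute_association_matrix(_series(data)).values
        assert vals[0, 1] == pytest.approx(1.0)

    def test_negated_residuals_correlate_at_minus_one(self):
        # sign-symmetric rows make the mean image exactly zero, so the
        # residual of -r is exactly the negated residual of r
        rng = np.random.default_rng(1)
        r0, r2 = rng.normal(size=(2, 30))
        data = np.vstack([r0, -r0, r2, -r2])
        vals = compute_association_matrix(_series(data)).values
        assert vals[0, 1] == pytest.approx(-1.0)

    def test_symmetric_bounded_zero_diagonal(self):
        rng = np.random.default_rng(2)
        vals = compute_association_matrix(_series(rng.normal(size=(12, 40)))).values
        assert np.allclose(vals, vals.T)
        assert np.all(np.abs(vals) <= 1.0)
        assert np.all(np.diag(vals) == 0)
        assert np.isfinite(vals).all()

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(8, 25))
        perm = rng.permutation(25)
        a = compute_association_matrix(_series(data)).values
        b = compute_association_matrix(_series(data[:, perm])).values
        assert np.allclose(a, b, atol=1e-10)

    def test_degenerate_row_rejected_then_zeroed(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(4, 30))
        m = data.mean(axis=0)
        # replace a row with an affine function of the mean image; its mean
        # contribution shifts m, so solve for the fixed point: use remaining
        # rows' mean plus itself
        data[1] = 2.0 * data.mean(axis=0) + 1.0
        # iterate once more so row 1 is affine in the *final* mean
        for _ in range(50):
            data[1] = 2.0 * data.mean(axis=0) + 1.0
        series = _series(data)
        with pytest.raises(ValueError, match="allow_degenerate"):
            compute_association_matrix(series)
        vals = compute_association_matrix(series, allow_degenerate=True).values
        assert np.all(vals[1] == 0) and np.all(vals[:, 1] == 0)


class TestThreshold:
    def test_keeps_exactly_k_largest(self):
        rng = np.random.default_rng(5)
        T = 6
        vals = np.zeros((T, T))
        iu, ju = np.triu_indices(T, 1)
        distinct = rng.permutation(15) + 1.0
        vals[iu, ju] = distinct
        vals += vals.T
        graph = threshold_top_fraction(AssociationMatrix(values=vals), 0.2)
        order = np.argsort(distinct)[::-1][:3]
        want = sorted((int(iu[e]), int(ju[e])) for e in order)
        assert graph.n_edges == 3
        assert sorted(graph.edges) == want

    def test_all_equal_uses_documented_tie_order(self):
        vals = np.ones((6, 6)) - np.eye(6)
        graph = threshold_top_fraction(AssociationMatrix(values=vals), 0.2)
        # quota forced to 3; ties resolve to smallest (i, j) lexicographically
        assert graph.edges == ((0, 1), (0, 2), (0, 3))

    def test_quota_at_reference_scale(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(900, 900))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        graph = threshold_top_fraction(AssociationMatrix(values=vals), 0.05)
        assert graph.n_edges == int(np.floor(0.05 * 900 * 899 / 2)) == 20227

    def test_zero_quota_rejected(self):
        vals = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="increase the fraction"):
            threshold_top_fraction(AssociationMatrix(values=vals), 0.01)


def random_graph(n, m, seed):
    rng = np.random.default_rng(seed)
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    idx = rng.choice(len(possible), size=m, replace=False)
    return AdjacencyGraph(n_nodes=n, edges=tuple(sorted(possible[k] for k in idx)))


class TestRewire:
    def test_triangle_is_rigid(self):
        tri = AdjacencyGraph(n_nodes=3, edges=((0, 1), (0, 2), (1, 2)))
        assert rewire_preserving_degree(tri, seed=0).edges == tri.edges

    def test_empty_graph_identity(self):
        empty = AdjacencyGraph(n_nodes=5, edges=())
        assert rewire_preserving_degree(empty, seed=0).edges == ()

    def test_degrees_conserved_and_edges_moved(self):
        g = random_graph(20, 40, seed=7)
        out = rewire_preserving_degree(g, seed=11)
        assert np.array_equal(np.sort(out.degrees()), np.sort(g.degrees()))
        assert np.array_equal(out.degrees(), g.degrees())  # per-node, not just sorted
        assert out.edge_set() != g.edge_set()
        assert out.n_edges == g.n_edges

    def test_deterministic_in_seed(self):
        g = random_graph(20, 40, seed=7)
        assert rewire_preserving_degree(g, seed=3).edges == \
            rewire_preserving_degree(g, seed=3).edges
        assert rewire_preserving_degree(g, seed=3).edges != \
            rewire_preserving_degree(g, seed=4).edges

    def test_stays_simple(self):
        g = random_graph(15, 30, seed=8)
        out = rewire_preserving_degree(g, seed=9)
        # AdjacencyGraph validation already rejects loops/duplicates; re-assert
        assert all(i < j for i, j in out.edges)
        assert len(set(out.edges)) == out.n_edges


class TestSurrogateEnsemble:
    def test_size_and_degree_preservation(self):
        g = random_graph(20, 40, seed=7)
        ensemble = make_surrogate_ensemble(g, n=10, seed=5)
        assert len(ensemble) == 10
        for s in ensemble:
            assert np.array_equal(s.degrees(), g.degrees())

    def test_reproducible_and_distinct(self):
        g = random_graph(20, 40, seed=7)
        a = make_surrogate_ensemble(g, n=2, seed=5)
        b = make_surrogate_ensemble(g, n=2, seed=5)
        assert a[0].edges == b[0].edges and a[1].edges == b[1].edges
        assert a[0].edges != a[1].edges

    def test_prefix_stability(self):
        # surrogate k does not depend on how many surrogates are requested
        g = random_graph(20, 40, seed=7)
        short = make_surrogate_ensemble(g, n=2, seed=5)
        long = make_surrogate_ensemble(g, n=5, seed=5)
        assert short[0].edges == long[0].edges
        assert short[1].edges == long[1].edges
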