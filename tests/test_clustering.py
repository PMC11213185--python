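"""Dendrogram construction, reordering, cophenetic/silhouette validation,
multiscale-bootstrap AU p-values and correlation-matrix PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

import sdcorr as s


def brute_force_complete_linkage(d):
    """Exhaustive recomputation of MAX-linkage merges from cluster contents."""
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[next_id] = merged
        merges.append((h, merged))
        next_id += 1
    return merges


def _line_distances():
    pts = np.array([[0.0], [1.0], [10.0], [11.0]])
    return squareform(pdist(pts))


# ---------------------------------------------------------------------------
# row-vector distances
# ---------------------------------------------------------------------------

def test_row_vector_distance_examples():
    corr = s.CorrelationMatrix(("a", "b", "c"), np.eye(3))
    d = s.row_vector_distances(corr)
    assert d.loc["a", "b"] == pytest.approx(np.sqrt(2))  # rows (1,0,0),(0,1,0)
    assert d.loc["a", "a"] == 0.0
    dup = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    d = s.row_vector_distances(s.CorrelationMatrix(("a", "b", "c"), dup))
    assert d.loc["a", "b"] == 0.0                        # identical rows
    assert np.allclose(d, d.T)


def test_row_vector_distances_exclude_undefined():
    v = np.eye(3)
    v[2, :] = v[:, 2] = np.nan
    v[2, 2] = np.nan
    corr = s.CorrelationMatrix(("a", "b", "c"), v, undefined=("c",))
    with pytest.warns(UserWarning, match="undefined"):
        d = s.row_vector_distances(corr)
    assert list(d.index) == ["a", "b"]


# ---------------------------------------------------------------------------
# complete linkage
# ---------------------------------------------------------------------------

def test_four_point_line_merges():
    dendro = s.cluster_areas(_line_distances(), labels="p q r s".split())
    z = dendro.linkage
    # {0,1}@1, {2,3}@1, then everything @11
    assert {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))} \
        == {frozenset({0, 1}), frozenset({2, 3})}
    np.testing.assert_allclose(z[:, 2], [1.0, 1.0, 11.0])


def test_identical_rows_merge_at_height_zero():
    d = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
    dendro = s.cluster_areas(d, labels=list("abc"))
    assert dendro.linkage[0, 2] == 0.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(2, 10), st.integers(0, 10_000))
def test_linkage_monotone_with_n_minus_1_merges(n, seed):
    rng = np.random.default_rng(seed)
    d = squareform(pdist(rng.normal(size=(n, 3))))
    z = s.complete_linkage(d)
    assert z.shape == (n - 1, 4)
    assert np.all(np.diff(z[:, 2]) >= 0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(3, 12), st.integers(0, 10_000))
def test_linkage_heights_match_scipy(n, seed):
    rng = np.random.default_rng(seed)
    d = squareform(pdist(rng.normal(size=(n, 4))))
    ours = s.complete_linkage(d)
    ref = hierarchy.linkage(squareform(d, checks=False), method="complete")
    np.testing.assert_allclose(np.sort(ours[:, 2]), np.sort(ref[:, 2]),
                               atol=1e-12)


def test_linkage_lowest_index_tie_break():
    # three mutually equidistant points: the first merge must be (0, 1)
    d = np.ones((3, 3)) - np.eye(3)
    z = s.complete_linkage(d)
    assert tuple(z[0, :2].astype(int)) == (0, 1)


# ---------------------------------------------------------------------------
# reorder
# ---------------------------------------------------------------------------

def _random_corr(rng, m=6, n=40):
    x = rng.normal(size=(n, m))
    v = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(v, 1.0)
    return s.CorrelationMatrix(tuple(f"c{i}" for i in range(m)), v)


def test_reorder_properties():
    rng = np.random.default_rng(0)
    corr = _random_corr(rng)
    dendro = s.cluster_areas(s.row_vector_distances(corr))
    ordered, leaf_order = s.reorder(corr, dendro)
    # multiset of entries invariant
    assert sorted(ordered.to_numpy().ravel()) == pytest.approx(
        sorted(corr.values.ravel()))
    # idempotence: reordering the reordered matrix changes nothing
    corr2 = s.CorrelationMatrix(tuple(ordered.index), ordered.to_numpy())
    dendro2 = s.cluster_areas(s.row_vector_distances(corr2))
    ordered2, _ = s.reorder(corr2, dendro2)
    np.testing.assert_allclose(ordered2.to_numpy(), ordered.to_numpy())
    assert list(ordered2.index) == list(ordered.index)


def test_reorder_label_mismatch_rejected():
    rng = np.random.default_rng(1)
    corr = _random_corr(rng)
    dendro = s.cluster_areas(np.array([[0.0, 1.0], [1.0, 0.0]]), labels=["x", "y"])
    with pytest.raises(s.DataError):
        s.reorder(corr, dendro)


# ---------------------------------------------------------------------------
# cophenetic analysis
# ---------------------------------------------------------------------------

def test_cophenetic_reads_off_merge_heights():
    dendro = s.cluster_areas(_line_distances(), labels="pqrs")
    res = s.cophenetic_analysis(dendro, _line_distances())
    assert res.frame().loc["p", "q"] == 1.0
    assert res.frame().loc["r", "s"] == 1.0
    assert res.frame().loc["p", "r"] == 11.0
    assert -1.0 <= res.correlation <= 1.0


def test_cophenetic_dominates_input_distances():
    rng = np.random.default_rng(3)
    d = squareform(pdist(rng.normal(size=(10, 3))))
    dendro = s.cluster_areas(d)
    res = s.cophenetic_analysis(dendro, d)
    assert np.all(res.distances >= d - 1e-12)


# ---------------------------------------------------------------------------
# silhouette cut
# ---------------------------------------------------------------------------

def _two_pair_distances():
    d = np.full((4, 4), 10.0)
    d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
    np.fill_diagonal(d, 0.0)
    return d


def test_silhouette_selects_two_tight_pairs():
    d = _two_pair_distances()
    dendro = s.cluster_areas(d)
    res = s.silhouette_cut(dendro, d)
    assert res.best_k == 2
    # hand evaluation: every object has a = 0.1, b = 10 → s = 9.9/10
    assert res.best_score == pytest.approx(0.99, abs=1e-12)
    # k = n−1 forces singletons whose score is 0 by convention
    s3 = res.scores[res.ks.index(3)]
    assert s3 == pytest.approx((0.99 + 0.99) / 4, abs=1e-12)
    assert all(-1.0 <= v <= 1.0 for v in res.scores)


def test_silhouette_identical_objects_degenerate():
    d = np.zeros((4, 4))
    dendro = s.cluster_areas(d)
    with pytest.raises(s.DegenerateInputError):
        s.silhouette_cut(dendro, d)


# ---------------------------------------------------------------------------
# AU p-values
# ---------------------------------------------------------------------------

def _block_tpv(rng, n=300, strength=4.0):
    """Two independent signal blocks of 5 columns each."""
    sig_a = rng.normal(size=n)
    sig_b = rng.normal(size=n)
    cols = [sig_a * strength + rng.normal(size=n) for _ in range(5)] + \
           [sig_b * strength + rng.normal(size=n) for _ in range(5)]
    x = np.column_stack(cols)
    cats = tuple(f"A{i}" for i in range(5)) + tuple(f"B{i}" for i in range(5))
    return s.TPVMatrix(tuple(map(str, range(n))), cats,
                       np.zeros_like(x, dtype=int), x, 300.0, {})


def test_au_two_block_branches_strongly_supported():
    tpv = _block_tpv(np.random.default_rng(11))
    cfg = s.AnalysisConfig(rng_seed=11, n_bootstrap=1000)
    res = s.au_pvalues(tpv, cfg)
    a = res.branch_for([f"A{i}" for i in range(5)])
    b = res.branch_for([f"B{i}" for i in range(5)])
    assert a is not None and b is not None
    assert a.au >= 0.95 and b.au >= 0.95


def test_au_saturated_branch_is_one():
    tpv = _block_tpv(np.random.default_rng(2), strength=50.0)
    cfg = s.AnalysisConfig(rng_seed=2, n_bootstrap=100)
    res = s.au_pvalues(tpv, cfg)
    root = res.branches[-1]
    assert root.au == 1.0 and root.saturated
    a = res.branch_for([f"A{i}" for i in range(5)])
    assert a.au == 1.0 and a.saturated  # present in every resample


def test_au_shuffled_data_not_concentrated_near_one():
    rng = np.random.default_rng(5)
    tpv = _block_tpv(rng)
    x = tpv.normalized.copy()
    for j in range(x.shape[1]):          # destroy column coupling
        rng.shuffle(x[:, j])
    shuffled = s.TPVMatrix(tpv.cell_ids, tpv.categories,
                           tpv.raw, x, 300.0, {})
    cfg = s.AnalysisConfig(rng_seed=5, n_bootstrap=200)
    res = s.au_pvalues(shuffled, cfg)
    aus = [b.au for b in res.branches[:-1]]
    assert np.median(aus) < 0.9


def test_au_requires_three_distinct_scales():
    tpv = _block_tpv(np.random.default_rng(0), n=50)
    cfg = s.AnalysisConfig(rng_seed=0, scales=(1.0, 1.0, 1.0, 1.0))
    with pytest.raises(s.DataError, match="scales"):
        s.au_pvalues(tpv, cfg)


def test_au_bp_agree_for_extreme_branches():
    tpv = _block_tpv(np.random.default_rng(7), strength=8.0)
    cfg = s.AnalysisConfig(rng_seed=7, n_bootstrap=500)
    res = s.au_pvalues(tpv, cfg)
    for b in res.branches:
        if b.bp_at_1 >= 0.99:
            assert abs(b.au - b.bp_at_1) <= 0.05


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_identity_matrix_uniform_fractions():
    corr = s.CorrelationMatrix(tuple(f"c{i}" for i in range(30)), np.eye(30))
    res = s.pca_correlation(corr)
    np.testing.assert_allclose(res.variance_fractions, np.full(30, 1 / 30))


def test_pca_rank_one_sign_matrix():
    v = np.array([1.0, -1.0, 1.0, 1.0])
    corr = s.CorrelationMatrix(("a", "b", "c", "d"), np.outer(v, v))
    res = s.pca_correlation(corr)
    assert res.variance_fractions[0] == pytest.approx(1.0)
    # sign convention: the largest-magnitude loading is positive
    assert res.loadings[np.argmax(np.abs(res.loadings[:, 0])), 0] > 0


def test_pca_two_by_two_closed_form():
    corr = s.CorrelationMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 1.0]]))
    res = s.pca_correlation(corr)
    np.testing.assert_allclose(res.eigenvalues, [1.5, 0.5], atol=1e-12)
    np.testing.assert_allclose(res.variance_fractions, [0.75, 0.25], atol=1e-12)
    assert np.allclose(res.loadings.T @ res.loadings, np.eye(2), atol=1e-12)


def test_pca_rejects_asymmetric_input():
    v = np.array([[1.0, 0.2], [0.4, 1.0]])
    with pytest.raises(s.DataError):
        s.pca_correlation(s.CorrelationMatrix(("a", "b"), v))


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def test_newick_roundtrips_through_skbio():
    import io
    from skbio import TreeNode
    dendro = s.cluster_areas(_line_distances(), labels=["p", "q", "r", "s"])
    tree = TreeNode.read(io.StringIO(dendro.to_newick()))
    assert {t.name for t in tree.tips()} == {"p", "q", "r", "s"}
    # root-to-tip distance equals the root merge height
    assert tree.descending_branch_length() > 0
    depths = {t.name: tree.distance(t) for t in tree.tips()}
    assert all(d == pytest.approx(11.0) for d in depths.values())
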