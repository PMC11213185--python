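"""Cluster-structure inference and validation on the correlation matrix.

The 30 correlation-matrix rows are treated as points in R^30 (self-entries
included); complete (MAX) linkage agglomerates their Euclidean distances
into a dendrogram whose structure is then validated three independent ways:

* cophenetic correlation between dendrogram and input distances,
* mean silhouette score over cuts k = 2 … n−1 (optimal cut selection),
* per-branch approximately-unbiased (AU) p-values from multiscale bootstrap
  resampling of the TPV rows (resample sizes τ·n for τ on a grid around 1;
  the probit of the per-scale branch frequency is fit as
  z(τ) = v·√τ + c/√τ and AU = Φ(c − v)).

A principal component analysis of the correlation matrix provides a
clustering-free check of the same block structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtr, ndtri
from sklearn.metrics import silhouette_score

from .data import AnalysisConfig, DataError, DegenerateInputError
from .density import CorrelationMatrix, TPVMatrix, pearson_columns


# ---------------------------------------------------------------------------
# Distances between correlation rows
# ---------------------------------------------------------------------------

def row_vector_distances(corr: CorrelationMatrix,
                         include_diagonal: bool = True) -> pd.DataFrame:
    """Euclidean distances between full rows of the correlation matrix.

    Undefined (constant-column) rows are excluded with a warning.  By default
    all coordinates, including the diagonal 1s, enter the distance; set
    ``include_diagonal=False`` to drop each row's self-entry (sensitivity
    option).
    """
    keep = [i for i, c in enumerate(corr.categories) if c not in corr.undefined]
    if corr.undefined:
        warnings.warn(f"excluding undefined rows: {corr.undefined}")
    codes = [corr.categories[i] for i in keep]
    v = corr.values[np.ix_(keep, keep)]
    if include_diagonal:
        d = squareform(pdist(v))
    else:
        m = len(keep)
        d = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                sel = [k for k in range(m) if k not in (i, j)]
                d[i, j] = d[j, i] = np.linalg.norm(v[i, sel] - v[j, sel])
    return pd.DataFrame(d, index=codes, columns=codes)


# ---------------------------------------------------------------------------
# Complete-linkage agglomeration
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Complete-linkage merge tree in scipy linkage-matrix form."""

    labels: tuple[str, ...]
    linkage: np.ndarray           # (n-1, 4): id_a, id_b, height, size

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage,
                            columns=["cluster_a", "cluster_b", "height", "size"])

    def branch_leafsets(self) -> list[frozenset[int]]:
        """Leaf-index set of every internal node, in merge order."""
        return [frozenset(_bits(m)) for m in _branch_bitmasks(self.linkage,
                                                              self.n_leaves)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f":{length:.10g}")

        return (f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});")


def complete_linkage(distances: np.ndarray) -> np.ndarray:
    """Deterministic complete-linkage agglomeration (scipy linkage format).

    At each step the pair of clusters with the smallest MAX-linkage distance
    is merged; ties are broken by the lowest (creation-order) cluster-index
    pair.  Cluster ids follow the scipy convention: leaves 0..n−1, the t-th
    merge creates id n+t.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise DataError("clustering needs at least 2 objects")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise DataError("distance matrix must be square and symmetric")
    total = 2 * n - 1
    big = np.full((total, total), np.inf)
    big[:n, :n] = d
    np.fill_diagonal(big, np.inf)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    z = np.zeros((n - 1, 4))
    for t in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            a = active[ai]
            row = big[a]
            for bi in range(ai + 1, len(active)):
                b = active[bi]
                if row[b] < best[0]:
                    best = (row[b], a, b)
        h, a, b = best
        new = n + t
        for k in active:
            if k not in (a, b):
                big[new, k] = big[k, new] = max(big[a, k], big[b, k])
        sizes[new] = sizes[a] + sizes[b]
        z[t] = (a, b, h, sizes[new])
        active.remove(a)
        active.remove(b)
        active.append(new)
    return z


def cluster_areas(distances: pd.DataFrame | np.ndarray,
                  labels: Sequence[str] | None = None) -> Dendrogram:
    """Cluster correlation-row vectors by complete-linkage agglomeration."""
    if isinstance(distances, pd.DataFrame):
        labels = tuple(distances.index)
        d = distances.to_numpy()
    else:
        d = np.asarray(distances, dtype=float)
        labels = tuple(labels) if labels is not None else tuple(
            str(i) for i in range(d.shape[0]))
    return Dendrogram(labels, complete_linkage(d))


def reorder(corr: CorrelationMatrix, dendro: Dendrogram) -> tuple[pd.DataFrame, list[str]]:
    """Permute correlation rows/columns into dendrogram leaf order."""
    if set(dendro.labels) != set(corr.categories) - set(corr.undefined):
        raise DataError("dendrogram labels do not match correlation categories")
    order_codes = [dendro.labels[i] for i in dendro.leaf_order()]
    idx = [corr.categories.index(c) for c in order_codes]
    vals = corr.values[np.ix_(idx, idx)]
    return pd.DataFrame(vals, index=order_codes, columns=order_codes), order_codes


# ---------------------------------------------------------------------------
# Cophenetic analysis
# ---------------------------------------------------------------------------

@dataclass
class CopheneticResult:
    labels: tuple[str, ...]
    distances: np.ndarray     # (n, n) ultrametric cophenetic distances
    correlation: float        # r_c over the n(n-1)/2 unordered pairs

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=list(self.labels),
                            columns=list(self.labels))


def cophenetic_analysis(dendro: Dendrogram,
                        distances: pd.DataFrame | np.ndarray) -> CopheneticResult:
    """Cophenetic distances (first-merge heights) and cophenetic correlation.

    r_c is the Pearson correlation, over all unordered leaf pairs, between
    the cophenetic and the input Euclidean distances — a measure of how
    faithfully the dendrogram summarizes the distance matrix.
    """
    if dendro.n_leaves < 3:
        raise DegenerateInputError("cophenetic correlation needs >= 3 leaves")
    d = distances.to_numpy() if isinstance(distances, pd.DataFrame) else np.asarray(distances)
    rc, coph = hierarchy.cophenet(dendro.linkage, squareform(d, checks=False))
    return CopheneticResult(dendro.labels, squareform(coph), float(rc))


# ---------------------------------------------------------------------------
# Silhouette cut
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteResult:
    ks: tuple[int, ...]
    scores: tuple[float, ...]
    best_k: int
    labels: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def best_score(self) -> float:
        return self.scores[self.ks.index(self.best_k)]

    @property
    def best_labels(self) -> np.ndarray:
        return self.labels[self.best_k]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "mean_silhouette": self.scores})


def silhouette_cut(dendro: Dendrogram,
                   distances: pd.DataFrame | np.ndarray,
                   k_range: Sequence[int] | None = None) -> SilhouetteResult:
    """Mean silhouette score of every dendrogram cut; best k reported.

    Each object's silhouette contrasts its mean within-cluster distance with
    the mean distance to the nearest other cluster, (b−a)/max(a,b);
    singletons score 0 by convention.
    """
    d = distances.to_numpy() if isinstance(distances, pd.DataFrame) else np.asarray(distances)
    n = dendro.n_leaves
    if np.nanmax(d) == 0:
        raise DegenerateInputError("all objects identical; silhouette undefined")
    ks = list(k_range) if k_range is not None else list(range(2, n))
    if any(k < 2 or k > n - 1 for k in ks):
        raise DataError("k_range must lie within [2, n-1]")
    scores, labels = [], {}
    cuts = hierarchy.cut_tree(dendro.linkage, n_clusters=ks)
    for col, k in enumerate(ks):
        lab = cuts[:, col]
        scores.append(float(silhouette_score(d, lab, metric="precomputed")))
        labels[k] = lab
    best_k = ks[int(np.nanargmax(scores))]
    return SilhouetteResult(tuple(ks), tuple(scores), best_k, labels)


# ---------------------------------------------------------------------------
# Multiscale bootstrap AU p-values
# ---------------------------------------------------------------------------

def _branch_bitmasks(linkage: np.ndarray, n: int) -> list[int]:
    """Leaf set of every internal node as a bit mask (bit i = leaf i)."""
    masks = [0] * (2 * n - 1)
    for i in range(n):
        masks[i] = 1 << i
    out = []
    for t in range(n - 1):
        a, b = int(linkage[t, 0]), int(linkage[t, 1])
        m = masks[a] | masks[b]
        masks[n + t] = m
        out.append(m)
    return out


def _bits(mask: int) -> list[int]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return out


@dataclass
class BranchSupport:
    """Bootstrap support of one internal dendrogram branch."""

    leaf_indices: tuple[int, ...]
    leaf_labels: tuple[str, ...]
    bp: dict[float, float]        # scale τ → bootstrap probability
    au: float
    v: float = np.nan             # signed distance (probit fit)
    c: float = np.nan             # curvature (probit fit)
    saturated: bool = False       # BP ≡ 1 (or ≡ 0) at every scale
    fit_rss: float = np.nan

    @property
    def bp_at_1(self) -> float:
        key = min(self.bp, key=lambda s: abs(s - 1.0))
        return self.bp[key]


@dataclass
class AUResult:
    dendrogram: Dendrogram
    branches: list[BranchSupport]
    n_bootstrap: int
    scales: tuple[float, ...]

    def branch_for(self, labels: Sequence[str]) -> BranchSupport | None:
        want = frozenset(labels)
        for b in self.branches:
            if frozenset(b.leaf_labels) == want:
                return b
        return None

    def frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            row = {"leaves": ";".join(b.leaf_labels), "au": b.au,
                   "bp_1": b.bp_at_1, "v": b.v, "c": b.c,
                   "saturated": b.saturated}
            row.update({f"bp_{s:g}": p for s, p in b.bp.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _fit_au(bp: np.ndarray, r: np.ndarray, n_boot: int) -> tuple[float, float, float, float]:
    """Weighted probit fit z(τ) = v√τ + c/√τ → AU = Φ(c − v).

    BP values are clamped away from {0, 1} by 1/(B+1); weights are the
    inverse asymptotic variances of the probit-transformed frequencies.
    """
    eps = 1.0 / (n_boot + 1)
    bpc = np.clip(bp, eps, 1 - eps)
    zz = -ndtri(bpc)                      # = Φ⁻¹(1 − BP)
    phi = np.exp(-0.5 * zz ** 2) / np.sqrt(2 * np.pi)
    w = (phi ** 2) * n_boot / (bpc * (1 - bpc))
    design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    a = design.T @ (design * w[:, None])
    b = design.T @ (w * zz)
    try:
        v, c = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular design in AU probit fit") from exc
    resid = zz - design @ np.array([v, c])
    rss = float(resid @ (w * resid))
    au = float(ndtr(c - v))
    return au, float(v), float(c), rss


def au_pvalues(tpv: TPVMatrix,
               config: AnalysisConfig,
               rng: np.random.Generator | None = None) -> AUResult:
    """Multiscale-bootstrap AU p-values for every branch of the reference tree.

    For each relative scale τ, B resamples of ⌈τ·n⌉ TPV rows (sampling
    points) are drawn with replacement; each resample is pushed through
    correlation → row-vector distances → complete linkage, and the branch
    frequency BP(τ) is the fraction of resample dendrograms containing the
    reference branch as a leaf subset.  The per-branch probit curve over
    scales is fit by weighted least squares and extrapolated to the
    approximately-unbiased p-value AU = Φ(c − v).  Branches found in every
    (or no) resample at every scale saturate at AU = 1 (or 0) and are
    flagged instead of fit.
    """
    scales = sorted(set(config.scales))
    if len(scales) < 3:
        raise DataError("multiscale bootstrap needs >= 3 distinct scales")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    x = tpv.normalized
    n, m = x.shape
    ref_corr = pearson_columns(x)
    if np.isnan(ref_corr).any():
        raise DataError("constant TPV columns; cannot bootstrap")
    ref_d = squareform(pdist(ref_corr))
    dendro = Dendrogram(tpv.categories, complete_linkage(ref_d))
    ref_masks = _branch_bitmasks(dendro.linkage, m)

    b_count = np.zeros((len(ref_masks), len(scales)), dtype=np.int64)
    r_actual = np.empty(len(scales))
    for si, tau in enumerate(scales):
        n_sub = int(np.ceil(tau * n))
        r_actual[si] = n_sub / n
        ref_set = {mk: bi for bi, mk in enumerate(ref_masks)}
        for _ in range(config.n_bootstrap):
            idx = rng.integers(0, n, n_sub)
            corr = pearson_columns(x[idx])
            np.nan_to_num(corr, copy=False)   # constant resample columns → 0
            np.fill_diagonal(corr, 1.0)
            d = squareform(pdist(corr))
            z = hierarchy.linkage(squareform(d, checks=False), method="complete")
            for mk in _branch_bitmasks(z, m):
                bi = ref_set.get(mk)
                if bi is not None:
                    b_count[bi, si] += 1

    bp_mat = b_count / config.n_bootstrap
    branches = []
    for bi, mk in enumerate(ref_masks):
        leaves = tuple(_bits(mk))
        labels = tuple(tpv.categories[i] for i in leaves)
        bp = dict(zip(scales, bp_mat[bi]))
        if np.all(bp_mat[bi] == 1.0):
            branches.append(BranchSupport(leaves, labels, bp, au=1.0, saturated=True))
        elif np.all(bp_mat[bi] == 0.0):
            branches.append(BranchSupport(leaves, labels, bp, au=0.0, saturated=True))
        else:
            au, v, c, rss = _fit_au(bp_mat[bi], r_actual, config.n_bootstrap)
            branches.append(BranchSupport(leaves, labels, bp, au=au, v=v, c=c,
                                          fit_rss=rss))
    return AUResult(dendro, branches, config.n_bootstrap, tuple(scales))


# ---------------------------------------------------------------------------
# PCA of the correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    categories: tuple[str, ...]
    eigenvalues: np.ndarray        # descending
    variance_fractions: np.ndarray
    loadings: np.ndarray           # (m, m) column i = loading vector of PC i

    def frame(self) -> pd.DataFrame:
        cols = {f"PC{i+1}": self.loadings[:, i] for i in range(self.loadings.shape[1])}
        return pd.DataFrame(cols, index=list(self.categories))


def pca_correlation(corr: CorrelationMatrix) -> PCAResult:
    """Eigendecomposition of the correlation matrix.

    Variance fraction of component i is λ_i/Σλ.  Loading signs are fixed so
    each component's largest-magnitude loading is positive.
    """
    v = corr.values
    if np.isnan(v).any():
        raise DataError("correlation matrix has undefined entries")
    if not np.allclose(v, v.T):
        raise DataError("correlation matrix must be symmetric")
    evals, evecs = np.linalg.eigh(v)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for i in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, i]))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    fractions = evals / evals.sum()
    return PCAResult(corr.categories, evals, fractions, evecs)
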