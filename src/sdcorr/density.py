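"""Spatial density correlation core: neighborhood counts, normalization, TPV,
and the cortical-area correlation matrix.

Each labeled neuron is a sampling point.  Inside a closed ball of radius
``r`` (default 300 μm) around point ``p`` we count, per injection ``j``, the
neighbors labeled by ``j`` (``N_p,j``).  Counts are corrected for injections
that multiply label the same cortical territory with a per-injection
normalization constant

    C_j = V(I_j) / Σ_{I_k ∈ I_R} V(I_j ∩ I_k)

where ``I_R`` is the set of injections covering the same ontology category
``R`` (the self term makes the denominator positive), then aggregated per
category: Ñ_p,R = Σ_{j∈R} C_j · N_p,j.  Stacking the Ñ rows gives the
n_cells × n_categories target-projection-vector (TPV) matrix, whose column
pairs are Pearson-correlated into the category correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .data import (AnalysisConfig, CellRecord, DataError, InjectionSite,
                   OntologyTable)
from .geometry import OverlapTable


def neighborhood_counts(cells: Sequence[CellRecord],
                        radius: float,
                        injection_order: Sequence[str],
                        include_center_cell: bool = True) -> np.ndarray:
    """Per-cell, per-injection neighbor counts within a closed ball.

    Entry ``(p, j)`` is the number of cells labeled by injection ``j`` whose
    Euclidean distance to cell ``p`` is ≤ ``radius``.  With
    ``include_center_cell`` the sampling cell counts itself for its own
    injection(s).  Double-labeled cells contribute once to each of their
    injections.
    """
    if radius <= 0:
        raise DataError("radius must be > 0")
    n = len(cells)
    if n == 0:
        raise DataError("need at least one cell")
    col = {iid: k for k, iid in enumerate(injection_order)}
    # cell × injection incidence
    rows, cols = [], []
    for i, c in enumerate(cells):
        for iid in c.injection_ids:
            rows.append(i)
            cols.append(col[iid])
    incidence = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(injection_order)))

    pts = np.array([c.position for c in cells])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    i_idx = [pairs[:, 0], pairs[:, 1]]
    j_idx = [pairs[:, 1], pairs[:, 0]]
    if include_center_cell:
        eye = np.arange(n)
        i_idx.append(eye)
        j_idx.append(eye)
    adj = sparse.csr_matrix(
        (np.ones(sum(len(a) for a in i_idx)),
         (np.concatenate(i_idx), np.concatenate(j_idx))), shape=(n, n))
    counts = adj @ incidence
    return np.asarray(counts.todense() if sparse.issparse(counts) else counts,
                      dtype=np.int64)


def normalization_constants(injections: Sequence[InjectionSite],
                            overlap: OverlapTable,
                            ontology: OntologyTable) -> dict[str, float]:
    """Per-injection constants C_j correcting co-category multiple labeling.

    C_j = 1 exactly when injection j overlaps no other injection of its own
    category; it decreases monotonically as overlap volume grows.
    """
    by_cat: dict[str, list[InjectionSite]] = {}
    for inj in injections:
        by_cat.setdefault(inj.category, []).append(inj)
    out: dict[str, float] = {}
    for inj in injections:
        denom = 0.0
        for other in by_cat[inj.category]:
            if other.injection_id == inj.injection_id:
                denom += inj.volume  # self term V(I_j ∩ I_j) = V(I_j)
            else:
                denom += overlap.intersection(inj.injection_id, other.injection_id)
        out[inj.injection_id] = inj.volume / denom
    return out


@dataclass
class TPVMatrix:
    """Target-projection vectors: one row per sampling point (cell)."""

    cell_ids: tuple[str, ...]
    categories: tuple[str, ...]
    raw: np.ndarray           # (n_cells, n_categories) int counts
    normalized: np.ndarray    # (n_cells, n_categories) float
    radius: float
    constants: dict[str, float]

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=list(self.cell_ids),
                            columns=list(self.categories))

    def normalized_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.normalized, index=list(self.cell_ids),
                            columns=list(self.categories))


def build_tpv(cells: Sequence[CellRecord],
              injections: Sequence[InjectionSite],
              ontology: OntologyTable,
              config: AnalysisConfig,
              overlap: OverlapTable | None = None) -> TPVMatrix:
    """Neighborhood counts → normalization → per-category TPV matrix.

    Normalization is applied per injection *before* category aggregation
    (the constants are defined per injection site), so duplicated coextensive
    injections do not double-count a category.
    """
    if overlap is None:
        overlap = OverlapTable.from_masks(injections)
    inj_order = [i.injection_id for i in injections]
    counts = neighborhood_counts(cells, config.radius, inj_order,
                                 config.include_center_cell)
    consts = normalization_constants(injections, overlap, ontology)
    c_vec = np.array([consts[iid] for iid in inj_order])

    m = len(ontology)
    cat_idx = np.array([ontology.index(i.category) for i in injections])
    agg = np.zeros((len(inj_order), m))
    agg[np.arange(len(inj_order)), cat_idx] = 1.0

    raw = counts @ agg
    normalized = (counts * c_vec) @ agg
    for k, code in enumerate(ontology.codes):
        if not np.any(cat_idx == k):
            warnings.warn(f"category {code} has no injections; all-zero column")
    return TPVMatrix(tuple(c.cell_id for c in cells), ontology.codes,
                     raw.astype(np.int64), normalized, config.radius, consts)


@dataclass
class CorrelationMatrix:
    """Pearson correlations between TPV category columns."""

    categories: tuple[str, ...]
    values: np.ndarray                  # (m, m), diagonal exactly 1
    undefined: tuple[str, ...] = ()     # constant columns (Pearson undefined)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.categories),
                            columns=list(self.categories))


def pearson_columns(x: np.ndarray) -> np.ndarray:
    """Two-pass Pearson correlation between all column pairs.

    Constant columns yield NaN rows/columns (flagged by the caller).
    """
    xc = x - x.mean(axis=0)
    ss = np.sqrt((xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ xc) / np.outer(ss, ss)
    r = np.clip(r, -1.0, 1.0)
    const = ss == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, np.where(const, np.nan, 1.0))
    return r


def correlation_matrix(tpv: TPVMatrix, use: str = "normalized") -> CorrelationMatrix:
    """Category × category Pearson correlation of TPV columns.

    ``use`` selects the normalized (default) or raw counts.  Columns that are
    constant over all sampling points have undefined correlation; they are
    marked NaN and listed in ``undefined``.
    """
    x = tpv.normalized if use == "normalized" else tpv.raw.astype(float)
    if x.shape[0] < 2:
        raise DataError("correlation needs at least 2 sampling points")
    r = pearson_columns(x)
    const = np.flatnonzero(np.isnan(np.diag(r)))
    undefined = tuple(tpv.categories[i] for i in const)
    if undefined:
        warnings.warn(f"constant TPV columns (correlation undefined): {undefined}")
    return CorrelationMatrix(tpv.categories, r, undefined)
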