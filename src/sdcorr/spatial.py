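"""Distance–similarity analyses and high-density point selection.

Relates three pairwise quantities over unordered category pairs: cortical
injection-centroid distance, the mean/median 3D distance between the two
categories' labeled cell populations in the basal forebrain, and the
row-vector Euclidean distance of the correlation matrix.  All C(m, 2)
unordered distinct pairs are enumerated (435 for a 30-area ontology).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .data import (CellRecord, DataError, DegenerateInputError, InjectionSite,
                   OntologyTable)
from .density import TPVMatrix


def cells_by_category(cells: Sequence[CellRecord],
                      injections: Sequence[InjectionSite],
                      ontology: OntologyTable) -> dict[str, np.ndarray]:
    """Cell position arrays per category (a double-labeled cell joins each
    of its injections' categories once)."""
    cat_of = {i.injection_id: i.category for i in injections}
    groups: dict[str, list[np.ndarray]] = {c: [] for c in ontology.codes}
    for cell in cells:
        for code in {cat_of[iid] for iid in cell.injection_ids}:
            groups[code].append(cell.position)
    return {c: (np.array(v) if v else np.empty((0, 3))) for c, v in groups.items()}


def population_distances(cells: Sequence[CellRecord],
                         injections: Sequence[InjectionSite],
                         ontology: OntologyTable,
                         stat: str = "median") -> pd.DataFrame:
    """Cross-population cell-distance statistic per category pair (μm).

    Entry (A, B) is the mean or median Euclidean distance over all cross
    pairs (a ∈ A, b ∈ B); the diagonal uses within-category pairs (i < j).
    Categories with no cells are excluded with a warning; diagonals of
    single-cell categories are NaN.
    """
    if stat not in ("mean", "median"):
        raise DataError("stat must be 'mean' or 'median'")
    fn = np.mean if stat == "mean" else np.median
    groups = cells_by_category(cells, injections, ontology)
    codes = [c for c in ontology.codes if len(groups[c]) > 0]
    dropped = set(ontology.codes) - set(codes)
    if dropped:
        warnings.warn(f"categories with no cells excluded: {sorted(dropped)}")
    m = len(codes)
    out = np.full((m, m), np.nan)
    for i, a in enumerate(codes):
        pa = groups[a]
        if len(pa) > 1:
            d = cdist(pa, pa)
            out[i, i] = fn(d[np.triu_indices(len(pa), k=1)])
        for j in range(i + 1, m):
            d = cdist(pa, groups[codes[j]])
            out[i, j] = out[j, i] = fn(d)
    return pd.DataFrame(out, index=codes, columns=codes)


def _pair_values(m: pd.DataFrame | np.ndarray,
                 codes: Sequence[str] | None = None) -> tuple[list[tuple[str, str]], np.ndarray]:
    if isinstance(m, pd.DataFrame):
        codes = list(m.index)
        v = m.to_numpy()
    else:
        v = np.asarray(m)
        codes = list(codes) if codes is not None else [str(i) for i in range(len(v))]
    pairs, vals = [], []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            pairs.append((codes[i], codes[j]))
            vals.append(v[i, j])
    return pairs, np.array(vals)


def distance_correlation(x: pd.DataFrame, y: pd.DataFrame,
                         networks: Mapping[str, str] | None = None,
                         network: str | None = None) -> tuple[float, int]:
    """Pearson r between two pairwise-distance matrices over unordered pairs.

    With ``network`` given, only pairs whose two categories both belong to
    that network (per ``networks``) are used.  Returns (r, n_pairs).
    """
    common = [c for c in x.index if c in set(y.index)]
    xs, ys = x.loc[common, common], y.loc[common, common]
    pairs, xv = _pair_values(xs)
    _, yv = _pair_values(ys)
    keep = np.isfinite(xv) & np.isfinite(yv)
    if network is not None:
        if networks is None:
            raise DataError("network subset requires a category→network map")
        keep &= np.array([networks.get(a) == network and networks.get(b) == network
                          for a, b in pairs])
    xv, yv = xv[keep], yv[keep]
    if len(xv) < 3:
        raise DataError("need at least 3 pairs for a correlation")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("constant pairwise vector; Pearson undefined")
    r, _ = pearsonr(xv, yv)
    return float(r), int(len(xv))


def rowvector_vs_celldistance(row_distances: pd.DataFrame,
                              cell_distances: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Correlation-row distance vs. population cell distance, over all pairs.

    Returns the Pearson r and the scatter table (one row per category pair)
    used to produce it.
    """
    common = [c for c in row_distances.index if c in set(cell_distances.index)]
    rd = row_distances.loc[common, common]
    cd = cell_distances.loc[common, common]
    pairs, xv = _pair_values(rd)
    _, yv = _pair_values(cd)
    keep = np.isfinite(xv) & np.isfinite(yv)
    table = pd.DataFrame({
        "category_a": [a for (a, _), k in zip(pairs, keep) if k],
        "category_b": [b for (_, b), k in zip(pairs, keep) if k],
        "row_vector_distance": xv[keep],
        "cell_distance_um": yv[keep],
    })
    if keep.sum() < 3:
        raise DataError("need at least 3 pairs for a correlation")
    if np.ptp(xv[keep]) == 0 or np.ptp(yv[keep]) == 0:
        raise DegenerateInputError("constant pairwise vector; Pearson undefined")
    r, _ = pearsonr(xv[keep], yv[keep])
    return float(r), table


def high_density_points(tpv: TPVMatrix, category: str) -> set[str]:
    """Sampling points where a category's normalized density exceeds its mean.

    "Above average" is strict; ties at the mean are excluded, so the returned
    set is always a proper subset of the sampling points.
    """
    if category not in tpv.categories:
        raise DataError(f"unknown category {category}")
    col = tpv.normalized[:, tpv.categories.index(category)]
    if not np.any(col):
        warnings.warn(f"category {category} has an all-zero column")
        return set()
    above = col > col.mean()
    return {cid for cid, flag in zip(tpv.cell_ids, above) if flag}
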