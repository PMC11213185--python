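"""Volume computations on voxel masks: Dice, participation, overlap, centroids.

All intersections are computed by voxel counting on a shared grid; two masks
are intersectable when they have identical spacings and lattice-aligned
origins (origins differing by integer multiples of the spacing).  Masks that
do not satisfy this must first be resampled explicitly
(:meth:`sdcorr.data.VoxelMask.resample`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (DataError, DegenerateInputError, InjectionSite,
                   OntologyTable, VoxelMask)


def _check_aligned(x: VoxelMask, y: VoxelMask) -> None:
    if not np.allclose(x.spacing, y.spacing):
        raise DataError("masks have different voxel spacings; resample first")
    shift = (y.origin - x.origin) / x.spacing
    if not np.allclose(shift, np.round(shift), atol=1e-6):
        raise DataError("mask origins are not lattice-aligned; resample first")


def intersection_volume(x: VoxelMask, y: VoxelMask) -> float:
    """V(X∩Y) in μm³ by voxel counting on the shared lattice."""
    _check_aligned(x, y)
    shift = np.round((y.origin - x.origin) / x.spacing).astype(int)
    # overlapping index window in x's index space
    lo = np.maximum(0, shift)
    hi = np.minimum(x.occupancy.shape, shift + np.array(y.occupancy.shape))
    if np.any(lo >= hi):
        return 0.0
    sub_x = x.occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ylo = lo - shift
    yhi = hi - shift
    sub_y = y.occupancy[ylo[0]:yhi[0], ylo[1]:yhi[1], ylo[2]:yhi[2]]
    return float(np.logical_and(sub_x, sub_y).sum()) * x.voxel_volume


def dice(x: VoxelMask, y: VoxelMask) -> float:
    """Dice coefficient 2·V(X∩Y)/(V(X)+V(Y)) on a shared grid.

    Used to validate how faithfully two delineations of the same zone agree;
    1 iff the non-empty masks coincide, 0 iff they are disjoint.
    """
    vx, vy = x.volume, y.volume
    if vx == 0 and vy == 0:
        raise DegenerateInputError("Dice of two empty masks is undefined")
    return 2.0 * intersection_volume(x, y) / (vx + vy)


def participation(injection: InjectionSite, region: VoxelMask) -> float:
    """P_I(R) = V(I∩R)/V(I): fraction of injection I inside region R."""
    if injection.mask is None:
        raise DataError(
            f"injection {injection.injection_id} has no mask; participation "
            "needs voxel geometry")
    return intersection_volume(injection.mask, region) / injection.volume


@dataclass
class OverlapTable:
    """Symmetric injection-pair intersection volumes (μm³).

    The diagonal holds each injection's own volume; a missing off-diagonal
    pair reads as 0 (disjoint).
    """

    _data: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, volume_um3: float) -> None:
        if volume_um3 < 0:
            raise DataError("intersection volume must be >= 0")
        self._data[self._key(a, b)] = float(volume_um3)

    def intersection(self, a: str, b: str) -> float:
        return self._data.get(self._key(a, b), 0.0)

    def volume(self, a: str) -> float:
        v = self._data.get((a, a))
        if v is None or v <= 0:
            raise DataError(f"overlap table has no positive volume for {a}")
        return v

    def __contains__(self, a: str) -> bool:
        return (a, a) in self._data

    def validate(self) -> None:
        for (a, b), v in self._data.items():
            if a != b:
                cap = min(self.volume(a), self.volume(b))
                if v > cap * (1 + 1e-9):
                    raise DataError(
                        f"V({a}∩{b}) = {v} exceeds min volume {cap}")

    @classmethod
    def from_masks(cls, injections: Sequence[InjectionSite]) -> "OverlapTable":
        """Exact table by voxel counting; requires masks on one lattice."""
        table = cls()
        with_masks = [i for i in injections if i.mask is not None]
        if len(with_masks) != len(injections):
            missing = [i.injection_id for i in injections if i.mask is None]
            raise DataError(f"injections without masks: {missing}")
        for inj in with_masks:
            table.set(inj.injection_id, inj.injection_id, inj.volume)
        for a, b in itertools.combinations(with_masks, 2):
            v = intersection_volume(a.mask, b.mask)
            if v > 0:
                table.set(a.injection_id, b.injection_id, v)
        return table

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id_a": a, "id_b": b, "intersection_um3": v}
                for (a, b), v in sorted(self._data.items())]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "intersection_um3"])

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["intersection_um3"] = df["intersection_um3"].map(repr)
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OverlapTable":
        for col in ("id_a", "id_b", "intersection_um3"):
            if col not in df.columns:
                raise DataError(f"overlap table is missing column '{col}'")
        table = cls()
        for row in df.itertuples(index=False):
            table.set(str(row.id_a), str(row.id_b), float(row.intersection_um3))
        table.validate()
        return table

    @classmethod
    def from_csv(cls, path: str | Path) -> "OverlapTable":
        return cls.from_frame(pd.read_csv(path))


def overlap_fraction(a: InjectionSite, b: InjectionSite,
                     table: OverlapTable | None = None) -> float:
    """O_A(B) = V(A∩B)/V(A): how much of injection A is covered by B.

    Asymmetric in general.  Masks take precedence over a supplied table.
    """
    if a.mask is not None and b.mask is not None:
        inter = intersection_volume(a.mask, b.mask)
    elif table is not None:
        inter = table.intersection(a.injection_id, b.injection_id)
    else:
        raise DataError("overlap_fraction needs masks or an overlap table")
    return inter / a.volume


def centroid_distance_matrix(injections: Sequence[InjectionSite]) -> pd.DataFrame:
    """Pairwise Euclidean distances (μm) between injection centroids."""
    ids = [i.injection_id for i in injections]
    pts = np.array([i.centroid for i in injections])
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(pts)) if len(ids) > 1 else np.zeros((len(ids), len(ids)))
    return pd.DataFrame(d, index=ids, columns=ids)


def category_centroids(injections: Sequence[InjectionSite],
                       ontology: OntologyTable) -> pd.DataFrame:
    """Volume-weighted mean injection centroid per category (μm).

    Categories with no injection are excluded with a warning.
    """
    rows, codes = [], []
    for code in ontology.codes:
        members = [i for i in injections if i.category == code]
        if not members:
            warnings.warn(f"category {code} has no injections; excluded")
            continue
        w = np.array([i.volume for i in members])
        pts = np.array([i.centroid for i in members])
        rows.append((w[:, None] * pts).sum(axis=0) / w.sum())
        codes.append(code)
    return pd.DataFrame(rows, index=codes, columns=["x_um", "y_um", "z_um"])


def category_centroid_distance_matrix(injections: Sequence[InjectionSite],
                                      ontology: OntologyTable) -> pd.DataFrame:
    """Pairwise distances between volume-weighted category centroids."""
    cents = category_centroids(injections, ontology)
    from scipy.spatial.distance import pdist, squareform
    pts = cents.to_numpy()
    d = squareform(pdist(pts)) if len(pts) > 1 else np.zeros((len(pts), len(pts)))
    return pd.DataFrame(d, index=cents.index, columns=cents.index)
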