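"""Domain types, file readers/writers, dataset validation and configuration.

The analysis operates on three tables that together describe a retrograde
tracing study registered into a common reference space:

* a **cell table** — one row per labeled projection neuron, with its 3D
  position in micrometres and the injection(s) that labeled it;
* an **injection table** — one row per cortical tracer deposit, carrying its
  ontology category and (optionally) a voxelized volume mask used for
  overlap normalization;
* an **ontology table** — the ordered list of cortical area categories that
  defines the axes of every downstream matrix.

Coordinates are right-handed micrometres in reference-brain space.  A voxel
``(i, j, k)`` of a :class:`VoxelMask` occupies the half-open box
``[origin + i*spacing, origin + (i+1)*spacing)``; points are assigned to
voxels with this half-open rule so the grid partitions space.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A file does not have the expected columns/structure."""


class DataError(ValueError):
    """A row or value violates a dataset invariant."""


class DegenerateInputError(ValueError):
    """An operation was called on input for which it is undefined."""


# ---------------------------------------------------------------------------
# Voxel masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelMask:
    """Axis-aligned boolean occupancy grid in reference-space micrometres."""

    origin: np.ndarray          # (3,) μm, corner of voxel (0,0,0)
    spacing: np.ndarray         # (3,) μm per voxel, all > 0
    occupancy: np.ndarray       # 3D bool array

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        occ = np.asarray(self.occupancy, dtype=bool)
        object.__setattr__(self, "occupancy", occ)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise DataError("origin and spacing must be 3-vectors")
        if not np.all(self.spacing > 0):
            raise DataError("voxel spacing components must be > 0")
        if occ.ndim != 3:
            raise DataError("occupancy must be a 3D array")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Occupied volume in μm³ (voxel count × voxel volume)."""
        return self.n_voxels * self.voxel_volume

    @property
    def centroid(self) -> np.ndarray:
        """Mean of occupied voxel centers, μm."""
        idx = np.argwhere(self.occupancy)
        if idx.size == 0:
            raise DegenerateInputError("centroid of an empty mask is undefined")
        centers = self.origin + (idx + 0.5) * self.spacing
        return centers.mean(axis=0)

    def voxel_centers(self) -> np.ndarray:
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.spacing

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Half-open voxel-box membership test for an (n, 3) point array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ijk = np.floor((pts - self.origin) / self.spacing).astype(int)
        inside = np.all((ijk >= 0) & (ijk < self.occupancy.shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if inside.any():
            sel = ijk[inside]
            out[inside] = self.occupancy[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def resample(self, origin: np.ndarray, spacing: np.ndarray,
                 shape: tuple[int, int, int]) -> "VoxelMask":
        """Resample onto an explicit target grid (nearest voxel-center rule).

        Comparing two masks voxel-wise is only meaningful on a shared grid;
        this is the explicit operation that produces one.
        """
        origin = np.asarray(origin, dtype=float)
        spacing = np.asarray(spacing, dtype=float)
        idx = np.indices(shape).reshape(3, -1).T
        centers = origin + (idx + 0.5) * spacing
        occ = self.contains_points(centers).reshape(shape)
        return VoxelMask(origin, spacing, occ)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.occupancy.astype(np.uint8), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelMask":
        import nibabel as nib
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.diag(affine)[:3].copy()
        origin = affine[:3, 3].copy()
        if not np.allclose(affine[:3, :3], np.diag(spacing)):
            raise SchemaError(f"{path}: mask affine must be axis-aligned (diagonal)")
        occ = np.asarray(img.dataobj) > 0
        return cls(origin, np.abs(spacing), occ)


def shared_grid(masks: Sequence[VoxelMask]) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Smallest common grid (origin, spacing, shape) covering all masks.

    Requires identical spacings; origins are aligned down to the common
    lattice of the first mask.
    """
    spacing = masks[0].spacing
    for m in masks[1:]:
        if not np.allclose(m.spacing, spacing):
            raise DataError("shared_grid requires identical voxel spacings")
    los = np.min([m.origin for m in masks], axis=0)
    his = np.max([m.origin + np.array(m.occupancy.shape) * m.spacing for m in masks], axis=0)
    base = masks[0].origin
    origin = base + np.floor((los - base) / spacing) * spacing
    shape = tuple(int(np.ceil(x)) for x in (his - origin) / spacing)
    return origin, spacing, shape


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """One retrogradely labeled projection neuron."""

    cell_id: str
    brain_id: str
    position: np.ndarray                 # (3,) μm in reference space
    injection_ids: frozenset[str]        # ≥ 2 elements marks a double-labeled cell

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "injection_ids", frozenset(self.injection_ids))
        if pos.shape != (3,):
            raise DataError(f"cell {self.cell_id}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise DataError(f"cell {self.cell_id}: non-finite coordinate")
        if not self.injection_ids:
            raise DataError(f"cell {self.cell_id}: empty injection_ids")

    @property
    def double_labeled(self) -> bool:
        return len(self.injection_ids) >= 2


@dataclass(frozen=True)
class InjectionSite:
    """One cortical tracer deposit with its ontology category and volume."""

    injection_id: str
    brain_id: str
    category: str
    centroid: np.ndarray                 # (3,) μm
    volume: float                        # μm³, > 0
    mask: VoxelMask | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if self.volume <= 0:
            raise DataError(f"zero-volume injection: {self.injection_id}")
        if self.mask is not None:
            if abs(self.mask.volume - self.volume) > 1e-6 * max(self.volume, 1.0):
                raise DataError(
                    f"injection {self.injection_id}: volume does not equal "
                    "voxel count × voxel volume")

    @classmethod
    def from_mask(cls, injection_id: str, brain_id: str, category: str,
                  mask: VoxelMask) -> "InjectionSite":
        if mask.n_voxels == 0:
            raise DataError(f"zero-volume injection: {injection_id}")
        return cls(injection_id, brain_id, category,
                   centroid=mask.centroid, volume=mask.volume, mask=mask)


@dataclass(frozen=True)
class OntologyTable:
    """Ordered cortical-area categories; the order fixes matrix axes."""

    codes: tuple[str, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.codes) != len(self.names):
            raise DataError("codes and names must have the same length")
        if len(set(self.codes)) != len(self.codes):
            raise DataError("ontology codes must be unique")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"code": self.codes, "name": self.names}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OntologyTable":
        df = pd.read_csv(path, dtype=str)
        for col in ("code", "name"):
            if col not in df.columns:
                raise SchemaError(f"ontology table is missing column '{col}'")
        return cls(tuple(df["code"]), tuple(df["name"]))

    @classmethod
    def default(cls) -> "OntologyTable":
        return OntologyTable(tuple(c for c, _, _ in DEFAULT_CATEGORIES),
                             tuple(n for _, n, _ in DEFAULT_CATEGORIES))


# 30-category cortical ontology fixture: (code, display name, functional network).
# Areas are the electrophysiologically / ontologically defined rat cortical
# targets of basal-forebrain cholinergic projections; the partition into the
# three principal networks (somatic sensory-motor, visual, auditory) is the
# planted structure the synthetic generator emulates.  Listed alphabetically
# by code; user-replaceable via OntologyTable.from_csv.
DEFAULT_CATEGORIES: tuple[tuple[str, str, str], ...] = (
    ("A1",     "Primary auditory cortex",              "Auditory"),
    ("AAF",    "Anterior auditory field",              "Auditory"),
    ("AIP",    "Agranular insular cortex, posterior",  "Auditory"),
    ("AMG",    "Amygdala",                             "Auditory"),
    ("Cg1",    "Cingulate cortex, area 1",             "Visual"),
    ("HC",     "Hippocampus",                          "Visual"),
    ("IDIGI",  "Insular cortex, dys/granular",         "Auditory"),
    ("IL",     "Infralimbic cortex",                   "Visual"),
    ("LEC",    "Lateral entorhinal cortex",            "Visual"),
    ("LO",     "Lateral orbital cortex",               "SSM"),
    ("M1FL",   "Primary motor, forelimb",              "SSM"),
    ("M1HL",   "Primary motor, hindlimb",              "SSM"),
    ("M1WH",   "Primary motor, whisker",               "SSM"),
    ("M2",     "Secondary motor cortex",               "SSM"),
    ("MEC",    "Medial entorhinal cortex",             "Visual"),
    ("PDAF",   "Posterior dorsal auditory field",      "Auditory"),
    ("PER",    "Perirhinal cortex",                    "Auditory"),
    ("POR",    "Postrhinal cortex",                    "Auditory"),
    ("PrL",    "Prelimbic cortex",                     "Visual"),
    ("RS",     "Retrosplenial cortex",                 "Visual"),
    ("S1FL",   "Primary somatosensory, forelimb",      "SSM"),
    ("S1HL",   "Primary somatosensory, hindlimb",      "SSM"),
    ("S1OF",   "Primary somatosensory, orofacial",     "SSM"),
    ("S1ULP",  "Primary somatosensory, upper lip",     "SSM"),
    ("S1WH",   "Primary somatosensory, whisker",       "SSM"),
    ("S2",     "Secondary somatosensory cortex",       "SSM"),
    ("SRAF",   "Suprarhinal auditory field",           "Auditory"),
    ("V1",     "Primary visual cortex",                "Visual"),
    ("V2",     "Secondary visual cortex",              "Visual"),
    ("VO",     "Ventral orbital cortex",               "SSM"),
)

#: Category → network mapping for the default fixture.
DEFAULT_NETWORK_PARTITION: dict[str, str] = {c: w for c, _, w in DEFAULT_CATEGORIES}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the density-correlation pipeline.

    radius
        Neighborhood sphere radius in μm (default 300; the analysis is
        reported stable from 100–500 μm).
    include_center_cell
        Whether the sampling-point cell counts itself for its own
        injection(s); default True (every TPV row is then non-zero).
    distance_stat
        Statistic over cross-population cell distances: "mean" or "median".
    n_bootstrap
        Bootstrap replicates per scale for branch AU p-values.
    scales
        Relative resample sizes for multiscale bootstrap; must include 1.0.
    """

    radius: float = 300.0
    include_center_cell: bool = True
    distance_stat: str = "median"
    linkage: str = "complete"
    n_bootstrap: int = 1000
    scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
    rng_seed: int = 0
    voxel_spacing: float = 50.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DataError("radius must be > 0")
        self.scales = tuple(float(s) for s in self.scales)
        if any(s <= 0 for s in self.scales):
            raise DataError("scales must all be > 0")
        if not any(abs(s - 1.0) < 1e-12 for s in self.scales):
            raise DataError("scales must include 1.0")
        if self.n_bootstrap < 100:
            raise DataError("n_bootstrap must be >= 100")
        if self.distance_stat not in ("mean", "median"):
            raise DataError("distance_stat must be 'mean' or 'median'")
        if self.linkage != "complete":
            raise DataError("only complete (MAX) linkage is supported")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise SchemaError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

CELL_COLUMNS = ("cell_id", "brain_id", "x_um", "y_um", "z_um", "injection_ids")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_cells(path: str | Path) -> list[CellRecord]:
    """Read a cell table (CSV/TSV, one row per labeled neuron)."""
    df = _read_table(path)
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing column '{col}'")
    cells: list[CellRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        cid = str(row.cell_id)
        if cid in seen:
            raise DataError(f"duplicate cell_id: {cid}")
        seen.add(cid)
        try:
            pos = np.array([float(row.x_um), float(row.y_um), float(row.z_um)])
        except (TypeError, ValueError) as exc:
            raise DataError(f"cell {cid}: unparseable coordinate") from exc
        inj = frozenset(s.strip() for s in str(row.injection_ids).split(";") if s.strip())
        cells.append(CellRecord(cid, str(row.brain_id), pos, inj))
    return cells


def write_cells(cells: Iterable[CellRecord], path: str | Path) -> None:
    rows = [{
        "cell_id": c.cell_id,
        "brain_id": c.brain_id,
        "x_um": repr(float(c.position[0])),
        "y_um": repr(float(c.position[1])),
        "z_um": repr(float(c.position[2])),
        "injection_ids": ";".join(sorted(c.injection_ids)),
    } for c in cells]
    pd.DataFrame(rows, columns=list(CELL_COLUMNS)).to_csv(path, index=False)


INJECTION_COLUMNS = ("injection_id", "brain_id", "category")


def load_injections(meta_path: str | Path,
                    masks_dir: str | Path | None = None,
                    overlap_table: "pd.DataFrame | None" = None,
                    ontology: OntologyTable | None = None) -> list[InjectionSite]:
    """Read injection metadata plus per-injection NIfTI masks.

    Each metadata row must either name a ``mask_file`` (resolved against
    ``masks_dir``) or carry explicit centroid/volume columns backed by a
    precomputed overlap table.  Volumes and centroids are recomputed from
    masks when present.
    """
    df = _read_table(meta_path)
    for col in INJECTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"injection table is missing column '{col}'")
    base = Path(masks_dir) if masks_dir is not None else Path(meta_path).parent
    out: list[InjectionSite] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        iid = str(row["injection_id"])
        if iid in seen:
            raise DataError(f"duplicate injection_id: {iid}")
        seen.add(iid)
        category = str(row["category"])
        if ontology is not None and category not in ontology:
            raise DataError(f"injection {iid}: unknown category code '{category}'")
        mask_file = row.get("mask_file")
        if isinstance(mask_file, str) and mask_file.strip():
            mask = VoxelMask.from_nifti(base / mask_file.strip())
            out.append(InjectionSite.from_mask(iid, str(row["brain_id"]), category, mask))
        else:
            if overlap_table is None:
                raise DataError(
                    f"injection {iid}: no mask file and no overlap table supplied")
            try:
                centroid = np.array([float(row["centroid_x_um"]),
                                     float(row["centroid_y_um"]),
                                     float(row["centroid_z_um"])])
                volume = float(row["volume_um3"])
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(
                    f"injection {iid}: mask-less rows need centroid_{{x,y,z}}_um "
                    "and volume_um3 columns") from exc
            out.append(InjectionSite(iid, str(row["brain_id"]), category,
                                     centroid=centroid, volume=volume, mask=None))
    return out


def write_injections(injections: Iterable[InjectionSite], meta_path: str | Path,
                     masks_dir: str | Path | None = None) -> None:
    rows = []
    for inj in injections:
        row = {
            "injection_id": inj.injection_id,
            "brain_id": inj.brain_id,
            "category": inj.category,
            "centroid_x_um": repr(float(inj.centroid[0])),
            "centroid_y_um": repr(float(inj.centroid[1])),
            "centroid_z_um": repr(float(inj.centroid[2])),
            "volume_um3": repr(float(inj.volume)),
            "mask_file": "",
        }
        if inj.mask is not None and masks_dir is not None:
            Path(masks_dir).mkdir(parents=True, exist_ok=True)
            fname = f"{inj.injection_id}.nii"
            inj.mask.to_nifti(Path(masks_dir) / fname)
            row["mask_file"] = fname
        rows.append(row)
    pd.DataFrame(rows).to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Accumulated dataset problems; the dataset is accepted iff empty."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, kind: str, message: str) -> None:
        self.entries.append((kind, message))

    @property
    def ok(self) -> bool:
        return not self.entries

    def __str__(self) -> str:
        if self.ok:
            return "dataset OK"
        return "\n".join(f"[{k}] {m}" for k, m in self.entries)


def validate_dataset(cells: Sequence[CellRecord],
                     injections: Sequence[InjectionSite],
                     ontology: OntologyTable) -> ValidationReport:
    """Cross-check referential integrity of a dataset."""
    report = ValidationReport()
    inj_ids = [i.injection_id for i in injections]
    dup_inj = {i for i in inj_ids if inj_ids.count(i) > 1}
    for d in sorted(dup_inj):
        report.add("duplicate-id", f"duplicate injection_id {d}")
    inj_set = set(inj_ids)
    cell_ids: set[str] = set()
    for c in cells:
        if c.cell_id in cell_ids:
            report.add("duplicate-id", f"duplicate cell_id {c.cell_id}")
        cell_ids.add(c.cell_id)
        for iid in sorted(c.injection_ids):
            if iid not in inj_set:
                report.add("dangling-reference",
                           f"cell {c.cell_id} references unknown injection {iid}")
    covered = {i.category for i in injections}
    for inj in injections:
        if inj.category not in ontology:
            report.add("unknown-category",
                       f"injection {inj.injection_id} has unknown category "
                       f"{inj.category}")
    for code in ontology.codes:
        if code not in covered:
            report.add("empty-category", f"category {code} has no injection")
    return report
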