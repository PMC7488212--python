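"""Core domain containers shared across the pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

ATOMIC_AREAS = ("V1", "V2d", "V2v", "V3d", "V3v", "hV4", "LO", "TO")
COMPOSITE_AREAS = {"V2": ("V2d", "V2v"), "V3": ("V3d", "V3v")}
EXTRASTRIATE_AREAS = ("V2", "V2v", "V2d", "V3", "V3v", "V3d", "hV4", "LO", "TO")

CONTRA = "contralateral"
IPSI = "ipsilateral"


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated cortical patch: 3-D vertex coordinates in mm, faces as
    vertex-index triples, and one unit id per vertex."""

    vertex_coords: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    unit_ids: np.ndarray  # (n,) int

    def __post_init__(self):
        coords = np.asarray(self.vertex_coords, dtype=float)
        faces = np.asarray(self.faces, dtype=int)
        unit_ids = np.asarray(self.unit_ids, dtype=int)
        object.__setattr__(self, "vertex_coords", coords)
        object.__setattr__(self, "faces", faces)
        object.__setattr__(self, "unit_ids", unit_ids)
        n = coords.shape[0]
        if unit_ids.shape != (n,):
            raise ValueError("unit_ids must match vertex count")
        if len(np.unique(unit_ids)) != n:
            raise ValueError("unit_ids must be unique")
        if faces.size and (faces.min() < 0 or faces.max() >= n):
            raise ValueError("face references an invalid vertex")
        for a, b in ((0, 1), (1, 2), (2, 0)):
            if faces.size:
                d = np.linalg.norm(coords[faces[:, a]] - coords[faces[:, b]], axis=1)
                if np.any(d <= 0):
                    raise ValueError("degenerate edge of zero length")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges (k, 2) from the face list."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertex_coords).tobytes())
        h.update(np.ascontiguousarray(self.faces).tobytes())
        h.update(np.ascontiguousarray(self.unit_ids).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class RegionLabeling:
    """Per-unit visual-area label and hemisphere."""

    unit_ids: np.ndarray
    area: np.ndarray  # str labels, one of ATOMIC_AREAS
    hemisphere: np.ndarray  # 'L' | 'R'

    def __post_init__(self):
        unknown = set(np.unique(self.area)) - set(ATOMIC_AREAS)
        if unknown:
            raise ValueError(f"unknown area labels: {sorted(unknown)}")

    def units_in(self, area: str) -> np.ndarray:
        """Unit ids labeled ``area``; composite V2/V3 are exact unions."""
        parts = COMPOSITE_AREAS.get(area, (area,))
        mask = np.isin(self.area, parts)
        return self.unit_ids[mask]


@dataclass(frozen=True)
class RetinotopicMap:
    """Per-unit visual-field assignment."""

    unit_ids: np.ndarray
    ecc_deg: np.ndarray  # >= 0
    polar_deg: np.ndarray
    hemifield: np.ndarray  # CONTRA | IPSI

    def __post_init__(self):
        if np.any(self.ecc_deg < 0):
            raise ValueError("eccentricities must be non-negative")
        unknown = set(np.unique(self.hemifield)) - {CONTRA, IPSI}
        if unknown:
            raise ValueError(f"unknown hemifield flags: {sorted(unknown)}")

    def visual_xy(self) -> np.ndarray:
        """(n, 2) Cartesian visual-field positions in degrees."""
        theta = np.deg2rad(self.polar_deg)
        return np.column_stack(
            [self.ecc_deg * np.cos(theta), self.ecc_deg * np.sin(theta)]
        )


@dataclass(frozen=True)
class CorticalPatch:
    """One area's mesh plus its labeling and retinotopy (aligned by row)."""

    mesh: SurfaceMesh
    labels: RegionLabeling
    retinotopy: RetinotopicMap

    def __post_init__(self):
        if not (
            np.array_equal(self.mesh.unit_ids, self.labels.unit_ids)
            and np.array_equal(self.mesh.unit_ids, self.retinotopy.unit_ids)
        ):
            raise ValueError("mesh, labels and retinotopy must share unit ids")


@dataclass
class Dataset:
    """A subject's bundle of per-area cortical patches with globally
    unique unit ids."""

    patches: dict[str, CorticalPatch]

    def __post_init__(self):
        seen: set[int] = set()
        for area, patch in self.patches.items():
            ids = set(patch.mesh.unit_ids.tolist())
            if ids & seen:
                raise ValueError(f"unit ids of area {area} overlap another patch")
            seen |= ids

    @property
    def areas(self) -> list[str]:
        return list(self.patches)

    @property
    def extrastriate_areas(self) -> list[str]:
        return [a for a in self.patches if a != "V1"]

    def patch(self, area: str) -> CorticalPatch:
        if area not in self.patches:
            raise KeyError(f"area {area} not in dataset (have {self.areas})")
        return self.patches[area]

    def all_unit_ids(self) -> np.ndarray:
        return np.concatenate([p.mesh.unit_ids for p in self.patches.values()])

    def retinotopy_frame(self):
        """Per-unit area/hemi/retinotopy as parallel arrays (dict of np arrays)."""
        cols = {"unit_id": [], "area": [], "hemi": [], "ecc_deg": [],
                "polar_deg": [], "hemifield": []}
        for area, p in self.patches.items():
            cols["unit_id"].append(p.mesh.unit_ids)
            cols["area"].append(p.labels.area)
            cols["hemi"].append(p.labels.hemisphere)
            cols["ecc_deg"].append(p.retinotopy.ecc_deg)
            cols["polar_deg"].append(p.retinotopy.polar_deg)
            cols["hemifield"].append(p.retinotopy.hemifield)
        return {k: np.concatenate(v) for k, v in cols.items()}


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """BOLD series: rows = volumes, columns = units."""

    values: np.ndarray  # (T, n) float
    unit_ids: np.ndarray  # (n,) int
    tr_s: float
    condition: str  # 'stimulus' | 'rest'

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.condition not in ("stimulus", "rest"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.values.shape[1] != len(self.unit_ids):
            raise ValueError("column count must match unit_ids")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return replace(self, values=values)

    def columns_for(self, unit_ids: np.ndarray) -> np.ndarray:
        """Series (T, k) for the requested unit ids, in the given order."""
        index = {u: i for i, u in enumerate(self.unit_ids)}
        missing = [u for u in unit_ids if u not in index]
        if missing:
            raise KeyError(f"units missing from time series: {missing[:5]}")
        cols = [index[u] for u in unit_ids]
        return self.values[:, cols]
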