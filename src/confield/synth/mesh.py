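"""Flat triangulated cortical patches with a retinotopic chart.

Patches are regular grids (1 unit per vertex, default 1 mm spacing)
carrying a smooth log-eccentricity x polar-angle chart. The analysis only
ever consumes geodesic distances, which flat patches exercise fully.
"""

from __future__ import annotations

import numpy as np

from ..types import (
    ATOMIC_AREAS,
    CONTRA,
    IPSI,
    CorticalPatch,
    Dataset,
    RegionLabeling,
    RetinotopicMap,
    SurfaceMesh,
)

MAX_ECC_DEG = 8.0


def build_flat_patch(
    area: str,
    n_rows: int,
    n_cols: int,
    *,
    ecc_range: tuple[float, float] = (0.5, 8.0),
    spacing_mm: float = 1.0,
    hemisphere: str = "L",
    polar_span_deg: float = 160.0,
    ipsi_margin_rows: int = 0,
    unit_id_start: int = 0,
    seed: int | None = None,
    z_jitter_mm: float = 0.0,
) -> CorticalPatch:
    """Build one area's rectangular patch with labels and retinotopy.

    Eccentricity runs log-linearly along columns; polar angle linearly
    along rows. All units are contralateral except an optional strip of
    ``ipsi_margin_rows`` rows placed just past the vertical meridian.
    Deterministic given its arguments (and seed, when z-jitter is used).
    """
    if area not in ATOMIC_AREAS:
        raise ValueError(f"unknown area {area!r}")
    if n_rows < 2 or n_cols < 2 or n_rows * n_cols < 4:
        raise ValueError("patch needs at least a 2x2 grid")
    e0, e1 = ecc_range
    if not (0.0 < e0 < e1 <= MAX_ECC_DEG):
        raise ValueError(
            f"eccentricity coverage must satisfy 0 < lo < hi <= {MAX_ECC_DEG}, "
            f"got {ecc_range}"
        )
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if not (0 <= ipsi_margin_rows < n_rows):
        raise ValueError("ipsi margin must leave at least one contralateral row")

    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack(
        [
            cols.ravel() * spacing_mm,
            rows.ravel() * spacing_mm,
            np.zeros(n_rows * n_cols),
        ]
    )
    if z_jitter_mm > 0:
        rng = np.random.default_rng(seed)
        coords[:, 2] = rng.normal(0.0, z_jitter_mm, size=coords.shape[0])

    faces = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            i = r * n_cols + c
            faces.append((i, i + 1, i + n_cols))
            faces.append((i + n_cols, i + 1, i + n_cols + 1))
    faces = np.asarray(faces, dtype=int)

    n = n_rows * n_cols
    unit_ids = np.arange(unit_id_start, unit_id_start + n)

    # chart: log-ecc along columns, polar angle along rows
    ecc_cols = np.geomspace(e0, e1, n_cols)
    n_contra = n_rows - ipsi_margin_rows
    half = polar_span_deg / 2.0
    polar_rows = np.empty(n_rows)
    polar_rows[:n_contra] = np.linspace(-half, half, n_contra)
    # ipsilateral strip: just past the vertical meridian
    for k in range(ipsi_margin_rows):
        polar_rows[n_contra + k] = 90.0 + 8.0 * (k + 1)
    if hemisphere == "R":
        polar_rows = polar_rows + 180.0
    elif hemisphere != "L":
        raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")

    ecc = np.tile(ecc_cols, n_rows)
    polar = np.repeat(polar_rows, n_cols)
    # contralateral for hemisphere L means right visual field (cos > 0)
    x_field = np.cos(np.deg2rad(polar))
    contra_sign = 1.0 if hemisphere == "L" else -1.0
    hemifield = np.where(contra_sign * x_field > 0, CONTRA, IPSI)

    mesh = SurfaceMesh(vertex_coords=coords, faces=faces, unit_ids=unit_ids)
    labels = RegionLabeling(
        unit_ids=unit_ids,
        area=np.full(n, area, dtype=object),
        hemisphere=np.full(n, hemisphere, dtype=object),
    )
    retinotopy = RetinotopicMap(
        unit_ids=unit_ids, ecc_deg=ecc, polar_deg=polar, hemifield=hemifield
    )
    return CorticalPatch(mesh=mesh, labels=labels, retinotopy=retinotopy)


DEFAULT_AREA_SHAPES: dict[str, tuple[int, int]] = {
    "V1": (10, 13),
    "V2d": (5, 9),
    "V2v": (5, 9),
    "V3d": (5, 9),
    "V3v": (5, 9),
    "hV4": (5, 8),
    "LO": (5, 8),
    "TO": (5, 8),
}


def build_subject(
    area_shapes: dict[str, tuple[int, int]] | None = None,
    *,
    ecc_range: tuple[float, float] = (0.5, 8.0),
    spacing_mm: float = 1.0,
    hemisphere: str = "L",
    ipsi_margin_rows: int = 0,
    seed: int | None = None,
) -> Dataset:
    """One subject's multi-area dataset; unit ids are globally unique."""
    shapes = dict(DEFAULT_AREA_SHAPES if area_shapes is None else area_shapes)
    if "V1" not in shapes:
        raise ValueError("a subject needs a V1 patch")
    patches: dict[str, CorticalPatch] = {}
    start = 0
    for area, (n_rows, n_cols) in shapes.items():
        patches[area] = build_flat_patch(
            area,
            n_rows,
            n_cols,
            ecc_range=ecc_range,
            spacing_mm=spacing_mm,
            hemisphere=hemisphere,
            ipsi_margin_rows=ipsi_margin_rows,
            unit_id_start=start,
            seed=seed,
        )
        start += n_rows * n_cols
    return Dataset(patches=patches)
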