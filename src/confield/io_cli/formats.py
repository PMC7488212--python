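"""Plain-text file formats: ASCII OBJ meshes, TSV unit tables and time
series with a JSON sidecar, plus an optional NIfTI-1 export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..types import (
    CorticalPatch,
    Dataset,
    RegionLabeling,
    RetinotopicMap,
    SurfaceMesh,
    TimeSeriesMatrix,
)

UNITS_TSV = "units.tsv"
UNIT_COLUMNS = ["unit_id", "area", "hemi", "ecc_deg", "polar_deg", "hemifield"]


def write_mesh_obj(mesh: SurfaceMesh, path: Path) -> None:
    """ASCII OBJ: v records in mm, f records 1-based, unit ids as comments."""
    lines = [f"# units {' '.join(str(u) for u in mesh.unit_ids)}"]
    for x, y, z in mesh.vertex_coords:
        lines.append(f"v {x:.9g} {y:.9g} {z:.9g}")
    for a, b, c in mesh.faces:
        lines.append(f"f {a + 1} {b + 1} {c + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_obj(path: Path) -> SurfaceMesh:
    coords, faces, unit_ids = [], [], None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# units "):
            unit_ids = np.array([int(t) for t in line.split()[2:]])
        elif line.startswith("v "):
            coords.append([float(t) for t in line.split()[1:4]])
        elif line.startswith("f "):
            faces.append([int(t.split("/")[0]) - 1 for t in line.split()[1:4]])
    coords = np.asarray(coords)
    if unit_ids is None:
        unit_ids = np.arange(len(coords))
    return SurfaceMesh(
        vertex_coords=coords, faces=np.asarray(faces, dtype=int), unit_ids=unit_ids
    )


def write_units_tsv(dataset: Dataset, path: Path) -> None:
    pd.DataFrame(dataset.retinotopy_frame())[UNIT_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_units_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(UNIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: units table lacks columns {sorted(missing)}")
    return df


def write_dataset(dataset: Dataset, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for area, patch in dataset.patches.items():
        write_mesh_obj(patch.mesh, out_dir / f"mesh_{area}.obj")
    write_units_tsv(dataset, out_dir / UNITS_TSV)


def read_dataset(in_dir: Path) -> Dataset:
    in_dir = Path(in_dir)
    units = read_units_tsv(in_dir / UNITS_TSV)
    patches: dict[str, CorticalPatch] = {}
    for area, sub in units.groupby("area", sort=False):
        mesh = read_mesh_obj(in_dir / f"mesh_{area}.obj")
        sub = sub.set_index("unit_id").loc[mesh.unit_ids].reset_index()
        patches[area] = CorticalPatch(
            mesh=mesh,
            labels=RegionLabeling(
                unit_ids=mesh.unit_ids,
                area=sub["area"].to_numpy(dtype=object),
                hemisphere=sub["hemi"].to_numpy(dtype=object),
            ),
            retinotopy=RetinotopicMap(
                unit_ids=mesh.unit_ids,
                ecc_deg=sub["ecc_deg"].to_numpy(dtype=float),
                polar_deg=sub["polar_deg"].to_numpy(dtype=float),
                hemifield=sub["hemifield"].to_numpy(dtype=object),
            ),
        )
    return Dataset(patches=patches)


def write_timeseries(ts: TimeSeriesMatrix, path: Path) -> None:
    """TSV matrix (rows = volumes, columns = unit_<id>) with a JSON
    sidecar carrying TR and condition."""
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=[f"unit_{u}" for u in ts.unit_ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"tr_s": ts.tr_s, "condition": ts.condition}, indent=1)
    )


def read_timeseries(path: Path) -> TimeSeriesMatrix:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t")
    unit_ids = np.array([int(c.removeprefix("unit_")) for c in df.columns])
    return TimeSeriesMatrix(
        values=df.to_numpy(dtype=float),
        unit_ids=unit_ids,
        tr_s=float(meta["tr_s"]),
        condition=str(meta["condition"]),
    )


def export_nifti(ts: TimeSeriesMatrix, path: Path) -> None:
    """Optional NIfTI-1 export as a 1 x 1 x n_units x T volume."""
    import nibabel as nib

    data = ts.values.T[None, None, :, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_s))
    nib.save(img, str(path))


def validate_bundle(dataset: Dataset, ts: TimeSeriesMatrix,
                    expected_tr_s: float | None = None) -> None:
    """Cross-validate a loaded bundle: every time-series column must have
    a labeled, retinotopically mapped unit; TR must match the config."""
    known = set(int(u) for u in dataset.all_unit_ids())
    orphans = [int(u) for u in ts.unit_ids if int(u) not in known]
    if orphans:
        raise ValueError(
            f"time-series units missing from labels/retinotopy: {orphans[:5]}"
        )
    missing = sorted(known - set(int(u) for u in ts.unit_ids))
    if missing:
        raise ValueError(f"labeled units missing a time series: {missing[:5]}")
    if expected_tr_s is not None and abs(ts.tr_s - expected_tr_s) > 1e-9:
        raise ValueError(
            f"TR mismatch: sidecar has {ts.tr_s} s, config expects {expected_tr_s} s"
        )
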