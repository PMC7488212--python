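"""Circular Gaussian connective-field fitting on cortical patches.

A connective field predicts one target unit's series as a gain times the
Gaussian-weighted sum of source-region series, with the Gaussian defined
over geodesic distance on the source surface. Fitting is an exhaustive
search over every source unit as candidate center v0 and a fixed size
grid; variance explained breaks ties toward smaller sigma, then smaller
v0 index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .types import CONTRA, COMPOSITE_AREAS, Dataset, SurfaceMesh, TimeSeriesMatrix

POINT_CF_SIGMA_MM = 0.0001
VE_THRESHOLD = 0.20


def sigma_grid() -> np.ndarray:
    """The candidate CF sizes: 0.0001 mm then 0.2 mm steps up to 10 mm."""
    return np.concatenate([[POINT_CF_SIGMA_MM], np.arange(1, 51) * 0.2])


# ---------------------------------------------------------------------------
# Geodesic distances
# ---------------------------------------------------------------------------

def geodesic_distances(mesh: SurfaceMesh, roi_unit_ids: Optional[np.ndarray] = None) -> np.ndarray:
    """All-pairs shortest-path distances (mm) over the mesh edge graph,
    restricted to the ROI's vertices.

    Edge weights are Euclidean lengths. The ROI must be connected within
    its own subgraph; otherwise the component sizes are reported.
    """
    if roi_unit_ids is None:
        roi_unit_ids = mesh.unit_ids
    roi_unit_ids = np.asarray(roi_unit_ids)
    id_to_vertex = {u: i for i, u in enumerate(mesh.unit_ids)}
    try:
        verts = np.array([id_to_vertex[u] for u in roi_unit_ids])
    except KeyError as exc:
        raise KeyError(f"unit {exc.args[0]} not in mesh") from None

    k = len(verts)
    if k == 1:
        return np.zeros((1, 1))
    in_roi = np.full(mesh.n_vertices, -1, dtype=int)
    in_roi[verts] = np.arange(k)
    edges = mesh.edges()
    keep = (in_roi[edges[:, 0]] >= 0) & (in_roi[edges[:, 1]] >= 0)
    edges = edges[keep]
    lengths = np.linalg.norm(
        mesh.vertex_coords[edges[:, 0]] - mesh.vertex_coords[edges[:, 1]], axis=1
    )
    i = in_roi[edges[:, 0]]
    j = in_roi[edges[:, 1]]
    graph = coo_matrix((lengths, (i, j)), shape=(k, k)).tocsr()

    n_comp, comp = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"ROI is disconnected on the mesh: {n_comp} components "
            f"with sizes {sizes.tolist()}"
        )
    dist = shortest_path(graph, method="D", directed=False)
    return dist


class DistanceCache:
    """Per-(mesh, ROI) geodesic distance cache keyed by mesh content hash,
    so mutating a mesh invalidates its entries."""

    def __init__(self):
        self._store: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}

    def get(self, mesh: SurfaceMesh, roi_unit_ids: np.ndarray) -> np.ndarray:
        key = (mesh.content_hash(), tuple(int(u) for u in roi_unit_ids))
        if key not in self._store:
            self._store[key] = geodesic_distances(mesh, roi_unit_ids)
        return self._store[key]


# ---------------------------------------------------------------------------
# Weights and fitting
# ---------------------------------------------------------------------------

def cf_weights(distances_from_v0: np.ndarray, sigma_mm: float) -> np.ndarray:
    """Normalized circular Gaussian weights w_i = exp(-d_i^2 / 2 sigma^2)."""
    if sigma_mm <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_mm}")
    d = np.asarray(distances_from_v0, dtype=float)
    w = np.exp(-(d**2) / (2.0 * sigma_mm**2))
    total = w.sum()
    if total == 0:
        raise ValueError("all weights underflowed to zero")
    return w / total


@dataclass(frozen=True)
class CFFit:
    """One target unit's fitted connective field."""

    target_unit: int
    source_roi: str
    v0_unit: int
    sigma_mm: float
    gain: float
    variance_explained: float
    sampling_extent_mm: Optional[float] = None
    ok: bool = True


def fit_cf_batch(
    targets: np.ndarray,
    sources: np.ndarray,
    distances: np.ndarray,
    grid: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Exhaustive CF fit for many targets at once.

    targets: (T, m); sources: (T, k) ordered like ``distances`` (k, k).
    Returns arrays v0_index, sigma_mm, gain, ve, ok. Prediction for a
    candidate (v0, sigma) is gain * sum_i w_i * source_i(t) with the
    non-negative least-squares gain; VE = max(0, 1 - RSS/TSS). Ties on VE
    resolve to the smaller sigma, then the smaller v0 index.
    """
    if grid is None:
        grid = sigma_grid()
    targets = np.asarray(targets, dtype=float)
    sources = np.asarray(sources, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    T, m = targets.shape
    k = sources.shape[1]
    if distances.shape != (k, k):
        raise ValueError("distance matrix does not match source count")

    tss = np.sum((targets - targets.mean(axis=0)) ** 2, axis=0)
    ttot = np.sum(targets**2, axis=0)
    ok = tss > 0

    best_ve = np.full(m, -1.0)
    best_sigma = np.zeros(m)
    best_v0 = np.zeros(m, dtype=int)
    best_gain = np.zeros(m)

    d2 = distances**2
    safe_tss = np.where(ok, tss, 1.0)
    for sigma in grid:  # ascending: strict improvement keeps smaller sigma
        w = np.exp(-d2 / (2.0 * sigma**2))
        w /= w.sum(axis=1, keepdims=True)
        preds = sources @ w.T  # (T, k) column j = prediction centered at v0=j
        pp = np.maximum(np.sum(preds**2, axis=0), 1e-300)
        cross = targets.T @ preds  # (m, k)
        cross_pos = np.maximum(cross, 0.0)
        rss = ttot[:, None] - cross_pos**2 / pp[None, :]
        ve = np.maximum(0.0, 1.0 - rss / safe_tss[:, None])
        j = np.argmax(ve, axis=1)  # first max -> smallest v0 index
        ve_j = ve[np.arange(m), j]
        improve = ve_j > best_ve + 1e-15
        best_ve[improve] = ve_j[improve]
        best_sigma[improve] = sigma
        best_v0[improve] = j[improve]
        best_gain[improve] = (cross_pos[np.arange(m), j] / pp[j])[improve]

    best_ve[~ok] = np.nan
    return {
        "v0_index": best_v0,
        "sigma_mm": best_sigma,
        "gain": best_gain,
        "ve": np.clip(best_ve, 0.0, 1.0),
        "ok": ok,
    }


def fit_cf(
    target_series: np.ndarray,
    source_series_matrix: np.ndarray,
    distances: np.ndarray,
    grid: Optional[np.ndarray] = None,
    *,
    target_unit: int = -1,
    source_roi: str = "",
    source_unit_ids: Optional[np.ndarray] = None,
) -> CFFit:
    """Fit a single target unit; see :func:`fit_cf_batch`."""
    if np.var(np.asarray(target_series, dtype=float)) == 0:
        raise ValueError("target series has zero variance")
    res = fit_cf_batch(np.asarray(target_series)[:, None], source_series_matrix,
                       distances, grid)
    v0_idx = int(res["v0_index"][0])
    v0_unit = v0_idx if source_unit_ids is None else int(source_unit_ids[v0_idx])
    return CFFit(
        target_unit=target_unit,
        source_roi=source_roi,
        v0_unit=v0_unit,
        sigma_mm=float(res["sigma_mm"][0]),
        gain=float(res["gain"][0]),
        variance_explained=float(res["ve"][0]),
    )


# ---------------------------------------------------------------------------
# Sampling extent
# ---------------------------------------------------------------------------

def _truncated_rms_extent(
    distances_from_v0: np.ndarray,
    sigma_mm: float,
    contra_mask: np.ndarray,
    weight_floor: float = 1e-6,
) -> float:
    """sigma scaled by the ratio of the contralateral-truncated to the
    full weighted-RMS distance from v0.

    Equal to sigma exactly when no ipsilateral unit carries unnormalized
    weight above ``weight_floor``.
    """
    d = np.asarray(distances_from_v0, dtype=float)
    w = np.exp(-(d**2) / (2.0 * sigma_mm**2))
    active = w > weight_floor
    if not np.any(active & contra_mask):
        raise ValueError("connective field is supported entirely ipsilaterally")
    if not np.any(active & ~contra_mask):
        return float(sigma_mm)  # wholly contralateral: calibrated to sigma
    def _rms(mask):
        ww = w[mask]
        return np.sqrt(np.sum(ww * d[mask] ** 2) / np.sum(ww))
    rms_all = _rms(active)
    if rms_all == 0:
        return float(sigma_mm)
    return float(sigma_mm * _rms(active & contra_mask) / rms_all)


SAMPLING_EXTENT_POLICIES: dict[str, Callable[..., float]] = {
    "truncated_rms": _truncated_rms_extent,
}


def sampling_extent(
    fit: CFFit,
    hemifield: np.ndarray,
    distances: np.ndarray,
    v0_index: int,
    *,
    policy: str = "truncated_rms",
) -> float:
    """CF size corrected for ipsilateral representations (named policy).

    ``hemifield`` holds the source units' hemifield flags ordered like
    ``distances``; ``v0_index`` is the fitted center's row.
    """
    if fit.sigma_mm <= 0:
        raise ValueError("sampling extent needs sigma > 0")
    fn = SAMPLING_EXTENT_POLICIES[policy]
    contra = np.asarray(hemifield) == CONTRA
    return fn(distances[v0_index], fit.sigma_mm, contra)


# ---------------------------------------------------------------------------
# Area-pair fitting on a dataset
# ---------------------------------------------------------------------------

CF_TABLE_COLUMNS = [
    "target_unit", "source_roi", "target_roi", "v0", "sigma_mm", "gain",
    "ve", "sampling_extent_mm", "target_ecc_deg",
]


def _atomic_parts(area: str) -> tuple[str, ...]:
    return COMPOSITE_AREAS.get(area, (area,))


def fit_area_pair(
    dataset: Dataset,
    ts: TimeSeriesMatrix,
    source_area: str,
    target_area: str,
    *,
    grid: Optional[np.ndarray] = None,
    cache: Optional[DistanceCache] = None,
    extent_policy: str = "truncated_rms",
) -> pd.DataFrame:
    """Fit CFs for every unit of ``target_area`` from ``source_area``.

    Composite areas (V2, V3) expand to their dorsal/ventral parts: as a
    target they pool the per-voxel fits; as a source each target voxel
    keeps the sub-source fit with the higher VE (equivalent to searching
    v0 over the union ROI, whose parts are mutually unreachable).
    """
    cache = cache or DistanceCache()
    grid = sigma_grid() if grid is None else grid
    rows: list[pd.DataFrame] = []
    for tgt in _atomic_parts(target_area):
        tgt_patch = dataset.patch(tgt)
        tgt_units = tgt_patch.mesh.unit_ids
        targets = ts.columns_for(tgt_units)
        per_source: list[pd.DataFrame] = []
        for src in _atomic_parts(source_area):
            src_patch = dataset.patch(src)
            src_units = src_patch.mesh.unit_ids
            sources = ts.columns_for(src_units)
            dist = cache.get(src_patch.mesh, src_units)
            res = fit_cf_batch(targets, sources, dist, grid)
            extents = np.full(len(tgt_units), np.nan)
            contra = src_patch.retinotopy.hemifield == CONTRA
            for idx in range(len(tgt_units)):
                if not res["ok"][idx]:
                    continue
                extents[idx] = _truncated_rms_extent(
                    dist[res["v0_index"][idx]], res["sigma_mm"][idx], contra
                ) if extent_policy == "truncated_rms" else SAMPLING_EXTENT_POLICIES[
                    extent_policy
                ](dist[res["v0_index"][idx]], res["sigma_mm"][idx], contra)
            per_source.append(
                pd.DataFrame(
                    {
                        "target_unit": tgt_units,
                        "source_roi": source_area,
                        "target_roi": target_area,
                        "v0": src_units[res["v0_index"]],
                        "sigma_mm": res["sigma_mm"],
                        "gain": res["gain"],
                        "ve": np.where(res["ok"], res["ve"], np.nan),
                        "sampling_extent_mm": extents,
                        "target_ecc_deg": tgt_patch.retinotopy.ecc_deg,
                    }
                )
            )
        if len(per_source) == 1:
            rows.append(per_source[0])
        else:  # composite source: keep best-VE sub-fit per target voxel
            stacked = pd.concat(per_source, ignore_index=True)
            best = stacked.loc[
                stacked.groupby("target_unit")["ve"].idxmax().dropna().astype(int)
            ]
            rows.append(best)
    out = pd.concat(rows, ignore_index=True)
    return out[CF_TABLE_COLUMNS]
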