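"""Sampling-extent summaries, convergence magnitudes, hierarchy slopes,
and the bias-variable audit.

Conventions: the eccentricity window is applied to the TARGET unit's
retinotopic eccentricity and is inclusive on both ends; the weighted
median is the lower weighted median (no interpolation); composite V2/V3
summaries pool the dorsal/ventral fits rather than averaging sub-area
medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cf_model import POINT_CF_SIGMA_MM, VE_THRESHOLD
from .stats import bonferroni, rank_sum_test, spearman_corr
from .synth.truth import HIERARCHY_LEVEL

ECC_WINDOW_DEG = (0.5, 7.5)

STREAMS: dict[str, tuple[str, ...]] = {
    "both": ("V2", "V3", "hV4", "LO", "TO"),
    "dorsal": ("V2d", "V3d", "TO"),
    "ventral": ("V2v", "V3v", "hV4", "LO"),
}

AUDIT_VARIABLES = ("d_median_ve", "d_n_voxels", "d_prop_point_cf", "d_mean_ecc")


def hierarchy_level(area: str) -> float:
    """Ordinal position of a visual area (V1=0 ... TO=5.5)."""
    try:
        return HIERARCHY_LEVEL[area]
    except KeyError:
        raise ValueError(f"unknown area name {area!r}") from None


@dataclass(frozen=True)
class SamplingExtentSummary:
    subject: str
    direction: str  # 'fwd' (V1 -> x) | 'bwd' (x -> V1)
    area: str
    weighted_median_se_mm: float
    n_voxels_included: int
    proportion_excluded_point_cf: float
    median_ve: float
    mean_target_ecc_deg: float


@dataclass(frozen=True)
class ConvergenceRecord:
    subject: str
    area: str
    convergence_magnitude_mm: float


@dataclass(frozen=True)
class HierarchySlopeFit:
    subject: str
    stream: str
    slope_mm_per_level: float
    intercept_mm: float


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: smallest v with cumulative weight of items
    <= v reaching at least half the total weight."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = np.searchsorted(cum, 0.5 * cum[-1], side="left")
    return float(values[order][idx])


def select_voxels(
    cf_table: pd.DataFrame,
    ve_min: float = VE_THRESHOLD,
    ecc_window: tuple[float, float] = ECC_WINDOW_DEG,
    point_cf_sigma: float = POINT_CF_SIGMA_MM,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows with ve >= ve_min, sigma > point_cf_sigma, and target
    eccentricity inside the (inclusive) window.

    Exclusion tallies are mutually exclusive, counted in the order
    ve -> point_cf -> eccentricity.
    """
    required = {"ve", "sigma_mm", "target_ecc_deg"}
    missing = required - set(cf_table.columns)
    if missing:
        raise ValueError(f"cf table lacks columns {sorted(missing)}")
    ve_ok = cf_table["ve"] >= ve_min
    not_point = cf_table["sigma_mm"] > point_cf_sigma
    in_window = cf_table["target_ecc_deg"].between(*ecc_window, inclusive="both")
    tallies = {
        "ve": int((~ve_ok).sum()),
        "point_cf": int((ve_ok & ~not_point).sum()),
        "eccentricity": int((ve_ok & not_point & ~in_window).sum()),
    }
    kept = cf_table[ve_ok & not_point & in_window]
    return kept, tallies


def summarize_direction(
    cf_table: pd.DataFrame,
    subject: str,
    direction: str,
    area: str,
    *,
    ve_min: float = VE_THRESHOLD,
    ecc_window: tuple[float, float] = ECC_WINDOW_DEG,
) -> SamplingExtentSummary:
    """VE-weighted median sampling extent over the selected voxels.

    The point-CF proportion is counted among voxels passing the VE
    threshold inside the eccentricity window.
    """
    kept, _ = select_voxels(cf_table, ve_min=ve_min, ecc_window=ecc_window)
    in_window = cf_table["target_ecc_deg"].between(*ecc_window, inclusive="both")
    ve_pass = (cf_table["ve"] >= ve_min) & in_window
    n_ve_pass = int(ve_pass.sum())
    n_point = int((ve_pass & (cf_table["sigma_mm"] <= POINT_CF_SIGMA_MM)).sum())
    if len(kept) == 0:
        return SamplingExtentSummary(
            subject, direction, area,
            weighted_median_se_mm=float("nan"),
            n_voxels_included=0,
            proportion_excluded_point_cf=(n_point / n_ve_pass) if n_ve_pass else float("nan"),
            median_ve=float("nan"),
            mean_target_ecc_deg=float("nan"),
        )
    wm = weighted_median(kept["sampling_extent_mm"].to_numpy(), kept["ve"].to_numpy())
    return SamplingExtentSummary(
        subject=subject,
        direction=direction,
        area=area,
        weighted_median_se_mm=wm,
        n_voxels_included=int(len(kept)),
        proportion_excluded_point_cf=(n_point / n_ve_pass) if n_ve_pass else 0.0,
        median_ve=float(kept["ve"].median()),
        mean_target_ecc_deg=float(kept["target_ecc_deg"].mean()),
    )


def convergence_magnitude(se_fwd_mm: float, se_bwd_mm: float) -> float:
    """SE(V1 -> x) - SE(x -> V1); positive means convergence."""
    if not (np.isfinite(se_fwd_mm) and np.isfinite(se_bwd_mm)):
        raise ValueError("sampling extents must be finite")
    return se_fwd_mm - se_bwd_mm


def fit_hierarchy_slope(
    records: Mapping[str, float],
    stream: str,
    *,
    subject: str = "",
) -> HierarchySlopeFit:
    """OLS of convergence magnitude on hierarchy level over the stream's
    area set."""
    if stream not in STREAMS:
        raise ValueError(f"unknown stream {stream!r} (want {list(STREAMS)})")
    areas = [a for a in STREAMS[stream] if a in records and np.isfinite(records[a])]
    levels = np.array([hierarchy_level(a) for a in areas])
    if len(set(levels.tolist())) < 2:
        raise ValueError(
            f"stream {stream!r} needs >= 2 distinct hierarchy levels, "
            f"got areas {areas}"
        )
    y = np.array([records[a] for a in areas])
    slope, intercept = np.polyfit(levels, y, 1)
    return HierarchySlopeFit(
        subject=subject, stream=stream,
        slope_mm_per_level=float(slope), intercept_mm=float(intercept),
    )


def bias_audit(
    table: pd.DataFrame,
    *,
    variables: Sequence[str] = AUDIT_VARIABLES,
    group_col: str = "group",
    magnitude_col: str = "convergence_magnitude_mm",
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Audit direction-difference variables for group confounds.

    ``table`` has one row per subject x area with the direction
    differences (V1->x minus x->V1) of each audited variable, the group
    label, and the convergence magnitude. Per area and variable an exact
    rank-sum test compares groups (Bonferroni over the variables); for
    each significant variable the Spearman correlation with convergence
    magnitude across all subjects is reported, Bonferroni-corrected the
    same way.
    """
    missing = [v for v in variables if v not in table.columns]
    for col in (group_col, magnitude_col, "area", "subject"):
        if col not in table.columns:
            missing.append(col)
    if missing:
        raise ValueError(f"audit table lacks columns {missing}")
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    m = len(variables)
    rows = []
    for area, sub in table.groupby("area", sort=False):
        a = sub[sub[group_col] == groups[0]]
        b = sub[sub[group_col] == groups[1]]
        for var in variables:
            res = rank_sum_test(
                a[var].to_numpy(), b[var].to_numpy(),
                correction_factor=m, seed=seed,
            )
            significant = res.p_corrected < alpha
            rho = rho_p = np.nan
            if significant:
                rho, p = spearman_corr(
                    sub[var].to_numpy(), sub[magnitude_col].to_numpy()
                )
                rho_p = bonferroni(p, m)
            rows.append(
                {
                    "area": area,
                    "variable": var,
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "p_corrected": res.p_corrected,
                    "significant": significant,
                    "spearman_rho": rho,
                    "spearman_p_corrected": rho_p,
                }
            )
    return pd.DataFrame(rows)
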