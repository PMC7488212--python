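"""End-to-end pipeline: simulate (or load), preprocess, fit both
directions, summarize, and run the group inference."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..cf_model import (
    DistanceCache,
    POINT_CF_SIGMA_MM,
    fit_area_pair,
    sigma_grid,
)
from ..convergence import (
    bias_audit,
    convergence_magnitude,
    fit_hierarchy_slope,
    summarize_direction,
)
from ..preprocess import preprocess_run
from ..stats import TestResult, rank_sum_test, signed_rank_test
from ..synth import build_subject, make_bar_stimulus, make_group_truth
from ..synth.runs import simulate_rest_run, simulate_stimulus_run
from ..types import COMPOSITE_AREAS, Dataset, TimeSeriesMatrix
from .config import RunConfig


def config_sigma_grid(config: RunConfig) -> np.ndarray:
    n = int(round(config.sigma_grid_max_mm / config.sigma_grid_step_mm))
    return np.concatenate(
        [[POINT_CF_SIGMA_MM], np.arange(1, n + 1) * config.sigma_grid_step_mm]
    )


@dataclass
class SubjectResult:
    subject: str
    group: str
    cf_tables: dict[tuple[str, str], pd.DataFrame]  # (direction, area)
    summaries: pd.DataFrame
    convergence: pd.DataFrame
    slopes: pd.DataFrame


def _composite_table(tables: list[pd.DataFrame], direction: str) -> pd.DataFrame:
    """Pool dorsal/ventral fits: plain union for forward fits (disjoint
    targets); best-VE per target voxel for backward fits, where the same
    V1 voxels were fitted from each sub-source."""
    stacked = pd.concat(tables, ignore_index=True)
    if direction == "fwd":
        return stacked
    idx = stacked.groupby("target_unit")["ve"].idxmax().dropna().astype(int)
    return stacked.loc[idx].reset_index(drop=True)


def analyze_subject(
    dataset: Dataset,
    ts: TimeSeriesMatrix,
    *,
    subject: str,
    group: str = "",
    config: RunConfig | None = None,
    cache: DistanceCache | None = None,
    preprocessed: bool = False,
) -> SubjectResult:
    """Fit connective fields in both directions for every configured area
    and reduce them to summaries, convergence records, and stream slopes."""
    config = config or RunConfig()
    cache = cache or DistanceCache()
    grid = config_sigma_grid(config)
    if not preprocessed:
        ts = preprocess_run(ts)

    atomic = [a for a in config.areas if a not in COMPOSITE_AREAS and a in dataset.patches]
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for area in atomic:
        tables[("fwd", area)] = fit_area_pair(dataset, ts, "V1", area, grid=grid, cache=cache)
        tables[("bwd", area)] = fit_area_pair(dataset, ts, area, "V1", grid=grid, cache=cache)
    for comp, parts in COMPOSITE_AREAS.items():
        if comp in config.areas and all(p in dataset.patches for p in parts):
            for direction in ("fwd", "bwd"):
                tables[(direction, comp)] = _composite_table(
                    [tables[(direction, p)] for p in parts], direction
                )

    sum_rows, conv_rows = [], []
    for area in config.areas:
        if ("fwd", area) not in tables:
            continue
        s_fwd = summarize_direction(
            tables[("fwd", area)], subject, "fwd", area,
            ve_min=config.ve_threshold, ecc_window=config.ecc_window_deg,
        )
        s_bwd = summarize_direction(
            tables[("bwd", area)], subject, "bwd", area,
            ve_min=config.ve_threshold, ecc_window=config.ecc_window_deg,
        )
        sum_rows += [asdict(s_fwd), asdict(s_bwd)]
        conv_rows.append(
            {
                "subject": subject,
                "group": group,
                "area": area,
                "convergence_magnitude_mm": convergence_magnitude(
                    s_fwd.weighted_median_se_mm, s_bwd.weighted_median_se_mm
                ),
                "d_median_ve": s_fwd.median_ve - s_bwd.median_ve,
                "d_n_voxels": s_fwd.n_voxels_included - s_bwd.n_voxels_included,
                "d_prop_point_cf": s_fwd.proportion_excluded_point_cf
                - s_bwd.proportion_excluded_point_cf,
                "d_mean_ecc": s_fwd.mean_target_ecc_deg - s_bwd.mean_target_ecc_deg,
            }
        )
    convergence = pd.DataFrame(conv_rows)

    slope_rows = []
    records = dict(zip(convergence["area"], convergence["convergence_magnitude_mm"]))
    for stream in config.streams:
        fit = fit_hierarchy_slope(records, stream, subject=subject)
        slope_rows.append(
            {
                "subject": subject,
                "group": group,
                "stream": stream,
                "slope_mm_per_level": fit.slope_mm_per_level,
                "intercept_mm": fit.intercept_mm,
            }
        )

    summaries = pd.DataFrame(sum_rows)
    return SubjectResult(
        subject=subject,
        group=group,
        cf_tables=tables,
        summaries=summaries,
        convergence=convergence,
        slopes=pd.DataFrame(slope_rows),
    )


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

def simulate_subject_run(
    group: str,
    subject_seed: int,
    *,
    condition: str = "stimulus",
    noise_sd: float | None = None,
    area_shapes: dict[str, tuple[int, int]] | None = None,
) -> tuple[Dataset, TimeSeriesMatrix]:
    """One subject's dataset plus a simulated run of the given condition."""
    dataset = build_subject(area_shapes)
    truth = make_group_truth(group, subject_seed,
                             **({"noise_sd": noise_sd} if noise_sd is not None else {}))
    if condition == "stimulus":
        movie = make_bar_stimulus(grid_n=48)
        ts = simulate_stimulus_run(dataset, truth, movie, seed=subject_seed * 7 + 1)
    elif condition == "rest":
        ts = simulate_rest_run(dataset, truth, seed=subject_seed * 7 + 1)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return dataset, ts


def run_cohort(
    config: RunConfig,
    *,
    replicate_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze a control + patient cohort.

    Returns (summaries, convergence, slopes) stacked over subjects.
    """
    base = config.seed if replicate_seed is None else replicate_seed
    all_sum, all_conv, all_slope = [], [], []
    specs = [("control", i) for i in range(config.n_controls)] + [
        ("patient", i) for i in range(config.n_patients)
    ]
    for group, i in specs:
        subject_seed = base * 1000 + (0 if group == "control" else 500) + i
        dataset, ts = simulate_subject_run(
            group, subject_seed, condition=config.condition, noise_sd=config.noise_sd
        )
        res = analyze_subject(
            dataset, ts, subject=f"{group}_{i:02d}", group=group, config=config
        )
        all_sum.append(res.summaries)
        all_conv.append(res.convergence)
        all_slope.append(res.slopes)
    return (
        pd.concat(all_sum, ignore_index=True),
        pd.concat(all_conv, ignore_index=True),
        pd.concat(all_slope, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Group inference
# ---------------------------------------------------------------------------

def _result_row(res: TestResult, **extra) -> dict:
    row = asdict(res)
    row.update(extra)
    return row


def group_inference(
    convergence: pd.DataFrame, slopes: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """The full test battery.

    Per stream (Bonferroni over the streams): each group's slopes vs 0 by
    exact signed rank, and control vs patient slopes by exact rank sum.
    Per area (Bonferroni over the areas): control vs patient convergence
    magnitude by exact rank sum.
    """
    config = config or RunConfig()
    rows = []
    m_s = config.bonferroni_streams
    slope_groups = slopes.groupby("stream", sort=False) if len(slopes) else []
    for stream, sub in slope_groups:
        for group, g in sub.groupby("group", sort=False):
            res = signed_rank_test(
                g["slope_mm_per_level"].to_numpy(), correction_factor=m_s,
                seed=config.seed,
            )
            rows.append(_result_row(res, design="slope_vs_zero", stream=stream,
                                    group=group, area=""))
        ctrl = sub[sub["group"] == "control"]["slope_mm_per_level"].to_numpy()
        pat = sub[sub["group"] == "patient"]["slope_mm_per_level"].to_numpy()
        if len(ctrl) and len(pat):
            res = rank_sum_test(ctrl, pat, correction_factor=m_s, seed=config.seed)
            rows.append(_result_row(res, design="slope_group_compare",
                                    stream=stream, group="control_vs_patient", area=""))
    m_a = config.bonferroni_areas
    conv_groups = convergence.groupby("area", sort=False) if len(convergence) else []
    for area, sub in conv_groups:
        ctrl = sub[sub["group"] == "control"]["convergence_magnitude_mm"].to_numpy()
        pat = sub[sub["group"] == "patient"]["convergence_magnitude_mm"].to_numpy()
        if len(ctrl) and len(pat):
            res = rank_sum_test(ctrl, pat, correction_factor=m_a, seed=config.seed)
            rows.append(_result_row(res, design="convergence_group_compare",
                                    stream="", group="control_vs_patient", area=area))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def bootstrap_se_median(
    values: np.ndarray, *, n_boot: int = 10_000, seed: int = 0
) -> float:
    """Standard error of the median by seeded bootstrap; 0 for a single
    value (resampling is degenerate there)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if values.size == 1:
        return 0.0
    rng = np.random.default_rng(seed)
    draws = rng.choice(values, size=(n_boot, values.size), replace=True)
    return float(np.median(draws, axis=1).std(ddof=1))


def report(
    convergence: pd.DataFrame,
    slopes: pd.DataFrame,
    *,
    n_boot: int = 10_000,
    seed: int = 0,
) -> str:
    """Human-readable per-area and per-stream tables of
    median +/- bootstrap standard error of the median."""
    lines = ["Convergence magnitude (mm), median +/- SE of median", ""]
    conv_groups = (
        convergence.groupby(["area", "group"], sort=False) if len(convergence) else []
    )
    for (area, group), sub in conv_groups:
        v = sub["convergence_magnitude_mm"].to_numpy()
        se = bootstrap_se_median(v, n_boot=n_boot, seed=seed)
        lines.append(f"  {area:>4} {group:>8}: {np.median(v):6.2f} +/- {se:.2f} (n={len(v)})")
    lines += ["", "Hierarchy slope (mm/level), median +/- SE of median", ""]
    slope_groups = (
        slopes.groupby(["stream", "group"], sort=False) if len(slopes) else []
    )
    for (stream, group), sub in slope_groups:
        v = sub["slope_mm_per_level"].to_numpy()
        se = bootstrap_se_median(v, n_boot=n_boot, seed=seed)
        lines.append(f"  {stream:>7} {group:>8}: {np.median(v):6.2f} +/- {se:.2f} (n={len(v)})")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir: Path) -> dict[str, pd.DataFrame]:
    """Simulate a cohort, run the analysis and inference, write every
    table as TSV plus a provenance JSON. Deterministic given the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries, convergence, slopes = run_cohort(config)
    tests = group_inference(convergence, slopes, config)
    audit = bias_audit(convergence, seed=config.seed)
    results = {
        "summaries": summaries,
        "convergence": convergence,
        "slopes": slopes,
        "tests": tests,
        "bias_audit": audit,
    }
    for name, df in results.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    (out_dir / "report.txt").write_text(
        report(convergence, slopes, seed=config.seed) + "\n"
    )
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "confield": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return results
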