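"""Forward simulation of stimulus and resting-state BOLD runs.

Stimulus runs: V1 units are driven by a pRF response to the bar movie;
each extrastriate unit is a Gaussian-kernel-weighted sum of V1 drives
over the V1 surface (forward width); V1 optionally mixes back a
component propagated from extrastriate drives through the backward
kernel. Everything is convolved with a double-gamma HRF and degraded
with white noise plus a random linear drift.

Resting runs: a spatially smooth, temporally band-limited latent field
over visual space is sampled at each unit's visual position and
propagated through the same direction-specific kernels.
"""

from __future__ import annotations

import numpy as np

from ..cf_model import DistanceCache, cf_weights
from ..types import Dataset, TimeSeriesMatrix
from .hrf import convolve_hrf
from .stimulus import StimulusMovie, prf_response_matrix
from .truth import GroundTruth

DEFAULT_PRF_BASE_DEG = 0.5
DEFAULT_PRF_SLOPE = 0.2
REST_N_VOLUMES = 240
REST_TR_S = 2.0


def _coupling_matrix(
    dataset: Dataset,
    source_area: str,
    target_area: str,
    width_mm: float,
    cache: DistanceCache,
) -> np.ndarray:
    """(n_target, n_source) rows = normalized Gaussian kernels on the
    source surface, centered at the source unit nearest each target
    unit's visual-field position."""
    if width_mm <= 0:
        raise ValueError(f"kernel width must be > 0, got {width_mm}")
    src = dataset.patch(source_area)
    tgt = dataset.patch(target_area)
    src_xy = src.retinotopy.visual_xy()
    tgt_xy = tgt.retinotopy.visual_xy()
    dist = cache.get(src.mesh, src.mesh.unit_ids)
    d2 = (
        (tgt_xy[:, 0][:, None] - src_xy[:, 0][None, :]) ** 2
        + (tgt_xy[:, 1][:, None] - src_xy[:, 1][None, :]) ** 2
    )
    centers = np.argmin(d2, axis=1)
    rows = [cf_weights(dist[c], width_mm) for c in centers]
    return np.asarray(rows)


def _add_noise(
    signal: np.ndarray, noise_sd: float, drift_sd: float, rng: np.random.Generator
) -> np.ndarray:
    T, n = signal.shape
    out = signal.copy()
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=(T, n))
    if drift_sd > 0:
        ramp = np.linspace(-0.5, 0.5, T)
        out += ramp[:, None] * rng.normal(0.0, drift_sd, size=n)[None, :]
    return out


def _assemble(dataset: Dataset, series: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    cols = [series[a] for a in dataset.areas]
    ids = [dataset.patch(a).mesh.unit_ids for a in dataset.areas]
    return np.concatenate(cols, axis=1), np.concatenate(ids)


def simulate_stimulus_run(
    dataset: Dataset,
    truth: GroundTruth,
    movie: StimulusMovie,
    *,
    seed: int,
    noise_sd: float | None = None,
    feedback_fraction: float | None = None,
    prf_base_deg: float = DEFAULT_PRF_BASE_DEG,
    prf_slope: float = DEFAULT_PRF_SLOPE,
    cache: DistanceCache | None = None,
) -> TimeSeriesMatrix:
    """One stimulus run: frames map 1:1 to volumes at TR = step duration."""
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    f = truth.feedback_fraction if feedback_fraction is None else feedback_fraction
    drift_sd = truth.effective_drift_sd if noise_sd == truth.noise_sd else noise_sd
    cache = cache or DistanceCache()
    rng = np.random.default_rng(seed)

    missing = [a for a in dataset.extrastriate_areas if a not in truth.forward_width_mm]
    if missing:
        raise ValueError(f"ground truth lacks kernels for areas {missing}")

    v1 = dataset.patch("V1")
    sizes = prf_base_deg + prf_slope * v1.retinotopy.ecc_deg
    drive_v1 = prf_response_matrix(v1.retinotopy.visual_xy(), sizes, movie)

    drives: dict[str, np.ndarray] = {}
    for area in dataset.extrastriate_areas:
        w_fwd = _coupling_matrix(dataset, "V1", area, truth.forward_width_mm[area], cache)
        drives[area] = drive_v1 @ w_fwd.T

    if f > 0 and dataset.extrastriate_areas:
        fb = np.zeros_like(drive_v1)
        for area in dataset.extrastriate_areas:
            w_bwd = _coupling_matrix(
                dataset, area, "V1", truth.backward_width_mm[area], cache
            )
            fb += drives[area] @ w_bwd.T
        fb /= len(dataset.extrastriate_areas)
        drives["V1"] = (1.0 - f) * drive_v1 + f * fb
    else:
        drives["V1"] = drive_v1

    neural, unit_ids = _assemble(dataset, drives)
    bold = convolve_hrf(neural, movie.frame_duration_s)
    scale = np.sqrt(np.mean(bold**2))
    if scale > 0:
        bold = bold / scale  # global scalar: preserves weighted-sum structure
    bold = _add_noise(bold, noise_sd, drift_sd, rng)
    return TimeSeriesMatrix(
        values=bold,
        unit_ids=unit_ids,
        tr_s=movie.frame_duration_s,
        condition="stimulus",
    )


def _latent_field(
    rng: np.random.Generator,
    n_volumes: int,
    grid_deg: np.ndarray,
    tr_s: float,
    *,
    spatial_smooth_deg: float = 2.0,
    ar_tau_s: float = 10.0,
    f_max_hz: float = 0.1,
) -> np.ndarray:
    """Smooth Gaussian random field over visual space, temporally AR(1)
    and band-limited below ``f_max_hz``. Returns (T, ny, nx)."""
    from scipy.ndimage import gaussian_filter

    ny = nx = len(grid_deg)
    field = rng.normal(size=(n_volumes, ny, nx))
    step = float(grid_deg[1] - grid_deg[0])
    field = gaussian_filter(field, sigma=(0, spatial_smooth_deg / step,
                                          spatial_smooth_deg / step))
    rho = np.exp(-tr_s / ar_tau_s)
    for t in range(1, n_volumes):
        field[t] = rho * field[t - 1] + np.sqrt(1 - rho**2) * field[t]
    spec = np.fft.rfft(field, axis=0)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    spec[freqs >= f_max_hz] = 0.0
    field = np.fft.irfft(spec, n=n_volumes, axis=0)
    sd = field.std()
    return field / sd if sd > 0 else field


def _sample_field(field: np.ndarray, grid_deg: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear sample of (T, ny, nx) at visual positions (n, 2) -> (T, n)."""
    step = grid_deg[1] - grid_deg[0]
    fx = np.clip((xy[:, 0] - grid_deg[0]) / step, 0, len(grid_deg) - 1.001)
    fy = np.clip((xy[:, 1] - grid_deg[0]) / step, 0, len(grid_deg) - 1.001)
    x0 = fx.astype(int); y0 = fy.astype(int)
    ax = fx - x0; ay = fy - y0
    return (
        field[:, y0, x0] * (1 - ax) * (1 - ay)
        + field[:, y0, x0 + 1] * ax * (1 - ay)
        + field[:, y0 + 1, x0] * (1 - ax) * ay
        + field[:, y0 + 1, x0 + 1] * ax * ay
    )


def simulate_rest_run(
    dataset: Dataset,
    truth: GroundTruth,
    *,
    seed: int,
    n_volumes: int = REST_N_VOLUMES,
    tr_s: float = REST_TR_S,
    noise_sd: float | None = None,
    mix_fraction: float | None = None,
    idiosyncratic_sd: float = 0.3,
    grid_n: int = 25,
    cache: DistanceCache | None = None,
) -> TimeSeriesMatrix:
    """One resting run driven by shared low-frequency latents.

    Each unit's base series samples the latent field at its visual
    position plus an idiosyncratic term; extrastriate series mix their
    own base with forward-propagated V1 bases, V1 mixes its base with
    backward-propagated extrastriate bases. The construction is exactly
    direction-symmetric when the kernels and patch geometries are.
    """
    if n_volumes < 16:
        raise ValueError(f"need at least 16 volumes, got {n_volumes}")
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    f = truth.feedback_fraction if mix_fraction is None else mix_fraction
    cache = cache or DistanceCache()
    rng = np.random.default_rng(seed)

    grid_deg = np.linspace(-8.5, 8.5, grid_n)
    field = _latent_field(rng, n_volumes, grid_deg, tr_s)

    base: dict[str, np.ndarray] = {}
    for area in dataset.areas:
        patch = dataset.patch(area)
        b = _sample_field(field, grid_deg, patch.retinotopy.visual_xy())
        if idiosyncratic_sd > 0:
            eta = rng.normal(size=b.shape)
            spec = np.fft.rfft(eta, axis=0)
            freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
            spec[freqs >= 0.1] = 0.0
            eta = np.fft.irfft(spec, n=n_volumes, axis=0)
            sd = eta.std()
            if sd > 0:
                b = b + idiosyncratic_sd * eta / sd
        base[area] = b

    series: dict[str, np.ndarray] = {}
    v1_mix = np.zeros_like(base["V1"])
    for area in dataset.extrastriate_areas:
        w_fwd = _coupling_matrix(dataset, "V1", area, truth.forward_width_mm[area], cache)
        series[area] = (1.0 - f) * base[area] + f * (base["V1"] @ w_fwd.T)
        w_bwd = _coupling_matrix(dataset, area, "V1", truth.backward_width_mm[area], cache)
        v1_mix += base[area] @ w_bwd.T
    if dataset.extrastriate_areas:
        v1_mix /= len(dataset.extrastriate_areas)
    series["V1"] = (1.0 - f) * base["V1"] + f * v1_mix

    values, unit_ids = _assemble(dataset, series)
    sd = np.sqrt(np.mean(values**2))
    if sd > 0:
        values = values / sd
    values = _add_noise(values, noise_sd, truth.effective_drift_sd if noise_sd else 0.0, rng)
    return TimeSeriesMatrix(
        values=values, unit_ids=unit_ids, tr_s=tr_s, condition="rest"
    )
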