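"""Drifting-bar aperture movies and the pRF forward response."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_RADIUS_DEG = 8.0
DEFAULT_N_STEPS = 16
DEFAULT_STEP_DEG = 1.0
DEFAULT_STEP_DUR_S = 1.5
DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class StimulusMovie:
    """Binary bar-aperture frames on a visual-field grid (degrees)."""

    frames: np.ndarray  # (F, ny, nx), values in {0, 1}
    grid_x: np.ndarray  # (nx,) degrees
    grid_y: np.ndarray  # (ny,) degrees
    frame_duration_s: float
    radius_deg: float
    bar_width_deg: float
    orientation_deg: np.ndarray  # (F,)
    direction: np.ndarray  # (F,) 0 | 1
    step: np.ndarray  # (F,)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pixel_area_deg2(self) -> float:
        dx = float(self.grid_x[1] - self.grid_x[0])
        dy = float(self.grid_y[1] - self.grid_y[0])
        return dx * dy


def make_bar_stimulus(
    radius_deg: float = DEFAULT_RADIUS_DEG,
    n_steps: int = DEFAULT_N_STEPS,
    step_deg: float = DEFAULT_STEP_DEG,
    step_dur_s: float = DEFAULT_STEP_DUR_S,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    directions_per_orientation: int = 2,
    grid_n: int = 64,
) -> StimulusMovie:
    """Bar aperture sweeping across a disk-shaped field.

    The bar is ``radius/4`` wide, oriented along each listed orientation,
    and steps perpendicular to its length; the second direction replays
    the sweep reversed. Frame count = orientations x directions x steps.
    """
    if radius_deg <= 0:
        raise ValueError("stimulus radius must be positive")
    if n_steps < 1:
        raise ValueError("need at least one bar step")
    if step_dur_s <= 0:
        raise ValueError("step duration must be positive")
    bar_width = radius_deg / 4.0

    axis = np.linspace(-radius_deg, radius_deg, grid_n)
    xs, ys = np.meshgrid(axis, axis)
    disk = xs**2 + ys**2 <= radius_deg**2

    offsets = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step_deg

    frames, oris, dirs, steps = [], [], [], []
    for ori in orientations:
        # movement axis is perpendicular to the bar's long axis
        phi = np.deg2rad(ori + 90.0)
        u = xs * np.cos(phi) + ys * np.sin(phi)
        for direction in range(directions_per_orientation):
            order = offsets if direction % 2 == 0 else offsets[::-1]
            for k, pos in enumerate(order):
                bar = np.abs(u - pos) <= bar_width / 2.0
                frames.append((bar & disk).astype(np.float64))
                oris.append(ori)
                dirs.append(direction)
                steps.append(k)

    return StimulusMovie(
        frames=np.stack(frames),
        grid_x=axis,
        grid_y=axis,
        frame_duration_s=step_dur_s,
        radius_deg=radius_deg,
        bar_width_deg=bar_width,
        orientation_deg=np.asarray(oris),
        direction=np.asarray(dirs),
        step=np.asarray(steps),
    )


def prf_response(
    prf_center: tuple[float, float],
    prf_size_deg: float,
    movie: StimulusMovie,
) -> np.ndarray:
    """Neural drive per frame: overlap integral of an isotropic 2-D
    Gaussian pRF with the binary aperture."""
    if prf_size_deg <= 0:
        raise ValueError("pRF size must be positive")
    cx, cy = prf_center
    if np.hypot(cx, cy) > 2.0 * movie.radius_deg:
        warnings.warn(
            f"pRF center {prf_center} lies beyond twice the stimulus radius; "
            "drive may be identically zero",
            stacklevel=2,
        )
    xs, ys = np.meshgrid(movie.grid_x, movie.grid_y)
    g = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * prf_size_deg**2))
    return np.tensordot(movie.frames, g, axes=([1, 2], [0, 1])) * movie.pixel_area_deg2


def prf_response_matrix(
    centers_xy: np.ndarray,
    sizes_deg: np.ndarray,
    movie: StimulusMovie,
) -> np.ndarray:
    """Vectorized drive for many pRFs: returns (n_frames, n_units)."""
    sizes = np.asarray(sizes_deg, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("pRF sizes must be positive")
    xs, ys = np.meshgrid(movie.grid_x, movie.grid_y)
    pix = np.column_stack([xs.ravel(), ys.ravel()])  # (P, 2)
    d2 = (
        (pix[:, 0][:, None] - centers_xy[:, 0][None, :]) ** 2
        + (pix[:, 1][:, None] - centers_xy[:, 1][None, :]) ** 2
    )
    g = np.exp(-d2 / (2.0 * sizes[None, :] ** 2))  # (P, n)
    flat = movie.frames.reshape(movie.n_frames, -1)  # (F, P)
    return flat @ g * movie.pixel_area_deg2
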