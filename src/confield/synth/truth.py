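"""Ground-truth inter-area coupling regimes for the simulators.

Forward (V1 -> x) and backward (x -> V1) kernel widths are generated so
that their difference follows a chosen linear trend in hierarchy level:
a rising trend for the control regime, a flat one (plus a V3d offset)
for the patient regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# hierarchy levels (shared with the convergence module)
HIERARCHY_LEVEL: dict[str, float] = {
    "V1": 0.0,
    "V2": 1.0, "V2d": 1.0, "V2v": 1.0,
    "V3": 2.0, "V3d": 2.0, "V3v": 2.0,
    "hV4": 3.0,
    "LO": 3.5,   # mean of LO1 (3) and LO2 (4)
    "TO": 5.5,   # mean of TO1 (5) and TO2 (6)
}

CONTROL_SLOPE_MM_PER_LEVEL = 1.61
PATIENT_SLOPE_MM_PER_LEVEL = -0.035
PATIENT_V3D_OFFSET_MM = 4.45

DEFAULT_BACKWARD_WIDTH_MM = 0.6
DEFAULT_NOISE_SD = 0.3
DEFAULT_FEEDBACK_FRACTION = 0.2
DEFAULT_WIDTH_JITTER_SD = 0.15

EXTRASTRIATE_ATOMIC = ("V2d", "V2v", "V3d", "V3v", "hV4", "LO", "TO")
SIGMA_MAX_MM = 10.0
WIDTH_FLOOR_MM = 0.2


@dataclass(frozen=True)
class GroundTruth:
    """Per-area kernel widths plus regime, noise and seed bookkeeping."""

    group: str  # 'control' | 'patient'
    forward_width_mm: dict[str, float]
    backward_width_mm: dict[str, float]
    slope_mm_per_level: float
    area_offsets_mm: dict[str, float]
    feedback_fraction: float = DEFAULT_FEEDBACK_FRACTION
    noise_sd: float = DEFAULT_NOISE_SD
    drift_sd: float | None = None  # defaults to noise_sd
    seed: int = 0

    def __post_init__(self):
        for name, widths in (("forward", self.forward_width_mm),
                             ("backward", self.backward_width_mm)):
            bad = {a: w for a, w in widths.items() if w <= 0}
            if bad:
                raise ValueError(f"{name} kernel widths must be > 0: {bad}")

    @property
    def effective_drift_sd(self) -> float:
        return self.noise_sd if self.drift_sd is None else self.drift_sd

    def width_difference(self, area: str) -> float:
        return self.forward_width_mm[area] - self.backward_width_mm[area]


def nominal_level_differences(slope_mm_per_level: float,
                              offsets_mm: dict[str, float] | None = None,
                              areas: tuple[str, ...] = ("V2", "V3", "hV4", "LO", "TO"),
                              ) -> dict[str, float]:
    """slope x hierarchy-level (+ per-area offset) for each listed area."""
    offsets_mm = offsets_mm or {}
    return {
        a: slope_mm_per_level * HIERARCHY_LEVEL[a] + offsets_mm.get(a, 0.0)
        for a in areas
    }


def make_group_truth(
    group: str,
    seed: int,
    *,
    slope_mm_per_level: float | None = None,
    area_offsets_mm: dict[str, float] | None = None,
    base_backward_mm: float = DEFAULT_BACKWARD_WIDTH_MM,
    width_jitter_sd: float = DEFAULT_WIDTH_JITTER_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    feedback_fraction: float = DEFAULT_FEEDBACK_FRACTION,
    areas: tuple[str, ...] = EXTRASTRIATE_ATOMIC,
) -> GroundTruth:
    """One subject's ground truth for the requested group regime.

    Control default: forward - backward width grows 1.61 mm per level.
    Patient default: flat (slope -0.035 mm/level) with a +4.45 mm offset
    on V1<->V3d. Widths are clipped to the searchable range; a seeded
    per-area jitter models between-subject variability.
    """
    if group == "control":
        slope = CONTROL_SLOPE_MM_PER_LEVEL if slope_mm_per_level is None else slope_mm_per_level
        offsets = {} if area_offsets_mm is None else dict(area_offsets_mm)
    elif group == "patient":
        slope = PATIENT_SLOPE_MM_PER_LEVEL if slope_mm_per_level is None else slope_mm_per_level
        offsets = (
            {"V3d": PATIENT_V3D_OFFSET_MM}
            if area_offsets_mm is None
            else dict(area_offsets_mm)
        )
    else:
        raise ValueError(f"unknown group label {group!r} (want control|patient)")

    rng = np.random.default_rng(seed)
    forward: dict[str, float] = {}
    backward: dict[str, float] = {}
    for area in areas:
        diff = slope * HIERARCHY_LEVEL[area] + offsets.get(area, 0.0)
        diff += rng.normal(0.0, width_jitter_sd)
        backward[area] = base_backward_mm
        forward[area] = float(
            np.clip(base_backward_mm + diff, WIDTH_FLOOR_MM, SIGMA_MAX_MM)
        )
    return GroundTruth(
        group=group,
        forward_width_mm=forward,
        backward_width_mm=backward,
        slope_mm_per_level=slope,
        area_offsets_mm=offsets,
        feedback_fraction=feedback_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
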