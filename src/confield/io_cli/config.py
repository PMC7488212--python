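"""Run configuration with defaults frozen to the reference analysis constants."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from ..cf_model import VE_THRESHOLD
from ..convergence import ECC_WINDOW_DEG, STREAMS


@dataclass
class RunConfig:
    """Pipeline configuration.

    Defaults reproduce the analysis constants: VE threshold 0.20,
    eccentricity window [0.5, 7.5] deg, sigma grid 0.0001 then
    0.2..10 mm, stimulus TR 1.5 s / rest TR 2 s, rest band 0.01-0.1 Hz,
    Bonferroni factor 3 for the stream comparisons and 9 for the
    per-area comparisons.
    """

    # data locations (files mode); unused in synthetic mode
    data_dir: str | None = None
    timeseries: str | None = None

    condition: str = "stimulus"
    tr_s: float | None = None  # validated against the sidecar when set
    band_hz: tuple[float, float] = (0.01, 0.1)
    ve_threshold: float = VE_THRESHOLD
    ecc_window_deg: tuple[float, float] = ECC_WINDOW_DEG
    sigma_grid_max_mm: float = 10.0
    sigma_grid_step_mm: float = 0.2
    streams: tuple[str, ...] = ("both", "dorsal", "ventral")
    areas: tuple[str, ...] = ("V2", "V2v", "V2d", "V3", "V3v", "V3d", "hV4", "LO", "TO")
    bonferroni_streams: int = 3
    bonferroni_areas: int = 9
    seed: int = 0

    # synthetic-cohort knobs
    n_controls: int = 8
    n_patients: int = 6
    noise_sd: float = 0.3

    def __post_init__(self):
        for s in self.streams:
            if s not in STREAMS:
                raise ValueError(f"unknown stream {s!r}")
        if self.bonferroni_streams < 1 or self.bonferroni_areas < 1:
            raise ValueError("correction factors must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("band_hz", "ecc_window_deg", "streams", "areas"):
            if k in raw and isinstance(raw[k], list):
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
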