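"""Run configuration: a single YAML document with strict key checking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    Either ``simulate=True`` (generate a synthetic dose-condition dataset,
    the default) or ``data_dir`` pointing at a dataset directory written by
    :func:`famotion.pipeline.save_dataset`.  Unknown YAML keys are rejected;
    physical quantities must be positive.
    """

    # data source
    simulate: bool = True
    data_dir: str | None = None
    out_dir: str | None = None

    # acquisition geometry / timing (used when sidecars are absent)
    pixel_size: float = 0.16  # um/px
    fa_frame_interval: float = 10.0  # s
    track_dt_min: float = 2.0  # min

    # synthetic-dataset size
    n_cells_per_dose: int = 20
    n_fa_movies_per_dose: int = 2
    n_edge_movies_per_dose: int = 2
    fa_n_frames: int = 120
    fa_frame_shape: tuple = (192, 192)
    edge_n_frames: int = 40
    track_duration_min: float = 480.0
    null_conditions: bool = False  # identical generator params at all doses

    # analysis parameters
    min_fa_area_um2: float = 0.05
    max_fa_area_um2: float = 10.0
    max_link_disp_um: float = 1.0
    gap_frames: int = 1
    n_sectors: int = 100
    max_fit_lag_min: float = 30.0
    scheme: str = "both"  # 'egf', 'speed' or 'both'
    speed_cutoff: float | None = None  # um/hr; None -> derive by 2-means
    alpha: float = 0.01
    equal_var_ttest: bool = False
    bleach_tolerance: float = 0.10

    seed: int = 0

    _POSITIVE = (
        "pixel_size", "fa_frame_interval", "track_dt_min", "min_fa_area_um2",
        "max_fa_area_um2", "max_link_disp_um", "track_duration_min",
        "max_fit_lag_min", "alpha", "bleach_tolerance",
    )

    def __post_init__(self):
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_fa_area_um2 >= self.max_fa_area_um2:
            raise ValueError("min_fa_area_um2 must be < max_fa_area_um2")
        if self.scheme not in ("egf", "speed", "both"):
            raise ValueError("scheme must be 'egf', 'speed' or 'both'")
        if self.n_sectors < 8:
            raise ValueError("n_sectors must be >= 8")
        if self.speed_cutoff is not None and self.speed_cutoff <= 0:
            raise ValueError("speed_cutoff must be positive when given")
        if not self.simulate and not self.data_dir:
            raise ValueError("data_dir is required when simulate is false")
        if isinstance(self.fa_frame_shape, list):
            self.fa_frame_shape = tuple(self.fa_frame_shape)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config YAML must be a mapping")
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fa_frame_shape"] = list(self.fa_frame_shape)
        return d
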