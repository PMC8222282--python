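"""Run configuration: every analysis constant as a serializable default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, serializable to YAML.

    Zone thresholds (nm): MV-tip radius 150, junction band 75, CB dilation
    300, MV length window 50-1500, tip merge distance 50; distance-profile
    bin 12.5 nm. STORM thresholds mirror the localization quality filters.
    """

    pixel_size_nm: float = 12.5
    tip_radius_nm: float = 150.0
    junction_nm: float = 75.0
    cb_dilation_nm: float = 300.0
    mv_min_nm: float = 50.0
    mv_max_nm: float = 1500.0
    tip_merge_nm: float = 50.0
    bin_nm: float = 12.5
    min_component_px: int = 2000
    storm_thresholds: dict = field(
        default_factory=lambda: {
            "precision_nm": [0.0, 14.0],
            "z_nm": [-400.0, 400.0],
            "photons_max": 20000.0,
            "background_max": 100.0,
            "sigma_px": [0.0, 2.5],
            "sigma_ratio": [0.6, 1.5],
        }
    )
    storm_dr_nm: float = 10.0
    storm_rmax_nm: float = 300.0
    frame_interval_s: float = 11.0
    seed: int = 0
    io: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm", "tip_radius_nm", "junction_nm", "cb_dilation_nm",
            "mv_min_nm", "mv_max_nm", "tip_merge_nm", "bin_nm",
            "storm_dr_nm", "storm_rmax_nm", "frame_interval_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mv_min_nm > self.mv_max_nm:
            raise ValueError("mv_min_nm must not exceed mv_max_nm")

    def to_dict(self) -> dict:
        return asdict(self)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
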