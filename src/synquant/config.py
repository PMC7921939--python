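"""Pipeline configuration: acquisition geometry and analysis thresholds.

All physical quantities are in micrometres (µm) and seconds.  Axis order is
(t, z, y, x) with 0-based voxel indices; CSV times are seconds relative to
tight cell coupling (t0), negative before coupling.

The classifier thresholds collected here hold the study's constants: the
35% interface-enrichment rule, the relative-radius-0.5 central disc, the
1.5 µm invagination depth, the 10% enrichment-region fraction, the
relative radius/depth 0.5 central core and the 1.3 µm neck rule.  The
pattern-geometry coverage fractions are re-derived defaults, each exposed
as a named parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class AcquisitionSpec:
    """Spinning-disk acquisition geometry.

    Defaults follow the study protocol: 21 z-sections at 1 µm intervals
    every 20 s.  The lateral pixel size is not part of the protocol; the
    0.25 µm default resolves the 1.3 µm neck criterion with >= 5 pixels.
    """

    n_z: int = 21
    z_step: float = 1.0
    xy_pixel: float = 0.25
    frame_interval: float = 20.0
    n_frames: int = 12
    n_xy: int = 64
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.n_z < 3:
            raise ValueError("n_z must be >= 3")
        if self.z_step <= 0 or self.xy_pixel <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing (z, y, x) in µm."""
        return (self.z_step, self.xy_pixel, self.xy_pixel)

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return (self.n_z, self.n_xy, self.n_xy)

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval


@dataclass
class TrackingParams:
    """Tight-coupling detection and segmentation parameters.

    ``full_width_fraction``/``full_width_window_s`` operationalize the
    "interface has reached its full width" judgement: the first frame whose
    diameter is at least the fraction of the running maximum over the
    subsequent window.  ``contact_rule_s`` is the 40 s fallback; t0 is
    whichever comes first.
    """

    full_width_fraction: float = 0.9
    full_width_window_s: float = 120.0
    contact_rule_s: float = 40.0
    min_component_voxels: int = 50
    tcell_threshold: float | None = None  # None -> Otsu
    apc_threshold: float | None = None


@dataclass
class ClassifierParams:
    """Thresholds for the six-pattern interface classifier.

    ``enrichment_threshold`` is the 35% rule: interface enrichment below it
    is classified as no accumulation; the same multiplicative cutoff
    (1.35 x background) defines the enriched voxel set used by the
    geometric rules.
    """

    enrichment_threshold: float = 0.35
    central_rel_radius: float = 0.5
    invagination_depth_um: float = 1.5
    invagination_seed_radius_um: float = 1.0
    invagination_seed_depth_um: float = 1.25
    background_exclusion_radius_um: float = 1.8
    background_exclusion_depth_um: float = 3.0
    peripheral_mass_fraction: float = 0.75
    peripheral_min_angle_deg: float = 180.0
    peripheral_central_coverage_max: float = 0.5
    asymmetric_max_angle_deg: float = 180.0
    lamella_area_fraction: float = 0.5
    lamella_depth_min_um: float = 0.5
    lamella_depth_max_um: float = 2.5
    diffuse_coverage: float = 0.75
    min_component_voxels: int = 4
    depth_min_voxels: int = 6
    angular_bins: int = 24

    def __post_init__(self) -> None:
        if not 0 <= self.enrichment_threshold:
            raise ValueError("enrichment_threshold must be >= 0")
        if not 0 < self.central_rel_radius <= 1:
            raise ValueError("central_rel_radius must be in (0, 1]")
        if self.invagination_depth_um <= 0:
            raise ValueError("invagination_depth_um must be positive")
        if not 0 < self.lamella_depth_min_um < self.lamella_depth_max_um:
            raise ValueError("lamella depth window must be increasing")


@dataclass
class ShapeParams:
    """Half-spheroid standardization grid and enrichment regions.

    The template grid is (depth, y, x); the central core is a cylinder of
    relative radius and relative depth 0.5 anchored at the interface
    center; the interface enrichment region is the top
    ``region_fraction`` of voxels of the cohort-average map.
    """

    grid: tuple[int, int, int] = (32, 64, 64)
    region_fraction: float = 0.10
    core_rel_radius: float = 0.5
    core_rel_depth: float = 0.5
    iso_spacing_um: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.region_fraction < 1:
            raise ValueError("region_fraction must be in (0, 1)")
        if not 0 < self.core_rel_radius <= 1:
            raise ValueError("core_rel_radius must be in (0, 1]")
        if not 0 < self.core_rel_depth <= 1:
            raise ValueError("core_rel_depth must be in (0, 1]")


@dataclass
class MorphParams:
    """Morphometry parameters; ``neck_min_um`` is the >1.3 µm neck rule."""

    neck_min_um: float = 1.3
    opening_radius_um: float = 1.0
    profile_step_um: float = 0.25
    midline_smooth_um: float = 1.0

    def __post_init__(self) -> None:
        if self.neck_min_um <= 0:
            raise ValueError("neck_min_um must be positive")


@dataclass
class StatsParams:
    """Cohort aggregation: alignment grid and dispersion/test choices."""

    grid_start_s: float = -40.0
    grid_stop_s: float = 420.0
    grid_step_s: float = 20.0
    continuity: float = 0.5
    dispersion: str = "binomial"  # or "experiment"

    def __post_init__(self) -> None:
        if self.grid_step_s <= 0:
            raise ValueError("grid_step_s must be positive")
        if self.dispersion not in ("binomial", "experiment"):
            raise ValueError("dispersion must be 'binomial' or 'experiment'")

    def grid(self) -> np.ndarray:
        """Aligned timepoints (s relative to t0)."""
        return np.arange(
            self.grid_start_s, self.grid_stop_s + 0.5 * self.grid_step_s,
            self.grid_step_s,
        )


@dataclass
class PipelineConfig:
    """Full end-to-end configuration (serializable to/from YAML)."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    shape: ShapeParams = field(default_factory=ShapeParams)
    morph: MorphParams = field(default_factory=MorphParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    conditions: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (
            ("acquisition", AcquisitionSpec),
            ("tracking", TrackingParams),
            ("classifier", ClassifierParams),
            ("shape", ShapeParams),
            ("morph", MorphParams),
            ("stats", StatsParams),
        ):
            if name in d:
                v = d.pop(name)
                if name == "acquisition" or name == "shape":
                    # tuples serialize to lists
                    v = {
                        k: tuple(x) if isinstance(x, list) else x
                        for k, x in v.items()
                    }
                kwargs[name] = sub(**v)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable short hash of the configuration, stamped on outputs."""
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
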