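"""Run configuration: a validated, JSON-serializable description of a
complete pipeline run (scan patterns, phantom, cohort, processing
parameters, ROI, statistics and output paths).

Every run writes its fully resolved configuration and root seed next to
its outputs so results are reproducible from the artifacts alone.  The
JSON schema is available from ``RunConfig.model_json_schema()``.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .cohort import CohortSpec, GroupSpec, OutcomeModel
from .containers import ScanPattern
from .enface import LayerConfig
from .metrics import TIME_POINTS, CircularROI
from .phantom import Disk, PhantomSpec, SpeckleModel, VesselLayer
from .surface import SurfaceParams

__all__ = ["RunConfig"]


class PatternConfig(BaseModel):
    n_ascans_per_bscan: int
    n_positions: int
    repeats: int = 3
    interscan_time_ms: float
    fov_mm: tuple[float, float] = (2.0, 2.0)
    name: str = ""

    def build(self) -> ScanPattern:
        return ScanPattern(**self.model_dump())


class SpeckleConfig(BaseModel):
    resolution_radius_um: float = 4.0
    noise_floor_sigma: float = 0.05
    correlation_law: str = "gaussian"

    def build(self) -> SpeckleModel:
        return SpeckleModel(**self.model_dump())


class DiskConfig(BaseModel):
    center: tuple[float, float]
    radius_px: float

    def build(self) -> Disk:
        return Disk(center=tuple(self.center), radius_px=self.radius_px)


class VesselLayerConfig(BaseModel):
    name: str
    depth_range_um: tuple[float, float]
    disks: list[DiskConfig]
    flow_speed_um_ms: float

    def build(self) -> VesselLayer:
        return VesselLayer(
            name=self.name,
            depth_range_um=tuple(self.depth_range_um),
            disks=tuple(d.build() for d in self.disks),
            flow_speed_um_ms=self.flow_speed_um_ms,
        )


class SurfaceProfileConfig(BaseModel):
    type: Literal["flat", "plane", "dome"] = "flat"
    z0: float
    gx: float = 0.0
    gy: float = 0.0
    amplitude: float = 0.0
    sigma_frac: float = 0.5

    def as_dict(self, nx: int, ny: int) -> dict:
        d = self.model_dump()
        d["nx"], d["ny"] = nx, ny
        return d


class PhantomConfig(BaseModel):
    grid: tuple[int, int, int]  # (n_z, n_x, n_y)
    axial_pitch_um: float = Field(gt=0)
    surface: SurfaceProfileConfig
    vessel_layers: list[VesselLayerConfig]
    static_tissue_amplitude: float = 1.0
    speckle: SpeckleConfig = SpeckleConfig()
    seed: int = 0

    def build(self) -> PhantomSpec:
        n_z, n_x, n_y = self.grid
        return PhantomSpec(
            grid=tuple(self.grid),
            axial_pitch_um=self.axial_pitch_um,
            surface_profile=self.surface.as_dict(n_x, n_y),
            vessel_layers=tuple(v.build() for v in self.vessel_layers),
            static_tissue_amplitude=self.static_tissue_amplitude,
            speckle=self.speckle.build(),
            seed=self.seed,
        )


class OutcomeModelConfig(BaseModel):
    intercept: float = 0.0
    slope: float = 1.0
    noise_sd: float = 0.0
    layer: str = "superficial"

    def build(self) -> OutcomeModel:
        return OutcomeModel(**self.model_dump())


class GroupConfig(BaseModel):
    name: str
    n_subjects: int = Field(ge=1)
    schedule: dict[str, float | dict[str, float]]

    def build(self) -> GroupSpec:
        return GroupSpec(
            name=self.name, n_subjects=self.n_subjects, schedule=dict(self.schedule)
        )


class CohortConfig(BaseModel):
    groups: list[GroupConfig]
    time_points: list[str] = list(TIME_POINTS)
    between_subject_cv: float = Field(ge=0, default=0.15)
    outcome_model: OutcomeModelConfig = OutcomeModelConfig()
    seed: int = 0

    def build(self) -> CohortSpec:
        return CohortSpec(
            groups=tuple(g.build() for g in self.groups),
            time_points=tuple(self.time_points),
            between_subject_cv=self.between_subject_cv,
            outcome_model=self.outcome_model.build(),
            seed=self.seed,
        )


class LayerSpecConfig(BaseModel):
    name: str
    depth_range_um: tuple[float, float]
    contributing_patterns: list[str]

    def build(self) -> LayerConfig:
        return LayerConfig(
            name=self.name,
            depth_range_um=tuple(self.depth_range_um),
            contributing_patterns=tuple(self.contributing_patterns),
        )


class ProcessingConfig(BaseModel):
    mask_threshold: float | Literal["auto"] = "auto"
    mask_k: float = 3.0
    noise_rows: int = 8
    surface_threshold_k: float = 4.0
    surface_axial_median: int = 3
    surface_median: int = 3
    fusion_grid: Optional[tuple[int, int]] = None

    def surface_params(self) -> SurfaceParams:
        return SurfaceParams(
            threshold_k=self.surface_threshold_k,
            noise_rows=self.noise_rows,
            axial_median=self.surface_axial_median,
            surface_median=self.surface_median,
        )


class ROIConfig(BaseModel):
    center: Optional[tuple[float, float]] = None
    radius_px: Optional[float] = None
    radius_frac: Optional[float] = 0.4

    @model_validator(mode="after")
    def _one_radius(self):
        if (self.radius_px is None) == (self.radius_frac is None):
            raise ValueError("set exactly one of radius_px / radius_frac")
        return self

    def build(self) -> CircularROI:
        return CircularROI(
            center=tuple(self.center) if self.center else None,
            radius_px=self.radius_px,
            radius_frac=self.radius_frac,
        )


class StatsConfig(BaseModel):
    alpha: float = Field(gt=0, lt=1, default=0.05)
    correction: Optional[Literal["holm"]] = None
    baseline_label: str = "baseline"


class RunConfig(BaseModel):
    """Complete description of one pipeline run."""

    patterns: list[PatternConfig]
    phantom: PhantomConfig
    cohort: Optional[CohortConfig] = None
    layers: list[LayerSpecConfig] = [
        LayerSpecConfig(
            name="superficial",
            depth_range_um=(50.0, 70.0),
            contributing_patterns=["256", "512", "1024"],
        ),
        LayerSpecConfig(
            name="deep",
            depth_range_um=(320.0, 340.0),
            contributing_patterns=["256", "512"],
        ),
    ]
    processing: ProcessingConfig = ProcessingConfig()
    roi: ROIConfig = ROIConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0
    output_dir: str = "octaflow_out"

    @model_validator(mode="after")
    def _patterns_cover_layers(self):
        names = {p.name or str(p.n_ascans_per_bscan) for p in self.patterns}
        for layer in self.layers:
            missing = set(layer.contributing_patterns) - names
            if missing:
                raise ValueError(
                    f"layer {layer.name!r} requires patterns {sorted(missing)} "
                    "not present in the pattern list"
                )
        return self
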