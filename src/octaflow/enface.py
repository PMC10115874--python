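"""Surface-referenced en-face maximum projection of OCTA volumes.

A depth layer is a slab at a fixed physical depth range below the
segmented tissue surface.  The defaults follow the renal-cortex
protocol: a superficial capillary layer 50-70 um below the surface
(fused from all three scan patterns) and a deep layer 320-340 um below
(fused from the 256 and 512 patterns only, the 1024 pattern's long
interscan time being saturated at those flow speeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .containers import OCTAVolume, ScanPattern
from .exceptions import GeometryError
from .surface import SurfaceMap

__all__ = [
    "LayerConfig",
    "EnFaceMap",
    "enface_max_projection",
    "default_layers",
    "SUPERFICIAL",
    "DEEP",
]


@dataclass(frozen=True)
class LayerConfig:
    """A named depth slab and the scan patterns that contribute to it."""

    name: str
    depth_range_um: tuple[float, float]
    contributing_patterns: tuple[str, ...]

    def __post_init__(self):
        d1, d2 = self.depth_range_um
        if not d1 < d2:
            raise ValueError(f"depth range must satisfy d1 < d2, got {d1}, {d2}")
        object.__setattr__(
            self, "contributing_patterns", tuple(self.contributing_patterns)
        )


SUPERFICIAL = LayerConfig("superficial", (50.0, 70.0), ("256", "512", "1024"))
DEEP = LayerConfig("deep", (320.0, 340.0), ("256", "512"))


def default_layers() -> list[LayerConfig]:
    """Superficial (50-70 um, all patterns) and deep (320-340 um, 256+512)."""
    return [SUPERFICIAL, DEEP]


@dataclass
class EnFaceMap:
    """2-D projection ``values[y, x]`` (batch axes allowed) of one layer."""

    values: np.ndarray
    layer: str
    pattern: ScanPattern | None = None
    lateral_pitch_um: float = 0.0
    position_pitch_um: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]


def enface_max_projection(
    octa: OCTAVolume, surface: SurfaceMap, layer: LayerConfig
) -> EnFaceMap:
    """Maximum decorrelation over a depth slab below the surface.

    The physical depth range ``(d1, d2)`` um converts to voxel offsets
    ``o1 = round(d1 / pitch)``, ``o2 = round(d2 / pitch)`` and the slab
    at each A-line is ``z in [surface + o1, surface + o2]`` (inclusive,
    clipped to the volume).  A-lines whose clipped slab is empty yield
    0.  Raises :class:`GeometryError` if the slab misses the volume for
    every A-line.
    """
    pitch = octa.axial_pitch_um
    if pitch <= 0:
        raise ValueError("axial_pitch_um must be positive")
    d1, d2 = layer.depth_range_um
    o1 = round(d1 / pitch)
    o2 = round(d2 / pitch)
    if o1 > o2:
        raise ValueError("depth range converts to an empty voxel slab")

    d = np.asarray(octa.decorrelation)  # [..., y, z, x]
    n_z = d.shape[-2]
    surf = np.asarray(surface.surface_index)  # [..., y, x]
    if surf.shape != d.shape[:-2] + (d.shape[-1],):
        raise ValueError(
            f"surface shape {surf.shape} inconsistent with volume {d.shape}"
        )

    offsets = np.arange(o1, o2 + 1)  # [S]
    zidx = surf[..., None] + offsets  # [..., y, x, S]
    valid = (zidx >= 0) & (zidx < n_z)
    if not valid.any():
        raise GeometryError(
            f"depth range {layer.depth_range_um} um lies outside the volume "
            "for every A-line"
        )
    dyx = np.moveaxis(d, -2, -1)  # [..., y, x, z]
    gathered = np.take_along_axis(dyx, np.clip(zidx, 0, n_z - 1), axis=-1)
    gathered = np.where(valid, gathered, -np.inf)
    values = gathered.max(axis=-1)
    values = np.where(np.isfinite(values), values, 0.0)

    return EnFaceMap(
        values=values,
        layer=layer.name,
        pattern=octa.pattern,
        lateral_pitch_um=octa.pattern.lateral_pitch_um if octa.pattern else 0.0,
        position_pitch_um=octa.pattern.position_pitch_um if octa.pattern else 0.0,
        meta={
            "depth_range_um": layer.depth_range_um,
            "voxel_offsets": (int(o1), int(o2)),
            "subject": octa.subject,
            "time_point": octa.time_point,
        },
    )
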