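"""Core data containers: scan patterns and raw / decorrelation volumes.

Axis convention used throughout the package
-------------------------------------------
Raw repeated-B-scan amplitude data are indexed ``[position, repeat, z, x]``
(slow raster axis, repeat index, depth, fast raster axis).  Decorrelation
volumes drop the repeat axis: ``[position, z, x]``.  En-face maps are
``[y, x]`` where ``y`` is the B-scan position axis.  All array-processing
functions accept arbitrary *leading* batch dimensions in front of these
core axes, which the cohort simulator exploits to process many subjects
and time points in single vectorized calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .exceptions import PatternError

__all__ = [
    "ScanPattern",
    "OCTVolume",
    "OCTAVolume",
    "DEFAULT_PATTERNS",
    "default_patterns",
]


@dataclass(frozen=True)
class ScanPattern:
    """Geometry and timing of one repeated raster acquisition.

    Parameters
    ----------
    n_ascans_per_bscan : int
        Number of A-scans in each B-scan (fast, ``x`` axis).
    n_positions : int
        Number of B-scan positions (slow, ``y`` axis).
    repeats : int
        Number of repeated B-scans per position, ``M >= 2``.
    interscan_time_ms : float
        Time between repeated B-scans at the same position (tau).  Longer
        interscan times render slower flows detectable while faster flows
        saturate.
    fov_mm : tuple of float
        Field of view ``(x, y)`` in millimetres, shared by all patterns of
        one protocol.
    name : str
        Identifier used by fusion rules (conventionally the A-scan count,
        e.g. ``"256"``).
    """

    n_ascans_per_bscan: int
    n_positions: int
    repeats: int
    interscan_time_ms: float
    fov_mm: tuple[float, float] = (2.0, 2.0)
    name: str = ""

    def __post_init__(self) -> None:
        if self.repeats < 2:
            raise PatternError(
                f"repeats must be >= 2, got {self.repeats}"
            )
        if self.n_ascans_per_bscan < 1 or self.n_positions < 1:
            raise PatternError("pattern dimensions must be positive")
        if self.interscan_time_ms <= 0:
            raise PatternError("interscan time must be positive")
        if not self.name:
            object.__setattr__(self, "name", str(self.n_ascans_per_bscan))

    @property
    def lateral_pitch_um(self) -> float:
        """Spacing of A-scans along ``x`` in micrometres."""
        return self.fov_mm[0] * 1000.0 / self.n_ascans_per_bscan

    @property
    def position_pitch_um(self) -> float:
        """Spacing of B-scan positions along ``y`` in micrometres."""
        return self.fov_mm[1] * 1000.0 / self.n_positions

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_ascans_per_bscan": self.n_ascans_per_bscan,
            "n_positions": self.n_positions,
            "repeats": self.repeats,
            "interscan_time_ms": self.interscan_time_ms,
            "fov_mm": list(self.fov_mm),
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScanPattern":
        d = dict(d)
        d["fov_mm"] = tuple(d.get("fov_mm", (2.0, 2.0)))
        return cls(**d)


def default_patterns(fov_mm: tuple[float, float] = (2.0, 2.0)) -> list[ScanPattern]:
    """The three standard raster patterns of the imaging protocol.

    256 x 256 A-scans at 1.5 ms interscan time, 512 x 512 at 3.0 ms and
    1024 x 1024 at 5.8 ms, all over a shared field of view and each
    repeated three times per B-scan position.
    """
    return [
        ScanPattern(256, 256, 3, 1.5, fov_mm, "256"),
        ScanPattern(512, 512, 3, 3.0, fov_mm, "512"),
        ScanPattern(1024, 1024, 3, 5.8, fov_mm, "1024"),
    ]


DEFAULT_PATTERNS = default_patterns()


@dataclass
class OCTVolume:
    """Repeated-B-scan amplitude data with physical metadata.

    ``amplitude`` has core axes ``[position, repeat, z, x]`` (arbitrary
    leading batch axes are allowed).
    """

    amplitude: np.ndarray
    pattern: ScanPattern
    axial_pitch_um: float
    subject: str = ""
    time_point: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude)
        if a.ndim < 4:
            raise ValueError(
                "amplitude must have at least 4 axes [position, repeat, z, x]"
            )
        p = self.pattern
        if (
            a.shape[-4] != p.n_positions
            or a.shape[-3] != p.repeats
            or a.shape[-1] != p.n_ascans_per_bscan
        ):
            raise ValueError(
                f"amplitude shape {a.shape} inconsistent with pattern "
                f"({p.n_positions} positions, {p.repeats} repeats, "
                f"{p.n_ascans_per_bscan} A-scans)"
            )
        if self.axial_pitch_um <= 0:
            raise ValueError("axial_pitch_um must be positive")
        self.amplitude = a

    @property
    def n_z(self) -> int:
        return self.amplitude.shape[-2]

    @property
    def lateral_pitch_um(self) -> float:
        return self.pattern.lateral_pitch_um


@dataclass
class OCTAVolume:
    """Per-voxel amplitude decorrelation plus the structural image.

    ``decorrelation`` and ``structural`` share core axes
    ``[position, z, x]``; decorrelation values lie in [0, 1].
    """

    decorrelation: np.ndarray
    structural: np.ndarray
    pattern: ScanPattern
    axial_pitch_um: float
    subject: str = ""
    time_point: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.decorrelation)
        s = np.asarray(self.structural)
        if d.shape != s.shape:
            raise ValueError("decorrelation and structural shapes differ")
        if d.ndim < 3:
            raise ValueError("expected core axes [position, z, x]")
        self.decorrelation = d
        self.structural = s

    @classmethod
    def like(cls, vol: OCTVolume, decorrelation: np.ndarray,
             structural: np.ndarray) -> "OCTAVolume":
        return cls(
            decorrelation=decorrelation,
            structural=structural,
            pattern=vol.pattern,
            axial_pitch_um=vol.axial_pitch_um,
            subject=vol.subject,
            time_point=vol.time_point,
            meta=dict(vol.meta),
        )


def _replace(obj, **kw):
    return replace(obj, **kw)
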