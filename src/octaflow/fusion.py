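"""Fusion of en-face maps acquired at different interscan times.

Each scan pattern covers the same field of view at a different lateral
sampling and interscan time.  The per-pattern maximum projections are
resampled to a common grid and summed pixelwise into the final
semiquantitative image: a short interscan time resolves fast flow
without saturating while a long one is sensitive to slow flow, so their
sum grades flow speed over a wider range than any single pattern.  The
superficial layer sums all three patterns; the deep layer sums only the
256 and 512 patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import ndimage

from .enface import EnFaceMap, LayerConfig
from .exceptions import MissingPatternError

__all__ = [
    "SemiQuantImage",
    "resample_to_common_grid",
    "fuse_semiquant",
    "pseudocolor",
]


@dataclass
class SemiQuantImage:
    """Fused semiquantitative OCTA image on the common grid."""

    values: np.ndarray  # [..., y, x], nonnegative
    layer: str
    contributing_patterns: tuple[str, ...]
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]


def _resample_values(values: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of ``[..., y, x]`` arrays onto a new grid.

    Pixel centers at the field-of-view corners stay aligned: output
    pixel ``i`` of ``n_out`` samples source coordinate
    ``i * (n_src - 1) / (n_out - 1)``.  Constants are preserved exactly.
    """
    ny_t, nx_t = target_size
    if ny_t < 2 or nx_t < 2:
        raise ValueError("target grid must be at least 2 x 2")
    ny_s, nx_s = values.shape[-2:]
    if (ny_s, nx_s) == (ny_t, nx_t):
        return values.copy()
    ys = np.linspace(0.0, ny_s - 1.0, ny_t)
    xs = np.linspace(0.0, nx_s - 1.0, nx_t)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    coords = np.stack([yy, xx])

    def one(img):
        return ndimage.map_coordinates(img, coords, order=1, mode="nearest")

    if values.ndim == 2:
        out = one(values)
    else:
        flat = values.reshape((-1,) + values.shape[-2:])
        out = np.stack([one(f) for f in flat]).reshape(
            values.shape[:-2] + (ny_t, nx_t)
        )
    return np.clip(out, 0.0, None)


def resample_to_common_grid(emap: EnFaceMap, target_size: tuple[int, int]) -> EnFaceMap:
    """Resample an en-face map onto the common fusion grid (bilinear)."""
    out = _resample_values(np.asarray(emap.values, dtype=np.float64), target_size)
    return EnFaceMap(
        values=out,
        layer=emap.layer,
        pattern=emap.pattern,
        lateral_pitch_um=emap.lateral_pitch_um * (emap.values.shape[-1] / target_size[1]),
        position_pitch_um=emap.position_pitch_um
        * (emap.values.shape[-2] / target_size[0]),
        meta={**emap.meta, "resampled_from": emap.grid_shape},
    )


def fuse_semiquant(
    maps: Mapping[str, EnFaceMap],
    layer: LayerConfig,
    target_size: tuple[int, int] | None = None,
) -> SemiQuantImage:
    """Sum the layer's contributing en-face maps on a common grid.

    ``maps`` is keyed by pattern name.  Every pattern named in
    ``layer.contributing_patterns`` must be present (a missing one
    raises :class:`MissingPatternError` naming it); maps of patterns
    outside that set are ignored.  The common grid defaults to the
    finest contributing map's grid.
    """
    missing = [p for p in layer.contributing_patterns if p not in maps]
    if missing:
        raise MissingPatternError(missing, layer=layer.name)
    contributing = [maps[p] for p in layer.contributing_patterns]
    if target_size is None:
        target_size = max(
            (m.grid_shape for m in contributing), key=lambda s: s[0] * s[1]
        )
    resampled = [resample_to_common_grid(m, target_size) for m in contributing]
    total = resampled[0].values
    for m in resampled[1:]:
        total = total + m.values
    return SemiQuantImage(
        values=total,
        layer=layer.name,
        contributing_patterns=tuple(layer.contributing_patterns),
        provenance={
            "target_size": tuple(target_size),
            "resampling": "bilinear, corner-aligned pixel centers",
            "sources": {
                m.pattern.name if m.pattern else str(i): m.meta
                for i, m in enumerate(contributing)
            },
        },
    )


def pseudocolor(
    image: SemiQuantImage | np.ndarray,
    colormap: str = "inferno",
    display_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Map a semiquantitative image onto an RGB pseudocolor rendering.

    Values are clipped to ``display_range`` (default: data min/max) and
    mapped linearly onto the named matplotlib colormap; returns a uint8
    RGB array ``[..., y, x, 3]``.  Values at or below the range minimum
    get the first color, at or above the maximum the last (no
    wraparound).
    """
    import matplotlib

    values = np.asarray(image.values if hasattr(image, "values") else image,
                        dtype=np.float64)
    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap!r}") from exc
    if display_range is None:
        display_range = (float(values.min()), float(values.max()) or 1.0)
    lo, hi = display_range
    if not lo < hi:
        raise ValueError("display_range min must be < max")
    normed = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    rgba = cmap(normed)
    return (rgba[..., :3] * 255).round().astype(np.uint8)
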