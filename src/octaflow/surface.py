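"""Automatic tissue-surface segmentation of structural OCT volumes.

Depth-layer projections are referenced to the tissue surface, so the
surface must be found first.  The algorithm is deliberately simple and
deterministic: per A-line, median-smooth the axial intensity profile,
threshold it adaptively against the above-surface noise statistics, and
take the first crossing; then clean the resulting height map with a 2-D
median filter.  A-lines with no crossing are flagged and filled from
their nearest successfully segmented neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .exceptions import SegmentationError

__all__ = ["SurfaceParams", "SurfaceMap", "segment_surface"]


@dataclass(frozen=True)
class SurfaceParams:
    """Tunables of the surface finder.

    ``threshold_k`` scales the noise SD added to the noise mean to form
    the crossing threshold; ``noise_rows`` is the number of topmost
    depth rows assumed to lie above the tissue; ``axial_median`` and
    ``surface_median`` are the median-filter window sizes along depth
    and over the (position, x) height map; ``max_failed_fraction`` is
    the tolerated fraction of A-lines without a threshold crossing.
    """

    threshold_k: float = 4.0
    noise_rows: int = 8
    axial_median: int = 3
    surface_median: int = 3
    max_failed_fraction: float = 0.5


@dataclass
class SurfaceMap:
    """Axial surface index per A-line, ``[position, x]`` (plus batch axes)."""

    surface_index: np.ndarray  # int
    quality_flags: np.ndarray  # bool, True where segmentation succeeded
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.surface_index.shape != self.quality_flags.shape:
            raise ValueError("surface_index and quality_flags shapes differ")


def _fill_nearest(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid entries by the nearest valid one (2-D Euclidean)."""
    if valid.all():
        return values
    idx = ndimage.distance_transform_edt(
        ~valid, return_distances=False, return_indices=True
    )
    return values[tuple(idx)]


def segment_surface(
    structural: np.ndarray, params: SurfaceParams | None = None
) -> SurfaceMap:
    """Find the tissue surface in a structural volume ``[position, z, x]``.

    Arbitrary leading batch axes are allowed; noise statistics and the
    failure check are evaluated per volume.  Raises
    :class:`SegmentationError` when more than ``max_failed_fraction`` of
    a volume's A-lines show no threshold crossing.
    """
    p = params or SurfaceParams()
    s = np.asarray(structural)
    if not np.issubdtype(s.dtype, np.floating):
        s = s.astype(np.float64)
    if s.ndim < 3:
        raise ValueError("expected structural axes [position, z, x]")
    n_z = s.shape[-2]
    if p.noise_rows >= n_z:
        raise ValueError("noise_rows must be smaller than the depth size")

    if p.axial_median > 1:
        size = (1,) * (s.ndim - 2) + (p.axial_median, 1)
        smooth = ndimage.median_filter(s, size=size, mode="nearest")
    else:
        smooth = s

    noise = smooth[..., : p.noise_rows, :]
    stat_ax = (-3, -2, -1)
    thr = noise.mean(axis=stat_ax, keepdims=True) + p.threshold_k * noise.std(
        axis=stat_ax, keepdims=True
    )

    above = smooth > thr
    found = above.any(axis=-2)  # [..., position, x]
    first = above.argmax(axis=-2).astype(np.int64)

    failed_frac = 1.0 - found.mean(axis=(-2, -1))
    if np.any(failed_frac > p.max_failed_fraction):
        worst = float(np.max(failed_frac))
        raise SegmentationError(
            f"{worst:.0%} of A-lines show no surface crossing "
            f"(limit {p.max_failed_fraction:.0%})"
        )

    # fill failed columns from nearest segmented neighbour, per volume
    if found.ndim == 2:
        filled = _fill_nearest(first, found)
    else:
        flat = first.reshape((-1,) + first.shape[-2:])
        flatv = found.reshape(flat.shape)
        filled = np.stack(
            [_fill_nearest(a, v) for a, v in zip(flat, flatv)]
        ).reshape(first.shape)

    if p.surface_median > 1:
        size = (1,) * (filled.ndim - 2) + (p.surface_median, p.surface_median)
        filled = ndimage.median_filter(filled, size=size, mode="nearest")

    np.clip(filled, 0, n_z - 1, out=filled)
    return SurfaceMap(
        surface_index=filled,
        quality_flags=found,
        meta={"params": p},
    )
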