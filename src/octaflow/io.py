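"""Volume and table I/O: multi-page TIFF with JSON sidecar metadata.

A repeated-B-scan volume is stored as a multi-page TIFF whose pages are
ordered position-major, repeat-minor (page ``i`` holds position
``i // M``, repeat ``i % M``), with a JSON sidecar next to it carrying
the scan pattern, interscan time, pixel pitches, seed and subject
labels.  Writing then reading reproduces the array bit-exactly and the
metadata field-for-field.  No vendor OCT formats are parsed.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import tifffile

from .containers import OCTVolume, ScanPattern
from .enface import EnFaceMap
from .exceptions import SidecarError

__all__ = [
    "sidecar_path",
    "write_volume",
    "read_volume",
    "write_enface",
    "write_png",
]

PAGE_ORDER = "position-major, repeat-minor"
SIDECAR_VERSION = 1


def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar path next to a TIFF volume (same stem, .json)."""
    p = Path(path)
    return p.with_suffix(".json")


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF plus JSON sidecar.

    One page per (position, repeat) B-scan, position-major; the array
    dtype is preserved.  Returns the TIFF path.
    """
    path = Path(path)
    amp = np.asarray(vol.amplitude)
    if amp.ndim != 4:
        raise ValueError("write_volume expects a single volume [position, repeat, z, x]")
    n_pos, m, n_z, n_x = amp.shape
    pages = amp.reshape(n_pos * m, n_z, n_x)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "sidecar_version": SIDECAR_VERSION,
        "page_order": PAGE_ORDER,
        "pattern": vol.pattern.to_dict(),
        "interscan_time_ms": vol.pattern.interscan_time_ms,
        "axial_pitch_um": vol.axial_pitch_um,
        "lateral_pitch_um": vol.pattern.lateral_pitch_um,
        "position_pitch_um": vol.pattern.position_pitch_um,
        "subject": vol.subject,
        "time_point": vol.time_point,
        "dtype": str(amp.dtype),
        "seed": vol.meta.get("seed"),
        "meta": {k: v for k, v in vol.meta.items() if k != "seed"},
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a multi-page TIFF volume and validate it against its sidecar.

    Raises :class:`SidecarError` on a missing sidecar, a page count
    that does not match ``n_positions * repeats``, or a nonpositive
    axial pitch.
    """
    path = Path(path)
    sc_path = sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar {sc_path}")
    try:
        sidecar = json.loads(sc_path.read_text())
    except json.JSONDecodeError as exc:
        raise SidecarError(f"unreadable sidecar {sc_path}: {exc}") from exc
    for key in ("pattern", "axial_pitch_um"):
        if key not in sidecar:
            raise SidecarError(f"sidecar {sc_path} lacks required field {key!r}")
    pattern = ScanPattern.from_dict(sidecar["pattern"])
    axial_pitch = float(sidecar["axial_pitch_um"])
    if axial_pitch <= 0:
        raise SidecarError(f"axial_pitch_um must be positive, got {axial_pitch}")

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    expected = pattern.n_positions * pattern.repeats
    if pages.shape[0] != expected:
        raise SidecarError(
            f"page count mismatch in {path.name}: expected "
            f"{pattern.n_positions} positions x {pattern.repeats} repeats "
            f"= {expected} pages, found {pages.shape[0]}"
        )
    amp = pages.reshape(
        pattern.n_positions, pattern.repeats, pages.shape[-2], pages.shape[-1]
    )
    meta = dict(sidecar.get("meta") or {})
    if sidecar.get("seed") is not None:
        meta["seed"] = sidecar["seed"]
    return OCTVolume(
        amplitude=amp,
        pattern=pattern,
        axial_pitch_um=axial_pitch,
        subject=sidecar.get("subject", ""),
        time_point=sidecar.get("time_point", ""),
        meta=meta,
    )


def write_enface(emap: EnFaceMap, path: str | Path) -> Path:
    """Write an en-face map (or fused image values) as a single-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(emap.values if hasattr(emap, "values") else emap,
                        dtype=np.float32)
    tifffile.imwrite(path, values, photometric="minisblack")
    return path


def write_png(rgb: np.ndarray, path: str | Path) -> Path:
    """Write a uint8 RGB pseudocolor image as PNG."""
    import matplotlib.image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matplotlib.image.imsave(path, np.asarray(rgb))
    return path
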