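"""Amplitude-decorrelation OCTA computation from repeated B-scans.

The OCTA signal at a voxel is the amplitude decorrelation between
repeated B-scans at the same position: the mean of normalized squared
amplitude differences over consecutive repeat pairs,

    D = mean_k (A_k - A_{k+1})^2 / (A_k^2 + A_{k+1}^2),  k = 1..M-1.

For the standard protocol of M = 3 repeats this averages exactly two
difference images.  The per-pair normalization bounds D in [0, 1] and
makes it invariant to global amplitude gain; consecutive pairing keeps
the effective interscan time equal to tau for every pair (the skipped
pair (1, 3) would double it).
"""

from __future__ import annotations

import numpy as np

from .containers import OCTAVolume, OCTVolume
from .exceptions import PatternError

__all__ = [
    "pairwise_decorrelation",
    "octa_bframe",
    "build_octa_volume",
    "estimate_noise_threshold",
]


def pairwise_decorrelation(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Normalized squared amplitude difference of two repeat frames.

    Per pixel ``D = (A1 - A2)^2 / (A1^2 + A2^2)`` with the convention
    ``D = 0`` where both amplitudes are zero (no evidence of flow).
    Output lies in [0, 1] since ``(a - b)^2 <= a^2 + b^2`` for
    nonnegative a, b.

    Parameters
    ----------
    frame_a, frame_b : ndarray
        Nonnegative amplitude images of identical shape.
    """
    dtype = np.result_type(np.asarray(frame_a).dtype, np.asarray(frame_b).dtype,
                           np.float32)
    a = np.asarray(frame_a, dtype=dtype)
    b = np.asarray(frame_b, dtype=dtype)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("amplitudes must be nonnegative")
    num = (a - b) ** 2
    den = a * a + b * b
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    # the bound D <= 1 holds exactly in reals; clip guards float rounding
    return np.clip(out, 0.0, 1.0, out=out)


def octa_bframe(repeat_stack: np.ndarray, repeat_axis: int = -3) -> np.ndarray:
    """Average the consecutive-pair decorrelation images of a repeat stack.

    Parameters
    ----------
    repeat_stack : ndarray
        Amplitude images stacked along ``repeat_axis`` (default layout
        ``[..., M, z, x]``), M >= 2.
    repeat_axis : int
        Axis holding the M repeats.

    Returns
    -------
    ndarray
        Mean of the M-1 consecutive-pair decorrelation images (for
        M = 3, the average of exactly two); the repeat axis is removed.
    """
    stack = np.asarray(repeat_stack)
    stack = np.moveaxis(stack, repeat_axis, 0)
    m = stack.shape[0]
    if m < 2:
        raise PatternError(f"need at least 2 repeats, got {m}")
    pairs = consecutive_pair_decorrelations(stack)
    return pairs.mean(axis=0)


def consecutive_pair_decorrelations(stack: np.ndarray) -> np.ndarray:
    """Decorrelation image of each consecutive repeat pair.

    ``stack`` is ``[M, ...]``; returns ``[M-1, ...]``.  Exposed so the
    number of averaged difference images is inspectable.
    """
    return pairwise_decorrelation(stack[:-1], stack[1:])


def estimate_noise_threshold(
    structural: np.ndarray,
    k: float = 3.0,
    noise_rows: int = 8,
) -> np.ndarray:
    """Structural-intensity mask threshold from the above-surface region.

    The topmost ``noise_rows`` depth rows of every B-scan lie above the
    tissue surface and contain only noise; the threshold is their mean
    plus ``k`` standard deviations.  For batched input the statistics are
    taken per volume (over the trailing [position, z, x] axes) and the
    result broadcasts against ``structural``.
    """
    region = structural[..., :noise_rows, :]
    ax = (-3, -2, -1)
    mean = region.mean(axis=ax, keepdims=True)
    sd = region.std(axis=ax, keepdims=True)
    return mean + k * sd


def build_octa_volume(
    vol: OCTVolume,
    mask_threshold: float | str = "auto",
    mask_k: float = 3.0,
    noise_rows: int = 8,
) -> OCTAVolume:
    """Compute the decorrelation volume of a repeated-B-scan acquisition.

    Applies :func:`octa_bframe` at every B-scan position, computes the
    structural image as the repeat-mean amplitude, and suppresses noise
    by zeroing D wherever the structural amplitude falls below the mask
    threshold.  ``mask_threshold="auto"`` estimates the threshold as
    mean + ``mask_k`` * SD of the above-surface noise region (the top
    ``noise_rows`` depth rows); pass a number to set it explicitly or 0
    to disable masking.
    """
    amp = np.asarray(vol.amplitude)
    if not np.issubdtype(amp.dtype, np.floating):
        amp = amp.astype(np.float64)
    d = octa_bframe(amp, repeat_axis=-3)
    structural = amp.mean(axis=-3)
    if mask_threshold == "auto":
        thr = estimate_noise_threshold(structural, k=mask_k, noise_rows=noise_rows)
    else:
        thr = np.asarray(float(mask_threshold))
    d = np.where(structural < thr, 0.0, d)
    out = OCTAVolume.like(vol, d, structural)
    out.meta["mask_threshold"] = (
        "auto" if mask_threshold == "auto" else float(mask_threshold)
    )
    out.meta["mask_k"] = float(mask_k)
    out.meta["noise_rows"] = int(noise_rows)
    return out
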