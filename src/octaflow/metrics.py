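"""Flow indices, baseline normalization and time-course statistics.

The flow index F of one semiquantitative image is the total OCTA signal
summed over a circular region of interest.  Because absolute
decorrelation levels differ between subjects (optical alignment, gain),
every subject's indices are normalized by that subject's own baseline
value, giving the dimensionless F-hat carried through the statistics:
paired signed-rank tests of F-hat against baseline within each group,
and rank-sum tests between groups, per time point and layer, at
alpha = 0.05 with no multiplicity correction by default (per-time-point
reporting; a Holm option is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BaselineError

__all__ = [
    "TIME_POINTS",
    "CircularROI",
    "flow_index",
    "records_to_frame",
    "normalize_to_baseline",
    "timecourse_stats",
    "TimeCourseStats",
    "reperfusion_representative",
    "outcome_correlation",
    "OutcomeCorrelation",
]

#: Canonical acquisition timeline: pre-ischemia baseline, the ischemic
#: period, and 1-60 minutes after reperfusion.
TIME_POINTS = ("baseline", "ischemia", "1", "15", "30", "45", "60")


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest on the fused common grid.

    ``center=None`` places the circle at the image center.  Exactly one
    of ``radius_px`` / ``radius_frac`` must be set; ``radius_frac`` is a
    fraction of the smaller image dimension (default 0.4, logged with
    every run since the protocol does not pin the geometry down).
    """

    center: tuple[float, float] | None = None  # (y, x) pixels
    radius_px: float | None = None
    radius_frac: float | None = 0.4

    def __post_init__(self):
        if (self.radius_px is None) == (self.radius_frac is None):
            raise ValueError("set exactly one of radius_px or radius_frac")
        r = self.radius_px if self.radius_px is not None else self.radius_frac
        if r <= 0:
            raise ValueError("ROI radius must be positive")

    def resolve(self, shape: tuple[int, int]) -> tuple[float, float, float]:
        """Concrete (cy, cx, radius_px) for an image shape ``(ny, nx)``."""
        ny, nx = shape
        cy, cx = self.center if self.center is not None else (
            (ny - 1) / 2.0,
            (nx - 1) / 2.0,
        )
        r = (
            self.radius_px
            if self.radius_px is not None
            else self.radius_frac * min(ny, nx)
        )
        return float(cy), float(cx), float(r)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask: centers within Euclidean distance <= radius."""
        cy, cx, r = self.resolve(shape)
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def flow_index(image, roi: CircularROI | None = None) -> float | np.ndarray:
    """Total OCTA signal over the circular region of interest.

    ``image`` is a :class:`~octaflow.fusion.SemiQuantImage` or a bare
    ``[..., y, x]`` array; with batch axes an array of sums is returned.
    Raises ``ValueError`` if the ROI contains no pixel centers.
    """
    roi = roi or CircularROI()
    values = np.asarray(image.values if hasattr(image, "values") else image,
                        dtype=np.float64)
    m = roi.mask(values.shape[-2:])
    if not m.any():
        raise ValueError("ROI contains no pixels for this image size")
    s = values[..., m].sum(axis=-1)
    return float(s) if s.ndim == 0 else s


def records_to_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Normalize an iterable of flow-index record dicts to a DataFrame."""
    df = pd.DataFrame(list(records))
    required = {"subject", "layer", "time_point", "F"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    return df


def normalize_to_baseline(
    records: pd.DataFrame | Iterable[dict], baseline_label: str = "baseline"
) -> pd.DataFrame:
    """Divide each subject/layer series by its own baseline flow index.

    Adds the column ``F_hat = F / F_baseline``; the baseline record gets
    exactly 1.  Raises :class:`BaselineError` if a (subject, layer)
    series lacks a unique baseline record or its baseline F is not
    positive.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    base = df[df["time_point"] == baseline_label]
    counts = base.groupby(["subject", "layer"]).size()
    all_keys = df.groupby(["subject", "layer"]).size()
    missing = sorted(set(all_keys.index) - set(counts.index))
    if missing:
        raise BaselineError(f"no baseline record for (subject, layer): {missing}")
    dup = sorted(counts[counts > 1].index.tolist())
    if dup:
        raise BaselineError(f"multiple baseline records for: {dup}")
    zero = base[base["F"] <= 0][["subject", "layer"]].apply(tuple, axis=1).tolist()
    if zero:
        raise BaselineError(f"baseline flow index not positive for: {sorted(zero)}")
    ref = base.set_index(["subject", "layer"])["F"]
    df["F_hat"] = df["F"].to_numpy() / ref.loc[
        pd.MultiIndex.from_frame(df[["subject", "layer"]])
    ].to_numpy()
    return df


def _signed_rank_p(values: np.ndarray) -> float:
    """Exact-when-possible Wilcoxon signed-rank p of values vs 1."""
    diffs = np.asarray(values, dtype=np.float64) - 1.0
    if np.all(diffs == 0):
        return 1.0  # degenerate no-signal case: no evidence of change
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diffs, zero_method="wilcox", method="auto")
    return float(res.pvalue)


@dataclass
class TimeCourseStats:
    """Within-group (vs baseline) and between-group test results.

    ``within``: one row per (group, layer, time_point) with the paired
    signed-rank p-value of F-hat against 1.  ``between``: one row per
    (layer, time_point) with the rank-sum p-value comparing the two
    groups' F-hat.  ``alpha`` marks the significance column.
    """

    within: pd.DataFrame
    between: pd.DataFrame
    alpha: float = 0.05
    correction: str | None = None


def timecourse_stats(
    records: pd.DataFrame,
    alpha: float = 0.05,
    baseline_label: str = "baseline",
    correction: str | None = None,
) -> TimeCourseStats:
    """Nonparametric time-course analysis of normalized flow indices.

    Within each group and layer, F-hat at every post-baseline time point
    is compared against the baseline value 1 with an exact paired
    Wilcoxon signed-rank test; between the two groups, F-hat is compared
    at every time point and layer with an exact Mann-Whitney rank-sum
    test.  Both are two-sided.  Ties and zero differences follow the
    exact-conditional convention of scipy (zero differences dropped,
    exact null enumeration when untied).  No multiplicity correction is
    applied unless ``correction="holm"``.
    """
    df = records
    if "F_hat" not in df.columns:
        raise ValueError("records must carry F_hat; run normalize_to_baseline first")
    groups = sorted(df["group"].unique()) if "group" in df.columns else []
    for g, sub in df.groupby("group") if groups else []:
        if sub["subject"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    tps = [t for t in _ordered_time_points(df) if t != baseline_label]

    within_rows = []
    for (g, layer), sub in df.groupby(["group", "layer"]) if groups else []:
        for tp in tps:
            vals = sub.loc[sub["time_point"] == tp, "F_hat"].to_numpy()
            if len(vals) == 0:
                continue
            p = _signed_rank_p(vals)
            within_rows.append(
                {"group": g, "layer": layer, "time_point": tp, "n": len(vals),
                 "p_value": p}
            )
    within = pd.DataFrame(within_rows)

    between_rows = []
    if len(groups) == 2:
        g1, g2 = groups
        for layer, sub in df.groupby("layer"):
            for tp in tps:
                a = sub.loc[
                    (sub["time_point"] == tp) & (sub["group"] == g1), "F_hat"
                ].to_numpy()
                b = sub.loc[
                    (sub["time_point"] == tp) & (sub["group"] == g2), "F_hat"
                ].to_numpy()
                if len(a) == 0 or len(b) == 0:
                    continue
                pooled = np.concatenate([a, b])
                method = (
                    "exact"
                    if max(len(a), len(b)) <= 30
                    and len(np.unique(pooled)) == len(pooled)
                    else "asymptotic"
                )
                res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method=method)
                between_rows.append(
                    {"layer": layer, "time_point": tp, "n_1": len(a),
                     "n_2": len(b), "p_value": float(res.pvalue)}
                )
    between = pd.DataFrame(between_rows)

    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        for frame in (within, between):
            if len(frame):
                frame["p_adjusted"] = multipletests(
                    frame["p_value"], method="holm"
                )[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    for frame in (within, between):
        if len(frame):
            pcol = "p_adjusted" if correction else "p_value"
            frame["significant"] = frame[pcol] < alpha
    return TimeCourseStats(within=within, between=between, alpha=alpha,
                           correction=correction)


def _ordered_time_points(df: pd.DataFrame) -> list[str]:
    present = list(dict.fromkeys(df["time_point"]))
    known = [t for t in TIME_POINTS if t in present]
    extra = [t for t in present if t not in TIME_POINTS]
    return known + extra


def reperfusion_representative(
    records: pd.DataFrame, times: Sequence[str] = ("45", "60")
) -> pd.DataFrame:
    """Representative short-term reperfusion index per subject and layer.

    The mean of the normalized flow indices at the 45- and 60-minute
    time points.  Raises ``ValueError`` if either time point is missing
    for some subject/layer.
    """
    col = "F_hat" if "F_hat" in records.columns else "F"
    sub = records[records["time_point"].isin(times)]
    counts = sub.groupby(["subject", "layer"]).size()
    bad = sorted(counts[counts != len(times)].index.tolist())
    missing_keys = sorted(
        set(records.groupby(["subject", "layer"]).size().index) - set(counts.index)
    )
    if bad or missing_keys:
        raise ValueError(
            f"missing {'/'.join(times)} records for (subject, layer): "
            f"{bad + missing_keys}"
        )
    out = (
        sub.groupby(["subject", "layer"], as_index=False)
        .agg(representative=(col, "mean"))
    )
    if "group" in records.columns:
        gmap = records.drop_duplicates("subject").set_index("subject")["group"]
        out["group"] = out["subject"].map(gmap)
    return out


@dataclass
class OutcomeCorrelation:
    """Per-layer least-squares fit of an outcome vs the flow index."""

    table: pd.DataFrame  # layer, slope, intercept, r_squared, n

    def r_squared(self, layer: str) -> float:
        row = self.table[self.table["layer"] == layer]
        if row.empty:
            raise KeyError(layer)
        return float(row["r_squared"].iloc[0])


def outcome_correlation(
    representatives: pd.DataFrame, outcomes: pd.DataFrame
) -> OutcomeCorrelation:
    """Correlate the representative reperfusion index with an outcome.

    ``representatives`` has columns (subject, layer, representative);
    ``outcomes`` has (subject, outcome).  Ordinary least squares per
    layer; R^2 = 1 - SS_res / SS_tot.  Requires n >= 3 matched subjects
    per layer; a zero-variance outcome yields R^2 = NaN with a warning.
    """
    merged = representatives.merge(outcomes[["subject", "outcome"]], on="subject")
    rows = []
    for layer, sub in merged.groupby("layer"):
        x = sub["representative"].to_numpy(dtype=np.float64)
        y = sub["outcome"].to_numpy(dtype=np.float64)
        n = len(sub)
        if n < 3:
            raise ValueError(f"layer {layer!r}: need >= 3 matched subjects, got {n}")
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            warnings.warn(
                f"layer {layer!r}: degenerate variance, R^2 not applicable",
                stacklevel=2,
            )
            rows.append({"layer": layer, "slope": np.nan, "intercept": np.nan,
                         "r_squared": np.nan, "n": n})
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {"layer": layer, "slope": float(fit.slope),
             "intercept": float(fit.intercept),
             "r_squared": float(fit.rvalue**2), "n": n}
        )
    return OutcomeCorrelation(table=pd.DataFrame(rows))
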