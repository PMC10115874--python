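"""End-to-end orchestration: simulate or load volumes, compute
decorrelation, segment the surface, project, fuse, and tabulate flow
indices and statistics.

Two execution paths share the same underlying operations:

- :func:`run_pipeline` is the file-based path driven by a
  :class:`~octaflow.config.RunConfig`; it writes volumes, en-face maps,
  fused images, CSV tables, and a provenance log.
- :func:`cohort_flow_table` is the in-memory path used for simulation
  studies; it batches all subjects and time points of a cohort through
  the identical array operations (every processing function accepts
  leading batch axes), which makes replicate studies cheap.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, cohort_truth, subject_ids
from .config import RunConfig
from .containers import OCTAVolume, OCTVolume, ScanPattern
from .decorr import build_octa_volume
from .enface import EnFaceMap, LayerConfig, enface_max_projection
from .exceptions import OctaflowError
from .fusion import SemiQuantImage, fuse_semiquant, pseudocolor
from .io import write_enface, write_png, write_volume
from .metrics import CircularROI, flow_index, normalize_to_baseline, timecourse_stats
from .phantom import PhantomSpec, simulate_speckle_repeats
from .surface import SurfaceParams, segment_surface

logger = logging.getLogger("octaflow")

__all__ = [
    "PipelineError",
    "process_volume",
    "fuse_timepoint",
    "cohort_flow_table",
    "run_pipeline",
]


class PipelineError(OctaflowError):
    """A pipeline stage failed; carries the stage name and input identity."""

    def __init__(self, stage: str, ident: str, cause: Exception):
        self.stage = stage
        self.ident = ident
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on {ident}: {cause}")


def process_volume(
    vol: OCTVolume,
    layers: Sequence[LayerConfig],
    mask_threshold="auto",
    mask_k: float = 3.0,
    noise_rows: int = 8,
    surface_params: SurfaceParams | None = None,
) -> tuple[OCTAVolume, dict[str, EnFaceMap]]:
    """Decorrelate one volume and project every requested layer.

    Returns the OCTA volume and a dict layer name -> en-face map.
    Layers whose contributing-pattern set excludes this volume's
    pattern are skipped.
    """
    octa = build_octa_volume(
        vol, mask_threshold=mask_threshold, mask_k=mask_k, noise_rows=noise_rows
    )
    surf = segment_surface(octa.structural, surface_params)
    maps: dict[str, EnFaceMap] = {}
    for layer in layers:
        if vol.pattern.name not in layer.contributing_patterns:
            continue
        maps[layer.name] = enface_max_projection(octa, surf, layer)
    return octa, maps


def fuse_timepoint(
    maps_by_pattern: Mapping[str, Mapping[str, EnFaceMap]],
    layers: Sequence[LayerConfig],
    target_size: tuple[int, int] | None = None,
) -> dict[str, SemiQuantImage]:
    """Fuse per-pattern en-face maps into one image per layer.

    ``maps_by_pattern`` maps pattern name -> {layer name -> EnFaceMap}.
    """
    fused = {}
    for layer in layers:
        maps = {
            pname: per_layer[layer.name]
            for pname, per_layer in maps_by_pattern.items()
            if layer.name in per_layer
        }
        fused[layer.name] = fuse_semiquant(maps, layer, target_size)
    return fused


def cohort_flow_table(
    cohort: CohortSpec,
    phantom: PhantomSpec,
    patterns: Sequence[ScanPattern],
    layers: Sequence[LayerConfig],
    roi: CircularROI | None = None,
    mask_threshold="auto",
    mask_k: float = 3.0,
    noise_rows: int = 8,
    surface_params: SurfaceParams | None = None,
    fusion_grid: tuple[int, int] | None = None,
    normalize: bool = True,
    return_images: bool = False,
):
    """Simulate a cohort and run the full pipeline to flow indices.

    All (subject, time point) acquisitions of each pattern are
    simulated and processed as one batch through the standard
    operations (decorrelation, masking, surface segmentation, en-face
    projection, fusion, circular-ROI summation).  Returns the flow-
    index table with columns (subject, group, time_point, layer, F and,
    if ``normalize``, F_hat) plus the ground-truth tables.
    Deterministic given ``cohort.seed``.
    """
    if not patterns:
        raise ValueError("patterns must be nonempty")
    roi = roi or CircularROI()
    rng = np.random.default_rng(cohort.seed)
    truth = cohort_truth(cohort, phantom, rng)
    ids = subject_ids(cohort)
    batch = [(sid, tp) for sid, _ in ids for tp in cohort.time_points]
    groups = {g.name: g for g in cohort.groups}
    gmap = dict(ids)
    factors = (
        truth.schedule.drop_duplicates("subject")
        .set_index("subject")["subject_factor"]
        .to_dict()
    )
    layer_names = [l.name for l in phantom.vessel_layers]

    maps_by_pattern: dict[str, dict[str, EnFaceMap]] = {}
    for pattern in patterns:
        spec = phantom.scaled_to(pattern)
        tissue = spec.tissue_mask()
        # per-vessel-layer unit masks; speeds scale per batch entry
        unit = {
            l.name: (spec.speed_map({n: (1.0 if n == l.name else 0.0)
                                     for n in layer_names}),)
            for l in spec.vessel_layers
        }
        v = np.zeros((len(batch),) + tissue.shape, dtype=np.float32)
        for b, (sid, tp) in enumerate(batch):
            mult = groups[gmap[sid]].multipliers(tp, layer_names)
            f = factors[sid]
            for lname, (vmap,) in unit.items():
                v[b] += (mult[lname] * f) * vmap.astype(np.float32)
        rho = spec.speckle.rho(v, pattern.interscan_time_ms)
        amp = simulate_speckle_repeats(
            rho,
            n_repeats=pattern.repeats,
            mean_amplitude=spec.static_tissue_amplitude,
            noise_sigma=spec.speckle.noise_floor_sigma,
            tissue_mask=tissue,
            rng=rng,
        )
        vol = OCTVolume(
            amplitude=amp, pattern=pattern, axial_pitch_um=spec.axial_pitch_um
        )
        octa = build_octa_volume(
            vol, mask_threshold=mask_threshold, mask_k=mask_k, noise_rows=noise_rows
        )
        surf = segment_surface(octa.structural, surface_params)
        per_layer = {}
        for layer in layers:
            if pattern.name not in layer.contributing_patterns:
                continue
            per_layer[layer.name] = enface_max_projection(octa, surf, layer)
        maps_by_pattern[pattern.name] = per_layer

    fused = fuse_timepoint(maps_by_pattern, layers, fusion_grid)
    rows = []
    for layer_name, image in fused.items():
        f_values = flow_index(image, roi)  # [B]
        for b, (sid, tp) in enumerate(batch):
            rows.append(
                {
                    "subject": sid,
                    "group": gmap[sid],
                    "time_point": tp,
                    "layer": layer_name,
                    "F": float(np.asarray(f_values)[b]),
                }
            )
    table = pd.DataFrame(rows)
    if normalize:
        table = normalize_to_baseline(table)
    if return_images:
        return table, truth, maps_by_pattern, fused, batch
    return table, truth


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        config.model_dump_json().encode()
    ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Paths and tables produced by a file-based pipeline run."""

    output_dir: Path
    flow_table: pd.DataFrame
    stats_within: pd.DataFrame
    stats_between: pd.DataFrame
    artifacts: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: RunConfig, write_volumes: bool = False) -> PipelineResult:
    """Execute the full simulate-and-process pipeline from a config.

    Writes per-layer fused images (TIFF + pseudocolor PNG), the flow
    index CSV (columns subject, group, time_point, layer, F, F_hat),
    the statistics CSVs, and a JSON run log carrying the resolved
    configuration, root seed, config hash and package version.
    Deterministic given config and seed.  Stage failures raise
    :class:`PipelineError` naming the stage and input.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    patterns = [p.build() for p in config.patterns]
    phantom = config.phantom.build()
    layers = [l.build() for l in config.layers]
    roi = config.roi.build()
    sp = config.processing.surface_params()

    if config.cohort is None:
        raise PipelineError("setup", "config", ValueError("config.cohort is required"))
    cohort = config.cohort.build()
    if cohort.seed == 0 and config.seed != 0:
        cohort = CohortSpec(
            groups=cohort.groups,
            time_points=cohort.time_points,
            between_subject_cv=cohort.between_subject_cv,
            outcome_model=cohort.outcome_model,
            seed=config.seed,
        )

    artifacts: dict[str, str] = {}

    if write_volumes:
        from .cohort import iter_cohort_volumes

        try:
            for (sid, tp, pname), vol in iter_cohort_volumes(
                cohort, phantom, patterns
            ):
                vpath = out / "volumes" / f"{sid}_{tp}_{pname}.tiff"
                write_volume(vol, vpath)
                artifacts[f"volume/{sid}/{tp}/{pname}"] = str(vpath)
        except OctaflowError as exc:
            raise PipelineError("simulate", "cohort volumes", exc) from exc

    try:
        table, truth, maps_by_pattern, fused, batch = cohort_flow_table(
            cohort,
            phantom,
            patterns,
            layers,
            roi=roi,
            mask_threshold=config.processing.mask_threshold,
            mask_k=config.processing.mask_k,
            noise_rows=config.processing.noise_rows,
            surface_params=sp,
            fusion_grid=config.processing.fusion_grid,
            return_images=True,
        )
    except OctaflowError as exc:
        raise PipelineError("process", "cohort", exc) from exc

    try:
        for pname, per_layer in maps_by_pattern.items():
            for lname, emap in per_layer.items():
                for b, (sid, tp) in enumerate(batch):
                    p = out / "enface" / f"{sid}_{tp}_{lname}_{pname}.tiff"
                    write_enface(emap.values[b], p)
                    artifacts[f"enface/{sid}/{tp}/{lname}/{pname}"] = str(p)
        for lname, image in fused.items():
            vmax = float(np.quantile(image.values, 0.999)) or 1.0
            for b, (sid, tp) in enumerate(batch):
                p = out / "fused" / f"{sid}_{tp}_{lname}.tiff"
                write_enface(image.values[b], p)
                artifacts[f"fused/{sid}/{tp}/{lname}"] = str(p)
                rgb = pseudocolor(image.values[b], display_range=(0.0, vmax))
                png = out / "fused" / f"{sid}_{tp}_{lname}.png"
                write_png(rgb, png)
                artifacts[f"pseudocolor/{sid}/{tp}/{lname}"] = str(png)
    except (OctaflowError, OSError) as exc:
        raise PipelineError("export", "fused images", exc) from exc

    try:
        stats = timecourse_stats(
            table,
            alpha=config.stats.alpha,
            baseline_label=config.stats.baseline_label,
            correction=config.stats.correction,
        )
    except (OctaflowError, ValueError) as exc:
        raise PipelineError("stats", "flow table", exc) from exc

    flow_csv = out / "flow_indices.csv"
    table.to_csv(flow_csv, index=False, float_format="%.10g")
    artifacts["flow_indices"] = str(flow_csv)
    for name, frame in (
        ("stats_within", stats.within),
        ("stats_between", stats.between),
        ("truth_schedule", truth.schedule),
        ("truth_outcomes", truth.outcomes),
    ):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        artifacts[name] = str(p)

    log = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "roi": {"center": config.roi.center, "radius_px": config.roi.radius_px,
                "radius_frac": config.roi.radius_frac},
        "mask_threshold": config.processing.mask_threshold,
        "artifacts": artifacts,
    }
    (out / "run_config.json").write_text(config.model_dump_json(indent=2))
    (out / "run_log.json").write_text(json.dumps(log, indent=2))

    return PipelineResult(
        output_dir=out,
        flow_table=table,
        stats_within=stats.within,
        stats_between=stats.between,
        artifacts=artifacts,
    )
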