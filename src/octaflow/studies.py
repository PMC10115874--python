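"""Reference study conditions for simulation experiments.

These fix, once, the synthetic conditions used by the package's own
validation studies: a desk-scale phantom whose scan patterns are
scaled-down stand-ins for the instrument's 256/512/1024 rasters
(identical interscan times, reduced lateral sampling so that replicate
cohort studies run quickly), baseline capillary speeds placed in the
fused response's pre-saturation quasi-linear band, and the two-group
ischemia-reperfusion designs (n = 8 mild-type and n = 9 moderate-type
subjects on the baseline / ischemia / 1-60 min timeline).

Parameter choices, in brief:

- Speckle radius ``w = 4`` um: half of a typical ~8 um lateral spot.
- Baseline speeds 0.55 um/ms (superficial) and 0.9 um/ms (deep):
  realistic capillary red-cell speeds, calibrated once by a pilot
  measurement of the fused flow-index-versus-speed response so that
  the response stays within about +-12% of proportional to the speed
  multiplier over multipliers 0.4-1.2 for each layer's contributing
  interscan times (the maximum projection's upper-tail bias makes the
  measured response flatter than the correlation law alone predicts,
  so the operating point sits below the single-tau theoretical
  optimum).
- Noise floor 0.02 relative to unit tissue amplitude (amplitude SNR
  50), enough to exercise masking and surface finding while keeping
  static-tissue noise decorrelation from putting a floor under the
  ROI sums.
- Axial pitch 10 um: the superficial (50-70 um) and deep (320-340 um)
  slabs fall at voxel offsets 5-7 and 32-34 below the surface.
"""

from __future__ import annotations

import numpy as _np

from .cohort import CohortSpec, GroupSpec, OutcomeModel
from .containers import ScanPattern
from .enface import DEEP, SUPERFICIAL, LayerConfig
from .metrics import CircularROI
from .phantom import Disk, PhantomSpec, SpeckleModel, VesselLayer

__all__ = [
    "mini_patterns",
    "mini_phantom",
    "mini_layers",
    "mini_roi",
    "recovery_cohort",
    "null_cohort",
    "outcome_cohort",
    "run_replicate_study",
]

#: Interscan times (ms) of the three raster patterns.
TAUS = {"256": 1.5, "512": 3.0, "1024": 5.8}

#: Flow-speed multiplier schedules mirroring the experimental course:
#: the mild group recovers fully after reperfusion; the moderate group
#: shows a sustained superficial deficit from 15 min and a delayed,
#: milder deep deficit at 45-60 min.
MILD_SCHEDULE = {
    "baseline": 1.0,
    "ischemia": 0.0,
    "1": 1.0,
    "15": 1.0,
    "30": 1.0,
    "45": 1.0,
    "60": 1.0,
}
MODERATE_SCHEDULE = {
    "baseline": 1.0,
    "ischemia": 0.0,
    "1": {"superficial": 1.0, "deep": 0.7},
    "15": {"superficial": 0.4, "deep": 0.9},
    "30": {"superficial": 0.4, "deep": 0.9},
    "45": {"superficial": 0.4, "deep": 0.6},
    "60": {"superficial": 0.4, "deep": 0.6},
}


def mini_patterns() -> list[ScanPattern]:
    """Scaled-down stand-ins for the 256/512/1024 rasters.

    All three sample a 0.288 x 0.096 mm field at 24 x 8 A-lines (12 um
    lateral pitch) but keep the protocol's interscan times, so speed-
    versus-tau behaviour matches the full-size patterns at a fraction
    of the cost.
    """
    return [
        ScanPattern(24, 8, 3, tau, (0.288, 0.096), name)
        for name, tau in TAUS.items()
    ]


def mini_phantom(seed: int = 0, noise_floor_sigma: float = 0.02) -> PhantomSpec:
    """Desk-scale curved-surface phantom with two vascular layers."""
    return PhantomSpec(
        grid=(42, 24, 8),
        axial_pitch_um=12.0,
        surface_profile={
            "type": "dome",
            "z0": 12.0,
            "amplitude": 4.0,
            "sigma_frac": 0.5,
            "nx": 24,
            "ny": 8,
        },
        vessel_layers=(
            VesselLayer(
                name="superficial",
                depth_range_um=(50.0, 70.0),
                disks=(
                    Disk((6.0, 2.0), 2.6),
                    Disk((12.0, 5.0), 2.6),
                    Disk((18.0, 2.0), 2.6),
                ),
                flow_speed_um_ms=0.55,
            ),
            VesselLayer(
                name="deep",
                depth_range_um=(320.0, 340.0),
                disks=(
                    Disk((10.0, 4.0), 2.6),
                    Disk((14.0, 3.0), 2.6),
                ),
                flow_speed_um_ms=0.9,
            ),
        ),
        static_tissue_amplitude=1.0,
        speckle=SpeckleModel(
            resolution_radius_um=4.0,
            noise_floor_sigma=noise_floor_sigma,
        ),
        seed=seed,
    )


def mini_layers() -> list[LayerConfig]:
    return [SUPERFICIAL, DEEP]


def mini_roi() -> CircularROI:
    """Centered circle, radius 0.4 x the smaller image dimension."""
    return CircularROI(radius_frac=0.4)


def recovery_cohort(seed: int = 0, between_subject_cv: float = 0.15) -> CohortSpec:
    """Two-group design: full mild recovery vs a sustained moderate deficit."""
    return CohortSpec(
        groups=(
            GroupSpec("mild", 8, MILD_SCHEDULE),
            GroupSpec("moderate", 9, MODERATE_SCHEDULE),
        ),
        between_subject_cv=between_subject_cv,
        outcome_model=OutcomeModel(intercept=50.0, slope=-30.0, noise_sd=5.19,
                                   layer="superficial"),
        seed=seed,
    )


def null_cohort(seed: int = 0, between_subject_cv: float = 0.15) -> CohortSpec:
    """Both groups follow the fully recovering schedule (no group effect)."""
    return CohortSpec(
        groups=(
            GroupSpec("mild", 8, MILD_SCHEDULE),
            GroupSpec("moderate", 9, MILD_SCHEDULE),
        ),
        between_subject_cv=between_subject_cv,
        seed=seed,
    )


def run_replicate_study(
    cohort_factory,
    n_replicates: int,
    seed: int,
    phantom_factory=mini_phantom,
):
    """Run the full pipeline on many independently seeded cohorts.

    For each replicate the cohort is simulated and processed end to end
    (decorrelation, surface segmentation, projection, fusion, ROI flow
    index, baseline normalization, time-course tests).  Returns two
    tidy tables: per-replicate median normalized flow index per
    (group, layer, time point), merged with the true multiplier, and
    the per-replicate between-group p-values per (layer, time point).
    """
    import pandas as pd

    from .metrics import timecourse_stats
    from .pipeline import cohort_flow_table

    rng_seeds = _np.random.default_rng(seed).integers(0, 2**31, size=n_replicates)
    med_rows = []
    p_rows = []
    for rep, s in enumerate(rng_seeds):
        cohort = cohort_factory(seed=int(s))
        table, truth = cohort_flow_table(
            cohort,
            phantom_factory(),
            mini_patterns(),
            mini_layers(),
            roi=mini_roi(),
        )
        med = (
            table.groupby(["group", "layer", "time_point"], as_index=False)
            .agg(median_f_hat=("F_hat", "median"))
        )
        mult = (
            truth.schedule.groupby(
                ["group", "layer", "time_point"], as_index=False
            ).agg(multiplier=("multiplier", "first"))
        )
        med = med.merge(mult, on=["group", "layer", "time_point"])
        med["replicate"] = rep
        med_rows.append(med)

        st = timecourse_stats(table)
        bw = st.between.copy()
        bw["replicate"] = rep
        p_rows.append(bw)
    return pd.concat(med_rows, ignore_index=True), pd.concat(
        p_rows, ignore_index=True
    )


def outcome_cohort(seed: int = 0) -> CohortSpec:
    """Recovery design with outcome noise set for a generating R^2 of 0.75.

    With 8 subjects at a superficial late-reperfusion multiplier of 1.0
    and 9 at 0.4, the population variance of the true representative
    index is 0.0897; with slope -30 the outcome noise SD of 5.19 makes
    slope^2 * var / (slope^2 * var + sd^2) = 0.75.
    """
    return recovery_cohort(seed=seed)
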