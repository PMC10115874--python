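"""Multi-subject ischemia-reperfusion cohort simulation.

A cohort couples the flow phantom to an experiment design: groups of
subjects imaged at a fixed timeline (baseline, during ischemia, and
1-60 minutes after reperfusion), each group following a schedule of
per-layer flow-speed multipliers relative to baseline.  Intersubject
variation in absolute flow is modelled as a subject-level lognormal
factor (which baseline normalization is designed to cancel), and a
per-subject scalar outcome (emulating, e.g., a late fibrosis readout)
is drawn linearly from the subject's true late-reperfusion flow plus
Gaussian noise.  The simulator emits the ground-truth multiplier and
outcome tables alongside the volumes so recovery can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import OCTVolume, ScanPattern
from .metrics import TIME_POINTS
from .phantom import PhantomSpec, simulate_repeat_bscans

__all__ = [
    "OutcomeModel",
    "GroupSpec",
    "CohortSpec",
    "CohortTruth",
    "subject_ids",
    "simulate_cohort",
    "iter_cohort_volumes",
]


@dataclass(frozen=True)
class OutcomeModel:
    """Linear outcome model: outcome = intercept + slope * true_rep + noise."""

    intercept: float = 0.0
    slope: float = 1.0
    noise_sd: float = 0.0
    layer: str = "superficial"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group and its multiplier schedule.

    ``schedule`` maps time point -> per-layer multiplier; an entry may
    be a single number (applied to every vessel layer) or a mapping
    from layer name to multiplier.
    """

    name: str
    n_subjects: int
    schedule: Mapping[str, object]

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def multipliers(self, time_point: str, layers: Sequence[str]) -> dict[str, float]:
        entry = self.schedule[time_point]
        if isinstance(entry, Mapping):
            return {name: float(entry.get(name, 1.0)) for name in layers}
        return {name: float(entry) for name in layers}


@dataclass(frozen=True)
class CohortSpec:
    """Experiment design: groups, timeline, variability and outcome model."""

    groups: tuple[GroupSpec, ...]
    time_points: tuple[str, ...] = TIME_POINTS
    between_subject_cv: float = 0.15
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "time_points", tuple(self.time_points))
        if "baseline" not in self.time_points:
            raise ValueError("time_points must include 'baseline'")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")
        for g in self.groups:
            for tp in self.time_points:
                if tp not in g.schedule:
                    raise ValueError(
                        f"group {g.name!r} schedule lacks time point {tp!r}"
                    )
                entry = g.schedule[tp]
                vals = (
                    list(entry.values()) if isinstance(entry, Mapping) else [entry]
                )
                if any(v < 0 for v in vals):
                    raise ValueError("schedule multipliers must be >= 0")
                if tp == "ischemia" and any(v != 0 for v in vals):
                    raise ValueError(
                        "ischemia multiplier must be 0 (flow signal "
                        "disappears while the arteries are clamped)"
                    )


@dataclass
class CohortTruth:
    """Ground truth emitted with a simulated cohort.

    ``schedule``: long table (subject, group, time_point, layer,
    multiplier, subject_factor, true_speed_um_ms).  ``outcomes``: per
    subject (subject, group, true_representative, outcome).
    """

    schedule: pd.DataFrame
    outcomes: pd.DataFrame


def subject_ids(cohort: CohortSpec) -> list[tuple[str, str]]:
    """(subject id, group name) pairs, group order preserved."""
    out = []
    for g in cohort.groups:
        for i in range(g.n_subjects):
            out.append((f"{g.name}-{i + 1:02d}", g.name))
    return out


def _subject_factors(cohort: CohortSpec, rng: np.random.Generator) -> dict[str, float]:
    cv = cohort.between_subject_cv
    ids = subject_ids(cohort)
    if cv == 0:
        return {sid: 1.0 for sid, _ in ids}
    sigma2 = math.log(1.0 + cv * cv)
    mu = -sigma2 / 2.0  # unit mean
    draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=len(ids))
    return {sid: float(f) for (sid, _), f in zip(ids, draws)}


def cohort_truth(
    cohort: CohortSpec,
    phantom: PhantomSpec,
    rng: np.random.Generator,
) -> CohortTruth:
    """Draw subject factors and outcomes; tabulate the ground truth."""
    layer_names = [l.name for l in phantom.vessel_layers]
    base_speed = {l.name: l.flow_speed_um_ms for l in phantom.vessel_layers}
    factors = _subject_factors(cohort, rng)
    groups = {g.name: g for g in cohort.groups}

    rows = []
    for sid, gname in subject_ids(cohort):
        g = groups[gname]
        for tp in cohort.time_points:
            mult = g.multipliers(tp, layer_names)
            for layer in layer_names:
                rows.append(
                    {
                        "subject": sid,
                        "group": gname,
                        "time_point": tp,
                        "layer": layer,
                        "multiplier": mult[layer],
                        "subject_factor": factors[sid],
                        "true_speed_um_ms": base_speed[layer]
                        * mult[layer]
                        * factors[sid],
                    }
                )
    schedule = pd.DataFrame(rows)

    om = cohort.outcome_model
    out_rows = []
    for sid, gname in subject_ids(cohort):
        g = groups[gname]
        m45 = g.multipliers("45", layer_names).get(om.layer, 1.0)
        m60 = g.multipliers("60", layer_names).get(om.layer, 1.0)
        true_rep = 0.5 * (m45 + m60)
        noise = float(rng.normal(0.0, om.noise_sd)) if om.noise_sd > 0 else 0.0
        out_rows.append(
            {
                "subject": sid,
                "group": gname,
                "true_representative": true_rep,
                "outcome": om.intercept + om.slope * true_rep + noise,
            }
        )
    return CohortTruth(schedule=schedule, outcomes=pd.DataFrame(out_rows))


def iter_cohort_volumes(
    cohort: CohortSpec,
    phantom: PhantomSpec,
    patterns: Sequence[ScanPattern],
    truth: CohortTruth | None = None,
) -> Iterator[tuple[tuple[str, str, str], OCTVolume]]:
    """Lazily simulate every (subject, time point, pattern) volume.

    Yields ``((subject, time_point, pattern_name), OCTVolume)``.  All
    randomness derives from ``cohort.seed``; pass a precomputed
    ``truth`` (from :func:`cohort_truth` with the same seed) to keep
    subject factors consistent.
    """
    if not patterns:
        raise ValueError("patterns must be nonempty")
    rng = np.random.default_rng(cohort.seed)
    if truth is None:
        truth = cohort_truth(cohort, phantom, rng)
    else:
        cohort_truth(cohort, phantom, rng)  # advance the stream identically
    layer_names = [l.name for l in phantom.vessel_layers]
    groups = {g.name: g for g in cohort.groups}
    factors = (
        truth.schedule.drop_duplicates("subject")
        .set_index("subject")["subject_factor"]
        .to_dict()
    )
    scaled = {p.name: phantom.scaled_to(p) for p in patterns}
    for sid, gname in subject_ids(cohort):
        g = groups[gname]
        for tp in cohort.time_points:
            mult = g.multipliers(tp, layer_names)
            for p in patterns:
                seed = int(rng.integers(0, 2**31))
                vol = simulate_repeat_bscans(
                    scaled[p.name],
                    p,
                    seed=seed,
                    speed_multipliers=mult,
                    subject_factor=factors[sid],
                    subject=sid,
                    time_point=tp,
                )
                yield (sid, tp, p.name), vol


def simulate_cohort(
    cohort: CohortSpec,
    phantom: PhantomSpec,
    patterns: Sequence[ScanPattern],
) -> tuple[dict[tuple[str, str, str], OCTVolume], CohortTruth]:
    """Simulate a full cohort into memory.

    Returns the volume dictionary keyed by (subject, time_point,
    pattern name) and the ground-truth tables.  For large cohorts
    prefer :func:`iter_cohort_volumes` or the batched
    :func:`octaflow.pipeline.cohort_flow_table`.
    """
    rng = np.random.default_rng(cohort.seed)
    truth = cohort_truth(cohort, phantom, rng)
    volumes = dict(iter_cohort_volumes(cohort, phantom, patterns, truth=truth))
    return volumes, truth
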