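"""Speckle simulator: determinism, correlation law, oracle agreement,
cohort structure."""

import numpy as np
import pytest

from octaflow.cohort import CohortSpec, GroupSpec, simulate_cohort, subject_ids
from octaflow.containers import ScanPattern
from octaflow.decorr import octa_bframe
from octaflow.exceptions import GeometryError, PatternError
from octaflow.phantom import (
    RAYLEIGH_PLATEAU_D,
    SpeckleModel,
    analytic_decorr_oracle,
    simulate_repeat_bscans,
)
from octaflow.studies import MILD_SCHEDULE, mini_patterns, mini_phantom


class TestSpeckleModel:
    def test_rho_is_one_at_zero_speed_and_decreasing(self):
        m = SpeckleModel(resolution_radius_um=4.0)
        assert m.rho(0.0, 5.8) == 1.0
        speeds = np.linspace(0, 10, 30)
        rho = m.rho(speeds, 3.0)
        assert np.all((rho >= 0) & (rho <= 1))
        assert np.all(np.diff(rho) < 0)

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError, match="correlation law"):
            SpeckleModel(correlation_law="cauchy")


class TestOracle:
    def test_perfect_correlation_gives_exact_zero(self):
        res = analytic_decorr_oracle(1.0, 50_000, seed=3)
        assert res.mean == 0.0

    def test_zero_correlation_matches_frozen_plateau(self):
        res = analytic_decorr_oracle(0.0, 1_000_000, seed=3)
        assert res.mean == pytest.approx(RAYLEIGH_PLATEAU_D, abs=4 * res.se + 1e-4)

    def test_monotone_decreasing_in_rho(self):
        means = [
            analytic_decorr_oracle(r, 200_000, seed=5).mean
            for r in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            analytic_decorr_oracle(1.2, 50_000)
        with pytest.raises(ValueError):
            analytic_decorr_oracle(0.5, 100)


class TestSimulator:
    def test_static_noise_free_repeats_identical(self, slab_phantom_factory,
                                                 slab_pattern_factory):
        ph = slab_phantom_factory(speed=0.0, noise=0.0)
        vol = simulate_repeat_bscans(ph, slab_pattern_factory())
        amp = vol.amplitude
        np.testing.assert_array_equal(amp[:, 0], amp[:, 1])
        np.testing.assert_array_equal(amp[:, 0], amp[:, 2])

    def test_same_seed_bit_identical(self, slab_phantom_factory,
                                     slab_pattern_factory):
        ph = slab_phantom_factory(speed=1.0, noise=0.03, seed=9)
        a = simulate_repeat_bscans(ph, slab_pattern_factory())
        b = simulate_repeat_bscans(ph, slab_pattern_factory())
        np.testing.assert_array_equal(a.amplitude, b.amplitude)

    def test_deep_saturation_reaches_rayleigh_plateau(
        self, slab_phantom_factory, slab_pattern_factory
    ):
        # v * tau / w = 10: field correlation effectively zero
        tau, w = 1.5, 4.0
        ph = slab_phantom_factory(speed=10 * w / tau, noise=0.0, w=w,
                                  grid=(60, 48, 24), depth_range=(50, 400))
        pat = slab_pattern_factory(tau=tau, grid=(60, 48, 24))
        vol = simulate_repeat_bscans(ph, pat)
        d = octa_bframe(vol.amplitude.astype(np.float64), repeat_axis=-3)
        vmask = ph.speed_map() > 0
        vals = np.moveaxis(d, 1, 0)[np.moveaxis(vmask, 1, 0)]
        oracle = analytic_decorr_oracle(0.0, 1_000_000, seed=2)
        se = np.std(vals) / np.sqrt(vals.size)
        assert np.mean(vals) == pytest.approx(
            oracle.mean, abs=3 * np.hypot(se, oracle.se)
        )

    def test_above_surface_is_noise_only(self, slab_phantom_factory,
                                         slab_pattern_factory):
        ph = slab_phantom_factory(speed=0.0, noise=0.0)
        vol = simulate_repeat_bscans(ph, slab_pattern_factory())
        assert np.all(vol.amplitude[:, :, :10, :] == 0)
        assert np.all(vol.amplitude[:, :, 10:, :] > 0)

    def test_repeats_below_two_rejected(self):
        with pytest.raises(PatternError):
            ScanPattern(16, 8, 1, 1.5)

    def test_depth_range_outside_grid_rejected(self, slab_phantom_factory,
                                               slab_pattern_factory):
        ph = slab_phantom_factory(depth_range=(50.0, 900.0))
        with pytest.raises(GeometryError):
            simulate_repeat_bscans(ph, slab_pattern_factory())

    def test_grid_pattern_mismatch_rejected(self, slab_phantom_factory):
        ph = slab_phantom_factory()
        with pytest.raises(GeometryError, match="scaled_to"):
            simulate_repeat_bscans(ph, ScanPattern(99, 7, 3, 1.5))


class TestCohort:
    def _null_cohort(self, cv=0.0, seed=0):
        return CohortSpec(
            groups=(
                GroupSpec("mild", 8, MILD_SCHEDULE),
                GroupSpec("moderate", 9, MILD_SCHEDULE),
            ),
            between_subject_cv=cv,
            seed=seed,
        )

    def test_group_sizes_yield_seventeen_subjects(self):
        ids = subject_ids(self._null_cohort())
        assert len(ids) == 17
        assert sum(1 for _, g in ids if g == "mild") == 8
        assert sum(1 for _, g in ids if g == "moderate") == 9

    def test_unit_schedule_zero_cv_matches_baseline_distribution(self, phantom):
        """All-1 multipliers with no intersubject spread: every non-
        ischemia acquisition shares the baseline's distributional
        parameters (identical true speeds)."""
        cohort = self._null_cohort(cv=0.0)
        pats = mini_patterns()[:1]
        volumes, truth = simulate_cohort(cohort, phantom, pats)
        sched = truth.schedule
        non_isch = sched[sched.time_point != "ischemia"]
        assert np.all(non_isch.subject_factor == 1.0)
        for (subj, layer), grp in non_isch.groupby(["subject", "layer"]):
            assert grp.true_speed_um_ms.nunique() == 1

    def test_ischemia_time_point_has_zero_flow(self, phantom):
        cohort = self._null_cohort(cv=0.1, seed=4)
        sched = simulate_cohort(cohort, phantom, mini_patterns()[:1])[1].schedule
        isch = sched[sched.time_point == "ischemia"]
        assert np.all(isch.multiplier == 0)
        assert np.all(isch.true_speed_um_ms == 0)

    def test_ischemia_multiplier_must_be_zero(self):
        bad = dict(MILD_SCHEDULE, ischemia=0.5)
        with pytest.raises(ValueError, match="ischemia"):
            CohortSpec(groups=(GroupSpec("g1", 4, bad), GroupSpec("g2", 4, bad)))

    def test_baseline_required(self):
        sched = {k: v for k, v in MILD_SCHEDULE.items() if k != "baseline"}
        with pytest.raises(ValueError):
            CohortSpec(
                groups=(GroupSpec("g", 4, sched),),
                time_points=tuple(sched),
            )

    def test_cohort_volumes_deterministic(self, phantom):
        cohort = self._null_cohort(cv=0.2, seed=21)
        pats = mini_patterns()[:1]
        va, _ = simulate_cohort(cohort, phantom, pats)
        vb, _ = simulate_cohort(cohort, phantom, pats)
        key = next(iter(va))
        np.testing.assert_array_equal(va[key].amplitude, vb[key].amplitude)
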