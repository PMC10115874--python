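"""Flow index, baseline normalization, time-course and outcome stats."""

import numpy as np
import pandas as pd
import pytest

from octaflow.exceptions import BaselineError
from octaflow.metrics import (
    CircularROI,
    flow_index,
    normalize_to_baseline,
    outcome_correlation,
    reperfusion_representative,
    timecourse_stats,
)


def brute_force_roi_sum(values, cy, cx, r):
    total = 0.0
    for y in range(values.shape[0]):
        for x in range(values.shape[1]):
            if (y - cy) ** 2 + (x - cx) ** 2 <= r * r:
                total += values[y, x]
    return total


class TestFlowIndex:
    def test_uniform_image_gives_value_times_pixel_count(self):
        roi = CircularROI(radius_px=5.0, radius_frac=None)
        count = int(roi.mask((32, 32)).sum())
        assert flow_index(np.full((32, 32), 0.25), roi) == pytest.approx(
            0.25 * count
        )

    def test_all_zero_image_gives_zero(self):
        assert flow_index(np.zeros((16, 16))) == 0.0

    def test_matches_brute_force_on_64x64(self, rng):
        values = rng.random((64, 64))
        roi = CircularROI(center=(30.0, 33.0), radius_px=17.5, radius_frac=None)
        expected = brute_force_roi_sum(values, 30.0, 33.0, 17.5)
        assert flow_index(values, roi) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_disjoint_rois_and_linear_in_scale(self, rng):
        values = rng.random((40, 40))
        left = CircularROI(center=(20.0, 10.0), radius_px=6, radius_frac=None)
        right = CircularROI(center=(20.0, 30.0), radius_px=6, radius_frac=None)
        both = left.mask((40, 40)) | right.mask((40, 40))
        assert flow_index(values, left) + flow_index(values, right) == (
            pytest.approx(values[both].sum())
        )
        assert flow_index(5 * values, left) == pytest.approx(
            5 * flow_index(values, left), rel=1e-12
        )

    def test_empty_roi_rejected(self):
        roi = CircularROI(center=(-50.0, -50.0), radius_px=2, radius_frac=None)
        with pytest.raises(ValueError, match="no pixels"):
            flow_index(np.ones((8, 8)), roi)

    def test_batched_images_return_vector(self, rng):
        values = rng.random((5, 16, 16))
        out = flow_index(values)
        assert out.shape == (5,)
        assert out[2] == pytest.approx(flow_index(values[2]))


def _records(subjects=("s1", "s2"), layers=("superficial",), f=lambda s, t, l: 1.0,
             times=("baseline", "ischemia", "45", "60"), group="g1"):
    return pd.DataFrame(
        [
            {"subject": s, "group": group, "time_point": t, "layer": l,
             "F": f(s, t, l)}
            for s in subjects for t in times for l in layers
        ]
    )


class TestNormalization:
    def test_baseline_gets_exactly_one_and_ratios_elsewhere(self):
        df = _records(f=lambda s, t, l: {"baseline": 4.0, "ischemia": 0.1,
                                         "45": 2.0, "60": 1.0}[t])
        out = normalize_to_baseline(df)
        by_tp = out.set_index(["subject", "time_point"])["F_hat"]
        assert by_tp[("s1", "baseline")] == 1.0
        assert by_tp[("s1", "45")] == 0.5
        assert by_tp[("s1", "ischemia")] == pytest.approx(0.025)

    def test_per_subject_gain_cancels(self, rng):
        base = _records(f=lambda s, t, l: {"baseline": 3.0, "ischemia": 0.2,
                                           "45": 1.5, "60": 2.4}[t])
        gains = {"s1": 1.0, "s2": 7.3}
        gained = base.assign(F=[r.F * gains[r.subject]
                                for r in base.itertuples()])
        np.testing.assert_allclose(
            normalize_to_baseline(base)["F_hat"],
            normalize_to_baseline(gained)["F_hat"],
            rtol=1e-12,
        )

    def test_missing_baseline_names_subject_and_layer(self):
        df = _records(times=("45", "60"))
        with pytest.raises(BaselineError, match="s1"):
            normalize_to_baseline(df)

    def test_zero_baseline_rejected(self):
        df = _records(f=lambda s, t, l: 0.0 if t == "baseline" else 1.0)
        with pytest.raises(BaselineError, match="not positive"):
            normalize_to_baseline(df)


class TestRepresentative:
    def test_mean_of_45_and_60(self):
        df = _records(f=lambda s, t, l: {"baseline": 1.0, "ischemia": 0.0,
                                         "45": 0.4, "60": 0.6}[t])
        rep = reperfusion_representative(normalize_to_baseline(df))
        np.testing.assert_allclose(rep["representative"], 0.5)

    def test_matches_recomputation_from_the_table(self, rng):
        df = _records(f=lambda s, t, l: float(rng.random() + 0.5))
        normed = normalize_to_baseline(df)
        rep = reperfusion_representative(normed).set_index(["subject", "layer"])
        for (s, l), row in rep.iterrows():
            manual = normed[
                (normed.subject == s) & (normed.layer == l)
                & normed.time_point.isin(["45", "60"])
            ]["F_hat"].mean()
            assert row["representative"] == pytest.approx(manual, rel=1e-12)

    def test_missing_time_point_rejected(self):
        df = _records(times=("baseline", "45"))
        with pytest.raises(ValueError, match="missing"):
            reperfusion_representative(normalize_to_baseline(df))


def _two_group_table(rng, effect=1.0, n1=5, n2=5,
                     times=("baseline", "15", "45", "60")):
    rows = []
    for g, n, mult in (("g1", n1, 1.0), ("g2", n2, effect)):
        for i in range(n):
            subj = f"{g}-{i}"
            for t in times:
                m = 1.0 if t == "baseline" else mult
                rows.append(
                    {"subject": subj, "group": g, "time_point": t,
                     "layer": "superficial",
                     "F": m * (1 + 0.05 * rng.standard_normal())}
                )
    return normalize_to_baseline(pd.DataFrame(rows))


class TestTimecourse:
    def test_degenerate_all_ones_give_p_one(self):
        df = _records(f=lambda s, t, l: 1.0)
        df = normalize_to_baseline(df)
        res = timecourse_stats(df)
        assert np.all(res.within["p_value"] == 1.0)
        assert not res.within["significant"].any()

    def test_baseline_comparison_omitted(self, rng):
        df = _two_group_table(rng)
        res = timecourse_stats(df)
        assert "baseline" not in set(res.within["time_point"])
        assert "baseline" not in set(res.between["time_point"])

    def test_strong_effect_detected_between_groups(self, rng):
        df = _two_group_table(rng, effect=0.3, n1=8, n2=9)
        res = timecourse_stats(df)
        post = res.between[res.between.time_point != "baseline"]
        assert post["significant"].all()

    def test_single_subject_group_rejected(self):
        df = _records(subjects=("only",))
        df = normalize_to_baseline(df)
        with pytest.raises(ValueError, match="fewer than 2"):
            timecourse_stats(df)

    def test_holm_correction_is_monotone_and_conservative(self, rng):
        df = _two_group_table(rng, effect=0.5)
        plain = timecourse_stats(df)
        holm = timecourse_stats(df, correction="holm")
        merged = plain.between.merge(
            holm.between[["layer", "time_point", "p_adjusted"]],
            on=["layer", "time_point"],
        )
        assert np.all(merged["p_adjusted"] >= merged["p_value"] - 1e-15)


class TestOutcomeCorrelation:
    def test_exact_linear_outcome_gives_r_squared_one(self):
        rep = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(6)],
             "layer": "superficial",
             "representative": np.linspace(0.2, 1.2, 6)}
        )
        out = pd.DataFrame(
            {"subject": rep.subject, "outcome": 3.0 - 2.0 * rep.representative}
        )
        res = outcome_correlation(rep, out)
        assert res.r_squared("superficial") == pytest.approx(1.0)
        row = res.table.iloc[0]
        assert row["slope"] == pytest.approx(-2.0)
        assert row["intercept"] == pytest.approx(3.0)

    def test_independent_outcome_gives_near_zero(self, rng):
        n = 400
        rep = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(n)], "layer": "deep",
             "representative": rng.random(n)}
        )
        out = pd.DataFrame({"subject": rep.subject,
                            "outcome": rng.standard_normal(n)})
        assert outcome_correlation(rep, out).r_squared("deep") < 0.05

    def test_zero_variance_outcome_warns_nan(self):
        rep = pd.DataFrame(
            {"subject": ["a", "b", "c"], "layer": "superficial",
             "representative": [0.1, 0.5, 0.9]}
        )
        out = pd.DataFrame({"subject": rep.subject, "outcome": 2.0})
        with pytest.warns(UserWarning, match="degenerate"):
            res = outcome_correlation(rep, out)
        assert np.isnan(res.r_squared("superficial"))

    def test_fewer_than_three_subjects_rejected(self):
        rep = pd.DataFrame(
            {"subject": ["a", "b"], "layer": "superficial",
             "representative": [0.1, 0.9]}
        )
        out = pd.DataFrame({"subject": ["a", "b"], "outcome": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 3"):
            outcome_correlation(rep, out)
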