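"""Cohort analyses linking looking style and preference."""

import numpy as np
import pandas as pd
import pytest

from lookmix import (
    conditional_means,
    delta_curve,
    independence_test,
    precedence_test,
    sampling_probability,
    trajectory_extrapolation,
    transition_probabilities,
    validate_cohort,
)


def make_cohort(rows):
    """rows: (infant_id, occasion, pi_hat, d_bar)"""
    df = pd.DataFrame(rows, columns=["infant_id", "occasion", "pi_hat", "d_bar"])
    return validate_cohort(df)


class TestTransitions:
    def test_direct_counting(self):
        cohort = make_cohort([
            ("a", 3, 0.2, -5), ("a", 6, 0.9, -5),
            ("b", 3, 0.1, -5), ("b", 6, 0.8, -5),
            ("c", 3, 0.3, -5), ("c", 6, 0.2, -5),
            ("d", 3, 0.9, -5), ("d", 6, 0.95, -5),
        ])
        t = transition_probabilities(cohort, (3, 6))
        assert t.probs[("LL", "SL")] == pytest.approx(2 / 3)
        assert t.probs[("SL", "SL")] == 1.0
        assert t.counts[("LL", "SL")] == 2 and t.n_earlier["LL"] == 3

    def test_zero_probability_with_nonzero_conditioning(self):
        cohort = make_cohort([
            ("a", 3, 0.9, 0), ("a", 6, 0.9, 0),
            ("b", 3, 0.8, 0), ("b", 6, 0.7, 0),
        ])
        t = transition_probabilities(cohort, (3, 6))
        assert t.probs[("SL", "LL")] == 0.0
        assert np.isnan(t.probs[("LL", "SL")])  # nobody was LL: undefined

    def test_rows_sum_to_one_given_support(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(40):
            rows.append((f"i{i}", 3, rng.uniform(), 0.0))
            rows.append((f"i{i}", 6, rng.uniform(), 0.0))
        t = transition_probabilities(make_cohort(rows), (3, 6))
        for y in ("SL", "LL"):
            if t.n_earlier[y]:
                assert t.probs[(y, "SL")] + t.probs[(y, "LL")] == pytest.approx(1.0)

    def test_recovers_generating_transition_matrix(self):
        # labels drawn with P(SL6|LL3)=0.87, P(SL6|SL3)=1
        rng = np.random.default_rng(10)
        n = 500
        rows = []
        for i in range(n):
            sl3 = rng.random() < 0.4
            sl6 = True if sl3 else rng.random() < 0.87
            rows.append((f"i{i}", 3, 0.9 if sl3 else 0.1, 0.0))
            rows.append((f"i{i}", 6, 0.9 if sl6 else 0.1, 0.0))
        t = transition_probabilities(make_cohort(rows), (3, 6))
        n_ll = t.n_earlier["LL"]
        se = np.sqrt(0.87 * 0.13 / n_ll)
        assert t.probs[("LL", "SL")] == pytest.approx(0.87, abs=3 * se)
        assert t.probs[("SL", "SL")] == 1.0

    def test_indeterminate_rows_excluded(self):
        cohort = make_cohort([
            ("a", 3, 0.5, 0), ("a", 6, 0.9, 0),
            ("b", 3, 0.4, 0), ("b", 6, 0.9, 0),
        ])
        t = transition_probabilities(cohort, (3, 6))
        assert t.n_excluded_indeterminate == 1
        assert t.n_infants == 1


class TestConditionalMeans:
    def test_group_means_are_plain_averages(self):
        cohort = make_cohort([
            ("a", 3, 0.9, 6.0), ("b", 3, 0.8, 7.0),
            ("c", 3, 0.2, -8.0), ("d", 3, 0.1, -9.0),
        ])
        m = conditional_means(cohort, 3)
        assert m.sl.mean == pytest.approx(6.5)
        assert m.ll.mean == pytest.approx(-8.5)
        assert m.unconditional.mean == pytest.approx(-1.0)

    def test_zero_variance_t_suppressed(self):
        cohort = make_cohort([(c, 3, 0.9, 1.0) for c in "abcd"])
        m = conditional_means(cohort, 3)
        assert m.sl.mean == 1.0 and m.sl.t is None

    def test_single_row_cell_reports_mean_only(self):
        cohort = make_cohort([
            ("a", 9, 0.9, -5.0), ("b", 9, 0.8, -7.0), ("c", 9, 0.2, -30.67),
        ])
        m = conditional_means(cohort, 9)
        assert m.ll.n == 1
        assert m.ll.mean == pytest.approx(-30.67)
        assert m.ll.t is None and m.welch_t is None

    def test_welch_with_one_degenerate_group(self):
        # {0,2,4,6,8} vs {1,1,1,1,1}: zero second variance collapses df to n1-1
        cohort = make_cohort(
            [(f"s{i}", 3, 0.9, v) for i, v in enumerate([0, 2, 4, 6, 8])]
            + [(f"l{i}", 3, 0.1, 1.0) for i in range(5)]
        )
        m = conditional_means(cohort, 3)
        assert m.welch_t == pytest.approx(3 / np.sqrt(2))
        assert m.welch_df == pytest.approx(4.0)


class TestDeltaCurve:
    def test_endpoints_equal_unconditional_mean_bit_exact(self, rng):
        rows = [(f"i{k}", 3, rng.uniform(), rng.uniform(-30, 30))
                for k in range(37)]
        cohort = make_cohort(rows)
        c = delta_curve(cohort, 3).table
        unconditional = float(cohort["d_bar"].to_numpy().mean())
        ge0 = c[(c.side == "ge") & (c.delta == 0.0)]["mean"].iloc[0]
        le1 = c[(c.side == "le") & (c.delta == 1.0)]["mean"].iloc[0]
        assert ge0 == unconditional and le1 == unconditional

    def test_monotone_relationship_preserved(self):
        rows = [(f"i{k}", 3, p, 10 * p) for k, p in enumerate(np.linspace(0, 1, 21))]
        c = delta_curve(make_cohort(rows), 3).table
        le = c[c.side == "le"].sort_values("delta")["mean"].to_numpy()
        assert np.all(np.diff(le) >= -1e-12)

    def test_empty_cells_flagged_not_fabricated(self):
        rows = [(f"i{k}", 3, 1.0, 5.0) for k in range(6)]
        c = delta_curve(make_cohort(rows), 3).table
        le = c[c.side == "le"].sort_values("delta")
        assert np.isnan(le[le.delta < 1.0]["mean"]).all()
        assert (le[le.delta < 1.0]["n"] == 0).all()
        ge = c[c.side == "ge"].sort_values("delta")["mean"].to_numpy()
        assert np.allclose(ge, 5.0)


class TestIndependence:
    def test_null_cohort_not_rejected(self):
        rng = np.random.default_rng(21)
        rows = [(f"i{k}", 3, rng.uniform(), rng.normal(0, 10))
                for k in range(200)]
        r = independence_test(make_cohort(rows), 3, B=999, seed=5)
        assert r.p_le > 0.05 and r.p_ge > 0.05

    def test_dependent_cohort_rejected(self):
        rng = np.random.default_rng(22)
        rows = [(f"i{k}", 3, p, 15 * (p - 0.5) + rng.normal(0, 2))
                for k, p in enumerate(rng.uniform(size=60))]
        r = independence_test(make_cohort(rows), 3, B=2000, seed=6)
        assert r.p_le < 0.01 and r.p_ge < 0.01
        assert r.slope_le > 0 and r.slope_ge > 0

    def test_constant_preference_has_zero_slope(self):
        rng = np.random.default_rng(23)
        rows = [(f"i{k}", 3, rng.uniform(), 4.0) for k in range(30)]
        r = independence_test(make_cohort(rows), 3, B=199, seed=0)
        assert r.slope_le == pytest.approx(0.0, abs=1e-12)
        assert r.slope_ge == pytest.approx(0.0, abs=1e-12)

    def test_too_few_rows_refused(self):
        rows = [(f"i{k}", 3, 0.5, 0.0) for k in range(5)]
        with pytest.raises(ValueError):
            independence_test(make_cohort(rows), 3, B=99, seed=0)


class TestPrecedence:
    def test_later_event_has_unit_conditional(self):
        # every ORP infant is SL; half the SL infants are not ORP
        rows = ([(f"o{i}", 6, 0.9, -5.0) for i in range(10)]
                + [(f"s{i}", 6, 0.9, 5.0) for i in range(10)])
        r = precedence_test(make_cohort(rows), 6, B=500, seed=0)
        assert r.p1 == 1.0 and r.p2 == 0.5

    def test_all_sl_and_orp(self):
        rows = [(f"i{k}", 6, 0.9, -4.0) for k in range(12)]
        r = precedence_test(make_cohort(rows), 6, B=200, seed=0)
        assert r.p1 == 1.0 and r.p2 == 1.0 and r.diff == 0.0

    def test_counting_identity_exact(self, rng):
        for _ in range(20):
            rows = [(f"i{k}", 6, rng.uniform(), rng.normal())
                    for k in range(rng.integers(10, 60))]
            try:
                r = precedence_test(make_cohort(rows), 6, B=100, seed=1)
            except ValueError:
                continue
            assert r.p1 * r.n_orp == pytest.approx(r.n_sl_orp, abs=1e-9)
            assert r.p2 * r.n_sl == pytest.approx(r.n_sl_orp, abs=1e-9)

    def test_month_six_like_structure_significant(self):
        rng = np.random.default_rng(30)
        rows = []
        for k in range(500):
            sl = rng.random() < 0.9
            orp = rng.random() < (0.64 if sl else 0.2)
            rows.append((f"i{k}", 6, 0.9 if sl else 0.1, -3.0 if orp else 3.0))
        r = precedence_test(make_cohort(rows), 6, B=2000, seed=7)
        assert r.p1 > r.p2
        assert r.p < 0.05

    def test_empty_conditioning_set_refused(self):
        rows = [(f"i{k}", 6, 0.9, 4.0) for k in range(8)]  # nobody ORP
        with pytest.raises(ValueError, match="ORP"):
            precedence_test(make_cohort(rows), 6, B=100, seed=0)


class TestTrajectory:
    def _cohort(self, trajs):
        rows = []
        for i, traj in enumerate(trajs):
            for occ, p in zip((3.0, 6.0, 9.0), traj):
                rows.append((f"i{i}", occ, p, 0.0))
        return make_cohort(rows)

    def test_flat_trajectory_predicts_itself(self):
        t = trajectory_extrapolation(self._cohort([(1.0, 1.0, 1.0)]), 0.25)
        assert t.predictions["prediction"].iloc[0] == 1.0

    def test_hand_computed_ols_clamped(self):
        t = trajectory_extrapolation(self._cohort([(0.0, 1.0, 1.0)]), 0.25)
        row = t.predictions.iloc[0]
        assert row["slope"] == pytest.approx(1 / 6)
        assert row["intercept"] == pytest.approx(-1 / 3)
        assert row["raw_prediction"] == pytest.approx(-1 / 3 + 0.25 / 6)
        assert row["prediction"] == 0.0

    def test_linear_rise_clamped_at_zero(self):
        t = trajectory_extrapolation(self._cohort([(0.2, 0.5, 0.8)]), 0.25)
        row = t.predictions.iloc[0]
        assert row["slope"] == pytest.approx(0.1)
        assert row["intercept"] == pytest.approx(-0.1)
        assert row["prediction"] == 0.0

    def test_incomplete_infants_excluded(self):
        cohort = self._cohort([(0.1, 0.5, 0.9)])
        extra = make_cohort([("only3", 3.0, 0.4, 0.0)])
        both = pd.concat([cohort, extra], ignore_index=True)
        t = trajectory_extrapolation(both, 0.25)
        assert t.n_included == 1 and t.n_excluded == 1

    def test_summary_proportion(self):
        t = trajectory_extrapolation(
            self._cohort([(1, 1, 1), (0, 0, 0), (0.9, 0.95, 1.0)]), 0.25)
        assert t.mean_prediction == pytest.approx((1.0 + 0.0 + 0.85) / 3, abs=0.02)
        assert t.proportion_sl == pytest.approx(2 / 3)


class TestSampling:
    def test_boundary_cases(self):
        assert sampling_probability(12, 0.0, 5) == 0.0
        assert sampling_probability(12, 0.7, 0) == 1.0

    def test_monotonicity(self):
        base = sampling_probability(12, 0.4, 5)
        assert sampling_probability(12, 0.4, 6) <= base
        assert sampling_probability(12, 0.4, 5, n_samples=2) <= base
        assert sampling_probability(12, 0.5, 5) >= base

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sampling_probability(12, 1.5, 5)
        with pytest.raises(ValueError):
            sampling_probability(12, 0.5, 13)
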