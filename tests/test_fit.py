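"""Estimation: EM layer, posterior layer, classification, bootstrap."""

import numpy as np
import pytest

from lookmix import (
    FittingError,
    LookingMixture,
    ParameterError,
    TrialSeries,
    bootstrap_fit,
    classify,
    fit_mixture,
    posterior_short,
    sample_trials,
)
from lookmix.fit import _run_em


def series(d, iid="t", occ=3.0):
    return TrialSeries(iid, occ, np.asarray(d, dtype=float))


class TestReferenceFits:
    def test_mixed_looker_worked_example(self, example_series):
        """The printed 24-trial series is a mixed looker with pi near 0.36."""
        res = fit_mixture(example_series)
        assert res.structure == "mixture"
        assert res.pi_hat == pytest.approx(0.36, abs=0.05)
        assert res.model.a == -130 and res.model.f == 130

    def test_boundary_clustered_series_is_pure_long(self, rng):
        """Scores only near +-130: the short component vanishes."""
        d = np.concatenate([rng.integers(-130, -118, 12),
                            rng.integers(118, 131, 12)])
        res = fit_mixture(series(d))
        assert res.pi_hat == 0.0
        assert res.structure == "long"

    def test_featureless_uniform_series_is_pure_short(self):
        """Draws from one flat uniform: the long bands vanish."""
        d = np.rint(np.random.default_rng(0).uniform(-50, 50, 24))
        res = fit_mixture(series(d))
        assert res.pi_hat == 1.0
        assert res.structure == "short"
        assert not res.bands_identified  # bands reported but non-identified

    def test_constant_series_degenerates_to_short(self):
        res = fit_mixture(series([0] * 10))
        assert res.pi_hat == 1.0
        assert res.degenerate
        assert np.isfinite(res.loglik)

    def test_one_sided_series_drops_missing_band(self):
        res = fit_mixture(series([3, 8, 15, 22, 40, 55, 70, 90, 110, 128]))
        assert res.model.b is None
        assert res.model.lam == 0.0

    def test_refuses_short_series(self):
        with pytest.raises(FittingError):
            fit_mixture(series([1, 2, 3]))


class TestEMProperties:
    def test_em_loglik_monotone(self, rng):
        """The EM trace never decreases, for random region configurations."""
        for _ in range(300):
            T = int(rng.integers(6, 40))
            n1 = int(rng.integers(0, T))
            n2 = int(rng.integers(0, T - n1))
            g = T - n1 - n2
            hs = 1 / rng.uniform(50, 261)
            hn = 1 / rng.uniform(2, 40)
            hp = 1 / rng.uniform(2, 40)
            *_, trace, _, _ = _run_em(n1, n2, g, hs, hn, hp,
                                      pi0=rng.uniform(0.05, 0.95),
                                      lam0=rng.uniform(0.05, 0.95),
                                      lam_free=True)
            assert np.all(np.diff(trace) >= -1e-9 * np.maximum(1, np.abs(trace[:-1])))

    def test_fit_trace_monotone_and_posterior_identity(self, rng):
        for _ in range(50):
            m = LookingMixture(a=-130, f=130, b=float(rng.integers(-125, -60)),
                               e=float(rng.integers(60, 125)),
                               lam=rng.uniform(0.2, 0.8), pi=rng.uniform())
            s = sample_trials(m, 24, seed=rng)
            res = fit_mixture(s)
            if res.loglik_trace.size:
                diffs = np.diff(res.loglik_trace)
                assert np.all(diffs >= -1e-9 * np.maximum(1, np.abs(res.loglik_trace[:-1])))
            assert res.pi_hat == pytest.approx(np.mean(res.posteriors), abs=1e-8)
            assert np.isfinite(res.loglik)

    def test_label_invariant_to_trial_order(self, rng, example_series):
        base = classify(fit_mixture(example_series).pi_hat).weak_label
        for _ in range(5):
            perm = rng.permutation(example_series.T)
            shuffled = series(example_series.d[perm], "2523")
            assert classify(fit_mixture(shuffled).pi_hat).weak_label == base

    def test_profile_ml_matches_brute_force_grid(self, rng):
        """EM layer reaches the exhaustive (b, e, pi, lam) grid optimum."""
        grid = np.linspace(0, 1, 201)
        for _ in range(8):
            m = LookingMixture(a=-130, f=130, b=-112.0, e=105.0,
                               lam=0.5, pi=rng.uniform(0.2, 0.8))
            s = sample_trials(m, 12, seed=rng)
            res = fit_mixture(s)
            best = brute_force_loglik(s.d, grid)
            assert res.loglik >= best - 1e-6


def brute_force_loglik(d, grid):
    """Independent oracle: direct mixture mass evaluation on a dense grid."""
    d = np.asarray(d, float)
    a, f = d.min(), d.max()
    best = -np.inf
    negs = np.unique(d[d < 0])
    poss = np.unique(d[d > 0])
    PI = grid[1:-1][:, None]  # avoid exact 0/1, where gap points break ll
    LAM = grid[None, :]
    for b in negs:
        for e in poss:
            in_nb = (d >= a) & (d <= b)
            in_pb = (d >= e) & (d <= f)
            mass = (PI[..., None] / (f - a + 1)
                    + (1 - PI[..., None]) * (LAM[..., None] * in_nb / (b - a + 1)
                                             + (1 - LAM[..., None]) * in_pb / (f - e + 1)))
            ll = np.where(np.all(mass > 0, axis=-1),
                          np.log(np.where(mass > 0, mass, 1.0)).sum(axis=-1),
                          -np.inf)
            best = max(best, float(ll.max()))
    return best


class TestPosteriorShort:
    def test_gap_points_are_certainly_short(self):
        m = LookingMixture(a=-130, f=130, b=-119, e=118, lam=0.5, pi=0.3)
        assert posterior_short(m, 0.0) == 1.0
        assert posterior_short(m, -50.0) == 1.0

    def test_no_short_mass_means_zero(self):
        m = LookingMixture(a=-130, f=130, b=-119, e=118, lam=0.5, pi=0.0)
        assert posterior_short(m, -125.0) == 0.0

    def test_hand_computed_band_posterior(self):
        m = LookingMixture(a=-130, f=130, b=-119, e=118, lam=0.5, pi=0.5)
        num = 0.5 / 260
        den = num + 0.5 * 0.5 / 11
        assert posterior_short(m, -120.0) == pytest.approx(num / den, abs=1e-4)
        assert posterior_short(m, -120.0) == pytest.approx(0.0779, abs=5e-4)

    def test_domain_checked(self):
        m = LookingMixture(a=-50, f=50, b=-40, e=40, lam=0.5, pi=0.5)
        with pytest.raises(ParameterError):
            posterior_short(m, 60.0)


class TestClassify:
    @pytest.mark.parametrize("pi,weak,strong", [
        (1.0, "SL", "SL"),
        (0.36, "LL", "neither"),
        (0.5, "indeterminate", "neither"),
        (0.0, "LL", "LL"),
        (0.51, "SL", "neither"),
    ])
    def test_weak_and_strong_criteria(self, pi, weak, strong):
        rec = classify(pi, "i", 3.0)
        assert (rec.weak_label, rec.strong_label) == (weak, strong)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            classify(1.5)


class TestBootstrap:
    def test_constant_data_has_zero_se(self):
        bs = bootstrap_fit(series([0] * 8), B=100, seed=0)
        assert bs.pi_se == 0.0
        assert bs.d_bar_se == 0.0

    def test_worked_example_interval_covers_point_estimate(self, example_series):
        bs = bootstrap_fit(example_series, B=1000, seed=42)
        assert bs.pi_se > 0
        assert bs.pi_ci[0] <= 0.36 <= bs.pi_ci[1]

    def test_pure_long_data_interval_floors_at_zero(self, rng):
        d = np.concatenate([rng.integers(-130, -120, 12),
                            rng.integers(120, 131, 12)])
        bs = bootstrap_fit(series(d), B=200, seed=1)
        assert bs.pi_ci[0] == 0.0

    def test_too_few_replicates_refused(self, example_series):
        with pytest.raises(FittingError):
            bootstrap_fit(example_series, B=50)


class TestRecoverySpotChecks:
    """Small-scale parameter recovery; the full study runs in acceptance."""

    def test_pure_short_truth_recovered(self, rng):
        m = LookingMixture(a=-130, f=130, b=-1.0, e=1.0, lam=0.5, pi=1.0)
        hits = 0
        for _ in range(20):
            res = fit_mixture(sample_trials(m, 24, seed=rng))
            hits += res.pi_hat == 1.0
        assert hits >= 18

    def test_pure_long_truth_recovered(self, rng):
        m = LookingMixture(a=-130, f=130, b=-118.0, e=118.0, lam=0.5, pi=0.0)
        for _ in range(20):
            res = fit_mixture(sample_trials(m, 24, seed=rng))
            assert res.pi_hat == 0.0
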