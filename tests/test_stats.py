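"""Macroecological statistics: frozen oracles and invariances."""

import numpy as np
import pytest

from crmacro.stats import (
    abundance_changes,
    fit_exponential_shape,
    fit_powerlaw_cutoff,
    pairwise_correlations,
    prevalence_and_rank,
    residence_return_times,
    restoring_slopes,
    richness,
    shuffle_times,
    summarize,
    taylor_fit,
)
from conftest import make_series


class TestRichness:
    def test_counts_entries_above_detection(self):
        x = np.array([[0.5, 0.5], [0.3, 5e-5], [2e-4, 0.4999], [0.1997, 0.0]])
        alpha_t, alpha_bar = richness(make_series(x))
        assert alpha_t.tolist() == [4, 2]
        assert alpha_bar == 3.0

    def test_empty_column_counts_zero(self):
        alpha_t, _ = richness(make_series([[1e-5], [5e-5]]))
        assert alpha_t.tolist() == [0]


class TestTaylor:
    def test_two_point_construction_has_slope_two(self):
        # taxon i takes values {0, 2 m_i}: mean m_i, var m_i^2 -> slope 2
        m = np.array([0.01, 0.02, 0.04, 0.08])
        x = np.column_stack([np.zeros(4), 2 * m])
        beta, intercept = taylor_fit(make_series(x))
        assert np.isclose(beta, 2.0, atol=1e-9)
        assert np.isclose(intercept, 0.0, atol=1e-9)

    def test_poisson_like_toy_has_slope_one(self, rng):
        lam = rng.uniform(5, 500, 40)
        counts = rng.poisson(lam, size=(200, 40)).T / 1e4
        beta, _ = taylor_fit(make_series(counts, detect=0.0))
        assert abs(beta - 1.0) < 0.1

    def test_matches_closed_form_ols(self, best_fit_series):
        beta, intercept = taylor_fit(best_fit_series)
        x = best_fit_series.thresholded
        mean, var = x.mean(axis=1), x.var(axis=1)
        ok = (mean > 0) & (var > 0)
        lx, ly = np.log10(mean[ok]), np.log10(var[ok])
        slope = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum(
            (lx - lx.mean()) ** 2
        )
        assert np.isclose(beta, slope, rtol=1e-10)

    def test_needs_two_variable_taxa(self):
        with pytest.raises(ValueError):
            taylor_fit(make_series([[0.5, 0.5], [0.5, 0.5]]))


class TestAbundanceChanges:
    def test_constant_series_has_zero_changes(self):
        dl, sigma_dl = abundance_changes(make_series([[0.4, 0.4, 0.4]]))
        assert np.allclose(dl, 0.0)
        assert sigma_dl == 0.0

    def test_decade_change_is_one(self):
        dl, _ = abundance_changes(make_series([[1e-3, 1e-2], [0.999, 0.99]]))
        assert np.isclose(dl[0], 1.0)

    def test_below_detection_endpoint_excluded(self):
        x = np.array([[0.5, 5e-5, 0.5], [0.5, 0.99995, 0.5]])
        dl, _ = abundance_changes(make_series(x))
        # taxon 0 contributes no pair; taxon 1 contributes both
        assert dl.size == 2


class TestLaplaceScale:
    def test_symmetric_two_point_pool(self):
        assert np.isclose(fit_exponential_shape(np.array([-0.3, 0.3])), 0.3)

    def test_zero_pool(self):
        assert fit_exponential_shape(np.zeros(5)) == 0.0

    def test_recovers_generated_scale(self, rng):
        sample = rng.laplace(0.0, 0.25, size=20000)
        assert abs(fit_exponential_shape(sample) - 0.25) < 0.01


class TestRestoringSlopes:
    def test_alternating_levels_give_slope_minus_two(self):
        # l alternates a, b: regression of dl on l is exactly -2
        x = np.array([[1e-3, 1e-2] * 8])
        s_i, s_bar = restoring_slopes(make_series(x), min_points=5)
        assert np.isclose(s_i[0], -2.0)
        assert np.isclose(s_bar, -2.0)

    def test_white_noise_levels_give_slope_minus_one(self, rng):
        # i.i.d. log-abundances: E[dl | l] = const - l
        x = 10 ** rng.normal(-2.0, 0.4, size=(30, 400))
        s_i, s_bar = restoring_slopes(make_series(x))
        assert abs(s_bar + 1.0) < 0.05

    def test_too_few_points_raises_when_no_taxon_eligible(self):
        x = np.array([[0.1, 0.2, 0.1, 0.2], [0.9, 0.8, 0.9, 0.8]])
        s_i, _ = restoring_slopes(make_series(x), min_points=3)
        assert not np.any(np.isnan(s_i))
        with pytest.raises(ValueError, match="presence pairs"):
            restoring_slopes(make_series(x), min_points=10)


class TestResidenceReturn:
    def test_hand_enumerated_runs(self):
        # presence 0,1,1,0,1 -> one completed residence of length 2;
        # the leading absence and trailing presence runs are censored
        x = np.array([[1e-5, 0.5, 0.5, 1e-5, 0.5]])
        t_res, t_ret = residence_return_times(make_series(x))
        assert t_res.tolist() == [2]
        assert t_ret.tolist() == [1]

    def test_always_present_contributes_nothing(self):
        x = np.full((1, 6), 0.5)
        t_res, t_ret = residence_return_times(make_series(x))
        assert t_res.size == 0 and t_ret.size == 0

    def test_alternating_presence_gives_unit_runs(self):
        x = np.array([[0.5 if t % 2 else 1e-5 for t in range(10)]])
        t_res, t_ret = residence_return_times(make_series(x))
        assert np.all(t_res == 1) and np.all(t_ret == 1)


class TestPowerlawCutoff:
    @staticmethod
    def draw(nu, tau, n, rng, t_max=400):
        t = np.arange(1, t_max + 1)
        p = t**nu * np.exp(-t / tau)
        return rng.choice(t, size=n, p=p / p.sum())

    def test_pure_exponential_special_case(self, rng):
        sample = self.draw(0.0, 5.0, 4000, rng)
        nu, tau = fit_powerlaw_cutoff(sample)
        assert abs(nu) < 0.15
        assert abs(tau - 5.0) < 1.0

    def test_recovers_powerlaw_with_cutoff(self, rng):
        sample = self.draw(-1.5, 20.0, 5000, rng)
        nu, tau = fit_powerlaw_cutoff(sample)
        assert abs(nu + 1.5) < 0.15
        assert abs(tau - 20.0) < 5.0

    def test_degenerate_sample_flagged(self):
        nu, tau = fit_powerlaw_cutoff(np.full(30, 4))
        assert np.isnan(nu) and np.isnan(tau)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match="intervals"):
            fit_powerlaw_cutoff(np.arange(1, 10))


class TestPrevalenceRank:
    def test_presence_fraction(self):
        x = np.array([[0.5] * 50 + [1e-5] * 50])
        p_i, mean_x, rank = prevalence_and_rank(make_series(x))
        assert p_i[0] == 0.5
        assert np.isclose(mean_x[0], 0.25)

    def test_never_detected_taxon(self):
        x = np.array([[0.9, 0.9], [1e-5, 1e-5]])
        p_i, mean_x, rank = prevalence_and_rank(make_series(x))
        assert p_i[1] == 0.0 and mean_x[1] == 0.0
        assert rank[-1] == 0.0

    def test_rank_is_sorted_permutation_of_means(self, best_fit_series):
        _, mean_x, rank = prevalence_and_rank(best_fit_series)
        assert np.array_equal(rank, np.sort(mean_x)[::-1])


class TestPairwiseCorrelations:
    def test_duplicated_taxon_correlates_perfectly(self, rng):
        row = rng.uniform(0.01, 0.5, 40)
        corr = pairwise_correlations(make_series(np.vstack([row, row])))
        assert np.allclose(corr, 1.0)

    def test_exact_anticorrelation(self, rng):
        row = rng.uniform(0.01, 0.4, 40)
        corr = pairwise_correlations(make_series(np.vstack([row, 0.9 - row])))
        assert np.allclose(corr, -1.0)

    def test_insufficient_shared_presence_skipped(self):
        x = np.array([[0.5] * 5 + [1e-5] * 5, [1e-5] * 5 + [0.5] * 5])
        assert pairwise_correlations(make_series(x)).size == 0


class TestShuffle:
    def test_order_free_statistics_invariant(self, best_fit_series, rng):
        shuffled = shuffle_times(best_fit_series, rng)
        assert richness(shuffled)[1] == richness(best_fit_series)[1]
        assert np.isclose(
            taylor_fit(shuffled)[0], taylor_fit(best_fit_series)[0], rtol=1e-12
        )

    def test_recorded_permutation_undoes_shuffle(self, best_fit_series, rng):
        shuffled = shuffle_times(best_fit_series, rng)
        perm = shuffled.meta["permutation"]
        inverse = np.argsort(perm)
        assert np.array_equal(shuffled.x[:, inverse], best_fit_series.x)


class TestSummarize:
    def test_bundle_is_consistent_with_parts(self, best_fit_series):
        s = summarize(best_fit_series)
        assert s.alpha_bar == richness(best_fit_series)[1]
        assert s.beta == taylor_fit(best_fit_series)[0]
        assert s.sigma_dl == abundance_changes(best_fit_series)[1]
        assert 0 < s.laplace_scale < s.sigma_dl  # Laplace MAD < SD
        doc = s.to_json_dict()
        assert isinstance(doc["alpha_t"], list)
        assert isinstance(doc["beta"], float)


class TestPowerlawBinned:
    def test_binned_alternative_agrees_roughly_with_mle(self, rng):
        t = np.arange(1, 400)
        p = t**-1.0 * np.exp(-t / 15.0)
        sample = rng.choice(t, size=8000, p=p / p.sum())
        nu_m, tau_m = fit_powerlaw_cutoff(sample, method="mle")
        nu_b, tau_b = fit_powerlaw_cutoff(sample, method="binned")
        assert abs(nu_b - nu_m) < 0.4
        assert 0.4 < tau_b / tau_m < 2.5
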