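"""Periodogram, rhythmicity scoring, anticipation and eduction checks
against hand arithmetic, a brute-force folding reference and the
generator's latent parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from crylight import locomotor, synth
from crylight.locomotor import (
    PeriodogramResult,
    RhythmicityCriteria,
    anticipation_index,
    chi_square_periodogram,
    classify_rhythmic,
    cohort_summary,
    eduction,
)
from conftest import make_series, with_locomotor


def brute_force_qp(x, p_bins):
    """Literal two-loop fold-and-compare reference for the periodogram
    statistic; deliberately free of the vectorised implementation."""
    n = len(x)
    k = n // p_bins
    retained = k * p_bins
    col_means = []
    for h in range(p_bins):
        tot = 0.0
        for c in range(k):
            tot += x[c * p_bins + h]
        col_means.append(tot / k)
    grand = sum(x[:retained]) / retained
    var = sum((x[i] - grand) ** 2 for i in range(retained)) / retained
    if var == 0:
        return 0.0
    return k * sum((m - grand) ** 2 for m in col_means) / var


class TestChiSquarePeriodogram:
    def test_hand_arithmetic_period_two_and_three(self):
        x = np.array([1, 3, 1, 3, 1, 3])
        grid = np.array([2 / 60, 3 / 60])  # 2- and 3-bin periods, in hours
        res = chi_square_periodogram(x, dd_only=False, period_grid_h=grid)
        assert res.qp[0] == pytest.approx(6.0)
        assert res.qp[1] == pytest.approx(0.0)
        assert res.chi2_threshold[0] == pytest.approx(3.8415, abs=1e-3)
        assert res.significant
        assert res.tau_h == pytest.approx(2 / 60)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(200, 2000))
            x = rng.poisson(2.0, n)
            p_bins = int(rng.integers(2, n // 2))
            res = chi_square_periodogram(
                x, dd_only=False, period_grid_h=np.array([p_bins / 60.0])
            )
            assert res.qp[0] == pytest.approx(
                brute_force_qp(x.tolist(), p_bins), rel=1e-9
            )

    def test_constant_series_flagged_degenerate_not_raised(self):
        res = chi_square_periodogram(
            np.full(4000, 5), dd_only=False,
            period_grid_h=np.array([24.0]),
        )
        assert res.degenerate_variance
        assert not res.significant
        assert res.tau_h is None

    def test_synthetic_tau_recovered_within_grid_step(self,
                                                      rhythmic_cohort):
        taus = []
        for s in rhythmic_cohort.series:
            res = chi_square_periodogram(s)
            rhythmic, _ = classify_rhythmic(res)
            if rhythmic:
                taus.append(res.tau_h)
        frac = np.mean([abs(t - 25.0) <= 0.1 for t in taus])
        assert len(taus) >= 27  # >= 90% of 30 rhythmic-preset flies
        assert frac >= 0.9

    def test_null_exceedance_controlled_at_alpha(self):
        # iid Poisson: the per-period exceedance of the chi2 line stays at
        # or below alpha (the folded-chi2 approximation is conservative
        # when few complete cycles fit in the record)
        rng = np.random.default_rng(5)
        hits, total = 0, 0
        for _ in range(30):
            x = rng.poisson(3.0, 4320)
            res = chi_square_periodogram(
                x, dd_only=False,
                period_grid_h=np.arange(16.0, 32.0, 0.5),
            )
            hits += int((res.qp > res.chi2_threshold).sum())
            total += res.periods_h.size
        rate = hits / total
        hi = sstats.binom.ppf(0.995, total, 0.05) / total
        assert 0.0 < rate <= hi

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 complete cycles"):
            chi_square_periodogram(np.ones(1000, dtype=int),
                                   dd_only=False)

    def test_dd_only_requires_dd_segment(self):
        s = make_series(np.ones(2 * 1440, dtype=int))
        with pytest.raises(ValueError, match="DD"):
            chi_square_periodogram(s, dd_only=True,
                                   period_grid_h=np.array([16.0]))


class TestClassification:
    def _result(self, significant, power, width):
        return PeriodogramResult(
            periods_h=np.array([24.0]), qp=np.array([100.0]),
            chi2_threshold=np.array([50.0]), alpha=0.05,
            significant=significant, tau_h=24.0 if significant else None,
            power=power, width_h=width,
        )

    def test_boundary_values_pass(self):
        rhythmic, failed = classify_rhythmic(
            self._result(True, 20.0, 2.0))
        assert rhythmic and failed == []

    def test_low_power_fails_power_criterion(self):
        rhythmic, failed = classify_rhythmic(
            self._result(True, 19.9, 5.0))
        assert not rhythmic and failed == ["power"]

    def test_insignificant_fails_regardless_of_power(self):
        rhythmic, failed = classify_rhythmic(
            self._result(False, 50.0, 5.0))
        assert not rhythmic and failed == ["significance"]

    def test_cohort_percent_and_means(self):
        results = [self._result(True, 30.0, 3.0)] * 3 \
            + [self._result(False, None, None)]
        cs = cohort_summary(results)
        assert cs.percent_rhythmic == pytest.approx(75.0)
        assert cs.n_rhythmic == 3
        assert cs.tau_mean == pytest.approx(24.0)

    def test_arrhythmic_preset_cohort_below_false_positive_bound(
            self, dm_preset):
        preset = with_locomotor(dm_preset, amplitude=0.0,
                                rhythmic_fraction=1.0)
        sim = synth.simulate_locomotor(preset, 20, 7, 7, seed=404)
        results = [chi_square_periodogram(s) for s in sim.series]
        cs = cohort_summary(results)
        assert cs.percent_rhythmic <= 10.0

    def test_rhythmic_cohort_tau_mean_near_generator(self,
                                                     rhythmic_cohort):
        results = [chi_square_periodogram(s)
                   for s in rhythmic_cohort.series]
        cs = cohort_summary(results)
        assert cs.tau_mean == pytest.approx(25.0, abs=0.2)


class TestAnticipation:
    def test_uniform_activity_is_exactly_one(self):
        s = make_series(np.ones(8 * 1440, dtype=int),
                        dd_start_bin=7 * 1440)
        for transition in ("morning", "evening"):
            res = anticipation_index(s, transition)
            assert res.ai == 1.0
            assert res.days_used == 5

    def test_all_activity_in_final_three_hours_is_two(self):
        counts = np.zeros(8 * 1440, dtype=int)
        for day in range(1, 8):
            t = day * 1440  # lights-on bins (series starts at ZT0)
            counts[t - 180:t] = 4
        s = make_series(counts, dd_start_bin=7 * 1440)
        assert anticipation_index(s, "morning").ai == 2.0

    def test_hourly_ramp_gives_ten_sevenths(self):
        counts = np.zeros(8 * 1440, dtype=int)
        for day in range(1, 8):
            t = day * 1440
            for h, v in enumerate([1, 2, 3, 4, 5, 6]):
                counts[t - 360 + h * 60: t - 300 + h * 60] = v
        s = make_series(counts, dd_start_bin=7 * 1440)
        assert anticipation_index(s, "morning").ai == \
            pytest.approx(10 / 7)

    def test_zero_activity_days_excluded_then_undefined(self):
        s = make_series(np.zeros(8 * 1440, dtype=int),
                        dd_start_bin=7 * 1440)
        res = anticipation_index(s, "morning")
        assert not res.defined
        assert res.ai is None and res.days_used == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_ai_always_in_unit_to_two_range(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(1.0, 8 * 1440)
        s = make_series(counts, dd_start_bin=7 * 1440)
        res = anticipation_index(s, "morning")
        if res.defined:
            assert 0.0 <= res.ai <= 2.0


class TestEductionActogram:
    def test_constant_series_flat_profile(self):
        s = make_series(np.full(3 * 1440, 2, dtype=int))
        np.testing.assert_array_equal(eduction(s), np.full(1440, 2.0))

    def test_single_day_returns_that_day(self):
        counts = np.arange(1440) % 7
        s = make_series(counts.astype(np.int64))
        np.testing.assert_array_equal(eduction(s), counts)

    def test_two_day_mean_matches_hand_computation(self):
        day1 = np.arange(1440) % 5
        day2 = 2 * day1
        s = make_series(np.concatenate([day1, day2]).astype(np.int64))
        np.testing.assert_allclose(eduction(s), 1.5 * day1)

    def test_partial_trailing_day_trimmed_with_warning(self):
        s = make_series(np.ones(1440 + 100, dtype=int))
        with pytest.warns(UserWarning, match="partial"):
            prof = eduction(s)
        np.testing.assert_array_equal(prof, np.ones(1440))

    def test_actogram_shapes(self):
        s = make_series(np.zeros(3 * 1440, dtype=int))
        assert locomotor.actogram_matrix(s).shape == (3, 1440)
        dbl = locomotor.actogram_matrix(s, double_plot=True)
        assert dbl.shape == (3, 2880)
        assert np.isnan(dbl[-1, 1440:]).all()
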