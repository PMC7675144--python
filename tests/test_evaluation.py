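"""Significance tests, equivalence analysis and response reliability."""

import numpy as np
import pytest

from audenc.datasets import random_ground_truth, simulate_neuron
from audenc.evaluation import (
    corrected_within_equivalence,
    effect_size,
    equivalence_partial_correlation,
    jackknife_improvement,
    permutation_significance,
    reliability,
    within_model_ceiling,
)
from audenc.fitting import FitConfig, _pearson, fit_model


class TestPermutationSignificance:
    def test_self_prediction_beats_all_shifts(self, rng):
        y = np.abs(rng.standard_normal(800)).cumsum() % 7  # aperiodic structure
        p = permutation_significance(y, y, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_prediction_returns_one(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            p = permutation_significance(np.full(400, 2.0), rng.standard_normal(400))
        assert p == 1.0

    def test_null_prediction_p_values_are_uniform(self, rng):
        """Oracle: empirical CDF of p over repeated independent predictions."""
        y = rng.standard_normal(300)
        ps = np.array([
            permutation_significance(rng.standard_normal(300), y, n_perm=99, seed=i)
            for i in range(120)
        ])
        # under the null, P(p <= q) ~ q; check at a few quantiles, loosely
        for q in (0.2, 0.5, 0.8):
            assert abs((ps <= q).mean() - q) < 0.15

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            permutation_significance(np.zeros(60), np.zeros(60))


class TestJackknifeImprovement:
    def test_identical_predictions_not_significant(self, rng):
        y = rng.standard_normal((5, 400))
        pred = rng.standard_normal(400)
        res = jackknife_improvement(pred, pred, y)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_reversal_flips_statistic(self, rng):
        sig = np.abs(rng.standard_normal(400)) * 3
        reps = sig[None, :] + rng.standard_normal((8, 400))
        a = sig + rng.standard_normal(400)
        b = rng.standard_normal(400)
        r1 = jackknife_improvement(a, b, reps)
        r2 = jackknife_improvement(b, a, reps)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.delta == pytest.approx(-r2.delta)

    def test_clear_improvement_is_significant(self, rng):
        """Oracle: large-sample z test on the same pseudo-values."""
        from scipy import stats
        sig = np.abs(rng.standard_normal(600)) * 4
        reps = sig[None, :] + 0.5 * rng.standard_normal((10, 600))
        good = sig + 0.2 * rng.standard_normal(600)
        bad = rng.standard_normal(600)
        res = jackknife_improvement(bad, good, reps)
        assert res.p_value < 1e-4 and res.delta > 0
        z_p = 2 * stats.norm.sf(abs(res.statistic))
        assert res.p_value == pytest.approx(z_p, rel=1.0, abs=0.01)

    def test_too_few_blocks_raises(self, rng):
        with pytest.raises(ValueError):
            jackknife_improvement(np.zeros(50), np.zeros(50),
                                  np.zeros((2, 50)), n_jack=1)


class TestEquivalencePartialCorrelation:
    def test_identical_deviations_give_one(self, rng):
        ln = rng.standard_normal(500).cumsum()
        res = np.sin(np.arange(500) / 9.0)
        assert equivalence_partial_correlation(ln + res, ln + res, ln) == pytest.approx(1.0)

    def test_orthogonal_deviations_give_zero(self, rng):
        ln = rng.standard_normal(1000)

        def orth(v, others):
            v = v - v.mean()
            for o in others:
                o = o - o.mean()
                v = v - (v @ o) / (o @ o) * o
            return v

        r1 = orth(rng.standard_normal(1000), [ln])
        r2 = orth(rng.standard_normal(1000), [ln, r1])
        val = equivalence_partial_correlation(ln + r1, ln + r2, ln)
        assert abs(val) < 1e-10

    def test_matches_regress_out_oracle(self, rng):
        """Oracle: correlate residuals after least-squares removal of the LN
        prediction."""
        ln = rng.standard_normal(400)
        a = 0.7 * ln + rng.standard_normal(400)
        b = -0.2 * ln + rng.standard_normal(400)

        def residual(v):
            vc, lc = v - v.mean(), ln - ln.mean()
            return vc - (vc @ lc) / (lc @ lc) * lc

        expected = _pearson(residual(a), residual(b))
        assert equivalence_partial_correlation(a, b, ln) == pytest.approx(expected)

    def test_symmetry_and_affine_invariance(self, rng):
        ln = rng.standard_normal(300)
        a = ln + rng.standard_normal(300)
        b = ln + rng.standard_normal(300)
        v1 = equivalence_partial_correlation(a, b, ln)
        assert equivalence_partial_correlation(b, a, ln) == pytest.approx(v1)
        assert equivalence_partial_correlation(3.0 * a - 1.0, 0.5 * b + 2.0, ln) == \
            pytest.approx(v1)

    def test_prediction_identical_to_ln_is_flagged(self, rng):
        ln = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="identical"):
            assert np.isnan(equivalence_partial_correlation(ln, ln + 1e-3, ln))


class TestCorrectedWithinEquivalence:
    def test_no_correction_needed(self):
        assert corrected_within_equivalence(0.5, 0.3, 0.3) == pytest.approx(0.5)

    def test_stated_arithmetic(self):
        assert corrected_within_equivalence(0.4, 0.3, 0.2) == pytest.approx(0.6)

    def test_ratio_invariance(self):
        assert corrected_within_equivalence(0.4, 0.6, 0.4) == \
            pytest.approx(corrected_within_equivalence(0.4, 0.3, 0.2))

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(corrected_within_equivalence(0.4, 0.3, 0.0))


class TestReliability:
    def test_identical_repetitions_give_one(self, rng):
        y = np.abs(rng.standard_normal(200))
        assert reliability(np.tile(y, (5, 1))).overall == pytest.approx(1.0)

    def test_equal_signal_and_noise_power_gives_half(self, rng):
        sig = np.abs(rng.standard_normal(1000)) * 3
        sd = np.sqrt(np.mean(sig ** 2))
        reps = sig[None, :] + sd * rng.standard_normal((60, 1000))
        assert reliability(reps).overall == pytest.approx(0.5, abs=0.03)

    def test_pure_noise_is_near_zero(self, rng):
        """Oracle: Monte-Carlo mean over independent draws."""
        vals = [reliability(rng.standard_normal((4, 150))).overall
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.02

    def test_monotone_in_noise(self, rng):
        sig = np.abs(rng.standard_normal(600)) * 3
        overall = [reliability(sig[None, :] + sd * rng.standard_normal((30, 600))).overall
                   for sd in (0.5, 2.0, 6.0)]
        assert overall[0] > overall[1] > overall[2]

    def test_overall_is_mean_of_per_stimulus(self, rng):
        stims = [rng.standard_normal((4, 100)) + 2 for _ in range(3)]
        res = reliability(stims)
        assert res.overall == pytest.approx(res.per_stimulus.mean())

    def test_zero_power_repetition_skipped(self, rng):
        y = np.abs(rng.standard_normal((3, 50))) + 0.5
        y[1] = 0.0
        res = reliability(y)
        assert res.n_skipped_reps == 1 and np.isfinite(res.overall)

    def test_single_repetition_raises(self):
        with pytest.raises(ValueError):
            reliability(np.ones((1, 10)))


class TestEffectSize:
    def test_all_equal_is_zero(self):
        assert effect_size(0.4, 0.4, 0.4) == 0.0

    def test_stated_arithmetic(self):
        assert effect_size(0.5, 0.7, 0.4) == pytest.approx(0.2)

    def test_shift_invariance(self):
        assert effect_size(0.5, 0.7, 0.4) == pytest.approx(effect_size(0.6, 0.8, 0.5))


class TestWithinModelCeiling:
    def test_deterministic_and_degrades_with_noise(self, small_bank):
        """Half-data within-model equivalence is reproducible and decreases
        as trial noise grows (noise ladder with fixed seeds)."""
        cfg = FitConfig(max_iter=250)
        w_halves = []
        for noise in (0.0, 1.0, 3.0):
            neuron = random_ground_truth("STP", seed=13, bank=small_bank,
                                         noise_model="gaussian" if noise else "none",
                                         noise_sd=noise * 5.0)
            resp = simulate_neuron(neuron, small_bank)
            est, val = resp.est_set(small_bank), resp.val_set(small_bank)
            ln = fit_model("LN", est, cfg)
            res = within_model_ceiling("STP", est, val, ln, config=cfg, seed=5)
            res2 = within_model_ceiling("STP", est, val, ln, config=cfg, seed=5)
            assert res.w_half == pytest.approx(res2.w_half, abs=1e-12)
            w_halves.append(res.w_half)
        assert w_halves[0] > w_halves[-1]
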