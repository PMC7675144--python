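"""Staged estimation: objective, gradients, schedule behavior and scoring."""

import numpy as np
import pytest

from audenc import models
from audenc.datasets import FitData, random_ground_truth, simulate_neuron
from audenc.fitting import (
    FitConfig,
    _initial_model,
    _loss_and_grad,
    _pack,
    _pearson,
    _unpack,
    fit_model,
    mse,
    noise_adjusted_correlation,
)
from audenc.models import predict


class TestMse:
    def test_exact_match_is_zero(self, rng):
        y = rng.standard_normal(50)
        assert mse(y, y) == 0.0

    def test_constant_offset(self, rng):
        y = rng.standard_normal(50)
        assert mse(y + 0.7, y) == pytest.approx(0.49)

    def test_matches_naive_loop(self, rng):
        a, b = rng.standard_normal(33), rng.standard_normal(33)
        expected = sum((x - y) ** 2 for x, y in zip(a, b)) / 33
        assert mse(a, b) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mse(np.zeros(3), np.zeros(4))


def test_analytic_gradient_matches_finite_differences(small_bank):
    """The fitting gradient (including backprop through the synaptic
    recursion and contrast modulation) agrees with central differences."""
    neuron = random_ground_truth("GC+STP", seed=3, bank=small_bank)
    resp = simulate_neuron(neuron, small_bank)
    est = resp.est_set(small_bank)
    m = _initial_model("GC+STP", est, FitConfig())
    groups = ["w", "h", "nl", "stp", "gc"]
    vec = _pack(m, groups)
    rng = np.random.default_rng(0)
    vec = vec + 0.03 * rng.standard_normal(vec.size) * np.maximum(np.abs(vec), 0.1)
    p = _unpack(vec, m, groups)
    p["tau"] = np.abs(p["tau"]) + 0.02
    p["u"] = np.clip(p["u"], -0.8, 0.8)

    levels = [s.levels for s in est.stimuli]
    Kraw = [models.contrast_index(models.compute_contrast(s)) for s in est.stimuli]
    ybar = est.mean_responses()

    def f(pp):
        return _loss_and_grad(pp, levels, Kraw, ybar, 0.01, m.gc.k_norm,
                              False, True, True)

    _, grads = f(p)
    flat = {"w": ("W", grads["w"].ravel()), "h": ("H", grads["h"].ravel()),
            "nl": ("nl", grads["nl"]), "gc": ("gc", grads["gc"])}
    checked = 0
    for g, (key, ga) in flat.items():
        arr = p[key].ravel()
        for i in rng.choice(arr.size, size=min(6, arr.size), replace=False):
            eps = 1e-6 * max(abs(arr[i]), 1e-2)
            hi = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in p.items()}
            hi[key] = p[key].copy().astype(float)
            hi[key].ravel()[i] += eps
            lo = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in p.items()}
            lo[key] = p[key].copy().astype(float)
            lo[key].ravel()[i] -= eps
            num = (f(hi)[0] - f(lo)[0]) / (2 * eps)
            assert ga[i] == pytest.approx(num, rel=1e-4, abs=1e-9)
            checked += 1
    # synaptic parameters
    for key, ga in (("u", grads["stp"][:3]), ("tau", grads["stp"][3:])):
        for i in range(3):
            eps = 1e-6 * max(abs(p[key][i]), 1e-2)
            hi = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in p.items()}
            hi[key] = p[key].copy(); hi[key][i] += eps
            lo = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in p.items()}
            lo[key] = p[key].copy(); lo[key][i] -= eps
            num = (f(hi)[0] - f(lo)[0]) / (2 * eps)
            assert ga[i] == pytest.approx(num, rel=1e-4, abs=1e-9)
    assert checked >= 20


class TestFitModel:
    def test_zero_iterations_returns_initial_parameters(self, small_bank, ln_response):
        est = ln_response.est_set(small_bank)
        cfg = FitConfig(max_iter=0)
        fitted = fit_model("LN", est, cfg)
        init = _initial_model("LN", est, cfg)
        assert np.array_equal(fitted.strf.spectral_weights,
                              init.strf.spectral_weights)
        assert fitted.nl == init.nl
        assert all(s["n_iter"] == 0 for s in fitted.meta["stage_losses"])

    def test_fit_is_deterministic(self, small_bank, ln_response):
        est = ln_response.est_set(small_bank)
        cfg = FitConfig(max_iter=40)
        a = fit_model("LN", est, cfg)
        b = fit_model("LN", est, cfg)
        assert a.to_dict() == b.to_dict()

    def test_stages_never_end_worse_than_they_start(self, small_bank):
        neuron = random_ground_truth("GC+STP", seed=31, bank=small_bank)
        resp = simulate_neuron(neuron, small_bank)
        fitted = fit_model("GC+STP", resp.est_set(small_bank), FitConfig(max_iter=120))
        for stage in fitted.meta["stage_losses"]:
            if stage.get("warm_start"):
                continue
            assert stage["loss_end"] <= stage["loss_start"] + 1e-12

    def test_recovers_noise_free_ln_simulation(self, small_bank, ln_response):
        est = ln_response.est_set(small_bank)
        val = ln_response.val_set(small_bank)
        fitted = fit_model("LN", est, FitConfig(max_iter=2500, fine_tol=1e-9))
        pred = np.concatenate([predict(fitted, s) for s in val.stimuli])
        ybar = np.concatenate([r.mean(axis=0) for r in val.responses])
        assert _pearson(pred, ybar) > 0.99

    def test_empty_estimation_data_raises(self):
        with pytest.raises(ValueError):
            fit_model("LN", FitData([], []))

    def test_unknown_architecture_raises(self, small_bank, ln_response):
        with pytest.raises(ValueError):
            fit_model("DNN", ln_response.est_set(small_bank))


class TestNoiseAdjustedCorrelation:
    def test_noise_free_perfect_prediction(self, rng):
        sig = np.abs(rng.standard_normal(300))
        reps = np.tile(sig, (6, 1))
        assert noise_adjusted_correlation(sig, reps) == pytest.approx(1.0)

    def test_zero_variance_prediction_flagged(self, rng):
        reps = rng.standard_normal((4, 100))
        with pytest.warns(UserWarning, match="zero-variance"):
            R, details = noise_adjusted_correlation(np.ones(100), reps,
                                                    return_details=True)
        assert R == 0.0 and details["degenerate"]

    def test_single_repetition_falls_back_to_raw(self, rng):
        sig = rng.standard_normal(200)
        with pytest.warns(UserWarning, match="single repetition"):
            R = noise_adjusted_correlation(sig, sig[None, :] * 0.5 + 1)
        assert R == pytest.approx(1.0)  # affine transform, raw Pearson

    def test_uncorrelated_prediction_is_near_zero(self, rng):
        reps = rng.standard_normal((8, 500)) + 2.0
        pred = rng.standard_normal(500)
        assert abs(noise_adjusted_correlation(pred, reps)) < 0.2

    def test_adjustment_raises_magnitude_when_ceiling_below_one(self, rng):
        sig = np.abs(rng.standard_normal(800)) * 4
        reps = sig[None, :] + 2.0 * rng.standard_normal((10, 800))
        pred = sig + rng.standard_normal(800)
        R, details = noise_adjusted_correlation(pred, reps, return_details=True)
        assert details["ceiling"] < 1.0
        assert R >= details["r_raw"]

    def test_converges_to_signal_correlation(self, rng):
        """Oracle: correlate the prediction with the stored noiseless signal."""
        sig = np.abs(rng.standard_normal(2000)) * 5
        noise_sd = np.sqrt(np.mean(sig ** 2))
        pred = sig + 0.6 * noise_sd * rng.standard_normal(2000)
        rho = _pearson(pred, sig)
        reps = sig[None, :] + noise_sd * rng.standard_normal((100, 2000))
        assert noise_adjusted_correlation(pred, reps) == pytest.approx(rho, abs=0.03)


def test_fit_config_file_roundtrip(tmp_path):
    cfg = FitConfig(max_iter=123, fine_tol=1e-8, stage_max_iter={"gc": 5})
    cfg.save(tmp_path / "fit.json")
    loaded = FitConfig.load(tmp_path / "fit.json")
    assert loaded == cfg
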