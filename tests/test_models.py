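"""Forward-model operations: filtering, nonlinearities, synaptic dynamics,
contrast, and the exact nesting relations between architectures."""

import numpy as np
import pytest

from audenc.models import (
    FittedModel,
    GcParams,
    NonlinearityParams,
    Spectrogram,
    StpParams,
    StrfParams,
    compute_contrast,
    contrast_index,
    double_exponential,
    linear_drive,
    modulated_nonlinearity,
    predict,
    stp_transform,
)


def _random_strf(rng, F=18, R=3, U=15):
    return StrfParams(rng.standard_normal((F, R)), rng.standard_normal((R, U)))


class TestLinearDrive:
    def test_zero_spectrogram_gives_zero_drive(self, rng):
        strf = _random_strf(rng)
        out = linear_drive(np.zeros((18, 40)), strf)
        assert np.allclose(out, 0.0)

    def test_impulse_reads_out_effective_filter(self, rng):
        strf = _random_strf(rng)
        spec = np.zeros((18, 30))
        f0, t0 = 5, 4
        spec[f0, t0] = 1.0
        out = linear_drive(spec, strf)
        h = strf.effective_filter()
        assert np.allclose(out[t0:t0 + 15], h[f0])
        assert np.allclose(out[:t0], 0.0)

    def test_factored_equals_full_filter_double_sum(self, rng):
        """Oracle: direct double sum over channels and lags of the expanded filter."""
        strf = _random_strf(rng)
        spec = rng.standard_normal((18, 60))
        h = strf.effective_filter()
        T, U = 60, 15
        expected = np.zeros(T)
        for t in range(T):
            for u in range(U):
                if t - u >= 0:
                    expected[t] += h[:, u] @ spec[:, t - u]
        assert np.allclose(linear_drive(spec, strf), expected)

    def test_channel_mismatch_raises(self, rng):
        strf = _random_strf(rng)
        with pytest.raises(ValueError, match="channels"):
            linear_drive(np.zeros((7, 10)), strf)


class TestDoubleExponential:
    def test_zero_amplitude_is_constant_baseline(self):
        p = NonlinearityParams(b=2.5, a=0.0, s=1.0, k=3.0)
        assert np.allclose(double_exponential(np.linspace(-5, 5, 50), p), 2.5)

    def test_value_at_offset(self):
        p = NonlinearityParams(b=1.0, a=10.0, s=0.3, k=2.0)
        assert double_exponential(np.array([0.3]), p)[0] == pytest.approx(
            1.0 + 10.0 * np.exp(-1.0))

    def test_strictly_increasing_for_positive_gain(self):
        p = NonlinearityParams(b=0.0, a=5.0, s=0.0, k=1.5)
        x = np.linspace(-4, 4, 400)
        y = double_exponential(x, p)
        assert np.all(np.diff(y) > 0)
        assert y.min() >= 0.0 and y.max() <= 5.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            NonlinearityParams(b=0.0, a=-1.0, s=0.0, k=1.0)


class TestStpTransform:
    def test_no_plasticity_is_identity(self, rng):
        sig = rng.standard_normal((3, 100))
        p = StpParams(u=np.zeros(3), tau=np.full(3, 0.1))
        assert np.array_equal(stp_transform(sig, p), sig)

    def test_zero_input_keeps_full_availability(self):
        p = StpParams(u=np.array([0.3]), tau=np.array([0.1]))
        out = stp_transform(np.zeros((1, 50)), p)
        assert np.allclose(out, 0.0)
        # with d(0)=1 and no input, d remains at its fixed point 1: a later
        # impulse is transmitted at full strength
        sig = np.zeros((1, 50))
        sig[0, 40] = 2.0
        out = stp_transform(sig, p)
        assert out[0, 40] == pytest.approx(2.0)

    def test_constant_drive_converges_to_algebraic_fixed_point(self):
        """Oracle: iterate the stated update to convergence and compare with
        d* = 1 / (1 + u*s*tau/bin)."""
        u, tau, sbar, bin_s = 0.25, 0.12, 1.7, 0.01
        p = StpParams(u=np.array([u]), tau=np.array([tau]))
        sig = np.full((1, 4000), sbar)
        out = stp_transform(sig, p, bin_s=bin_s)
        d_star = 1.0 / (1.0 + u * sbar * tau / bin_s)
        assert out[0, -1] / sbar == pytest.approx(d_star, abs=1e-6)
        # independent oracle: explicit iteration of the update rule
        d = 1.0
        for _ in range(4000):
            d = d - u * sbar * d + (1 - d) * bin_s / tau
        assert out[0, -1] / sbar == pytest.approx(d, abs=1e-9)

    def test_availability_bounds(self, rng):
        sig = 5.0 * np.abs(rng.standard_normal((3, 300)))
        p = StpParams(u=np.array([0.9, -0.9, 0.4]), tau=np.array([0.02, 0.02, 0.3]))
        out = stp_transform(sig, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(sig != 0, out / sig, 1.0)
        assert np.all(d >= -1e-12) and np.all(d <= 2.0 + 1e-12)

    def test_invalid_tau_raises(self):
        with pytest.raises(ValueError):
            StpParams(u=np.array([0.1]), tau=np.array([0.0]))


class TestContrast:
    def test_constant_spectrogram_has_zero_contrast(self):
        C = compute_contrast(np.full((4, 60), 3.0))
        assert np.allclose(C, 0.0)

    def test_window_contents_match_direct_enumeration(self, rng):
        """Oracle: gather the window bins explicitly and compute sigma/mu."""
        levels = np.abs(rng.standard_normal((5, 80))) + 0.5
        C = compute_contrast(levels, window_ms=70, offset_ms=20)
        win, off = 7, 2
        for t in (30, 50, 79):
            lo, hi = t - off - win + 1, t - off
            w = levels[:, lo:hi + 1]
            expect = w.std(axis=1) / w.mean(axis=1)
            assert np.allclose(C[:, t], expect)

    def test_early_bins_without_window_are_zero(self, rng):
        levels = np.abs(rng.standard_normal((3, 40))) + 0.5
        C = compute_contrast(levels)
        assert np.allclose(C[:, :3], 0.0)

    def test_window_not_multiple_of_bin_raises(self):
        with pytest.raises(ValueError):
            compute_contrast(np.ones((2, 50)), window_ms=73.0)

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            compute_contrast(np.ones((2, 50)), window_ms=10.0)

    def test_contrast_index_is_column_sum(self, rng):
        C = np.abs(rng.standard_normal((6, 30)))
        assert np.allclose(contrast_index(C), C.sum(axis=0))
        assert np.allclose(contrast_index(C, normalizer=2.0), C.sum(axis=0) / 2.0)
        single = np.zeros((6, 30))
        single[2] = C[2]
        assert np.allclose(contrast_index(single), C[2])


class TestModulatedNonlinearity:
    def setup_method(self):
        self.base = NonlinearityParams(b=1.0, a=20.0, s=0.5, k=2.0)
        self.gc = GcParams(b1=3.0, a1=10.0, s1=0.2, k1=0.8)

    def test_zero_modulation_matches_static(self, rng):
        x = rng.standard_normal(100)
        gc0 = GcParams(b1=1.0, a1=20.0, s1=0.5, k1=2.0)
        out = modulated_nonlinearity(x, rng.random(100), self.base, gc0)
        assert np.array_equal(out, double_exponential(x, self.base))

    def test_contrast_endpoints(self, rng):
        x = rng.standard_normal(50)
        low = modulated_nonlinearity(x, np.zeros(50), self.base, self.gc)
        assert np.array_equal(low, double_exponential(x, self.base))
        hi = modulated_nonlinearity(x, np.ones(50), self.base, self.gc)
        hi_static = double_exponential(x, NonlinearityParams(b=3.0, a=10.0, s=0.2, k=0.8))
        assert np.allclose(hi, hi_static)

    def test_misaligned_series_raise(self):
        with pytest.raises(ValueError):
            modulated_nonlinearity(np.zeros(10), np.zeros(11), self.base, self.gc)


class TestPredictNesting:
    def _ln_and_full(self, rng, centers):
        strf = _random_strf(rng)
        nl = NonlinearityParams(b=1.0, a=30.0, s=0.0, k=0.5)
        ln = FittedModel("LN", strf=strf, nl=nl)
        full = FittedModel(
            "GC+STP", strf=strf, nl=nl,
            stp=StpParams(u=np.zeros(3), tau=np.full(3, 0.1)),
            gc=GcParams(b1=nl.b, a1=nl.a, s1=nl.s, k1=nl.k, k_norm=1.3))
        return ln, full

    def test_double_nesting_is_bit_exact(self, rng, centers18):
        spec = Spectrogram(np.abs(rng.standard_normal((18, 120))), centers18)
        ln, full = self._ln_and_full(rng, centers18)
        assert np.array_equal(predict(full, spec), predict(ln, spec))

    def test_stp_only_nesting(self, rng, centers18):
        spec = Spectrogram(np.abs(rng.standard_normal((18, 100))), centers18)
        strf = _random_strf(rng)
        nl = NonlinearityParams(b=0.5, a=25.0, s=0.1, k=1.0)
        ln = FittedModel("LN", strf=strf, nl=nl)
        stp = FittedModel("STP", strf=strf, nl=nl,
                          stp=StpParams(u=np.zeros(3), tau=np.full(3, 0.2)))
        assert np.array_equal(predict(stp, spec), predict(ln, spec))

    def test_prediction_is_pure(self, rng, centers18):
        spec = Spectrogram(np.abs(rng.standard_normal((18, 80))), centers18)
        _, full = self._ln_and_full(rng, centers18)
        assert np.array_equal(predict(full, spec), predict(full, spec))

    def test_prediction_is_rectified(self, rng, centers18):
        spec = Spectrogram(np.abs(rng.standard_normal((18, 80))), centers18)
        strf = _random_strf(rng)
        nl = NonlinearityParams(b=-5.0, a=3.0, s=0.0, k=1.0)  # negative baseline
        out = predict(FittedModel("LN", strf=strf, nl=nl), spec)
        assert np.all(out >= 0.0)

    def test_architecture_parameter_mismatch_raises(self, rng):
        strf = _random_strf(rng)
        nl = NonlinearityParams(b=0.0, a=1.0, s=0.0, k=1.0)
        with pytest.raises(ValueError):
            FittedModel("STP", strf=strf, nl=nl)  # missing StpParams
        with pytest.raises(ValueError):
            FittedModel("LN", strf=strf, nl=nl,
                        stp=StpParams(u=np.zeros(3), tau=np.full(3, 0.1)))


def test_json_roundtrip_preserves_predictions(tmp_path, rng, centers18):
    spec = Spectrogram(np.abs(rng.standard_normal((18, 90))), centers18)
    strf = _random_strf(rng)
    nl = NonlinearityParams(b=1.0, a=20.0, s=0.2, k=1.1)
    model = FittedModel("GC+STP", strf=strf, nl=nl,
                        stp=StpParams(u=np.array([0.1, 0.2, -0.1]),
                                      tau=np.array([0.05, 0.1, 0.2])),
                        gc=GcParams(b1=2.0, a1=15.0, s1=0.2, k1=0.7, k_norm=1.5))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = FittedModel.load(path)
    assert np.array_equal(predict(loaded, spec), predict(model, spec))
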