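"""Synthetic stimulus banks and ground-truth model neurons.

Because no recorded data ship with the package, every downstream stage is
exercised on synthetic material:

* :func:`generate_stimulus_bank` builds banks of naturalistic
  log-spectrograms directly in spectrogram space -- sums of sparse
  spectro-temporal ridges plus smoothed-noise texture under a slow
  amplitude envelope.  Two contrast regimes are supported: a smooth
  continuum of per-stimulus contrast (natural-sound-like) and a bimodal
  clean/noisy design where "noisy" stimuli are mixed toward a flat
  broadband floor at equal power (a 0 dB SNR equivalent), which lowers
  their coefficient of variation.
* :func:`random_ground_truth` samples plausible parameters for any of the
  four architectures, calibrated so that the stimulus drive lands on the
  informative part of the output nonlinearity.
* :func:`simulate_neuron` runs the forward model and adds trial noise,
  splitting stimuli into a large low-repetition estimation set and a small
  high-repetition validation set (default 90% at 3 reps / 10% at 24 reps).

All randomness flows from one integer seed through a counter-based Philox
stream, so identical arguments always produce identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .models import (
    FittedModel,
    GcParams,
    NonlinearityParams,
    Spectrogram,
    StpParams,
    StrfParams,
    compute_contrast,
    contrast_index,
    predict,
    stp_transform,
    _temporal_filter,
)
from .spectrogram import gammatone_center_frequencies

__all__ = [
    "REGIMES",
    "StimulusBank",
    "GroundTruthNeuron",
    "NeuronResponse",
    "FitData",
    "generate_stimulus_bank",
    "random_ground_truth",
    "simulate_neuron",
    "generate_population",
]

REGIMES = ("smooth_contrast", "bimodal_clean_noisy")


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))


@dataclass
class StimulusBank:
    """A list of spectrogram stimuli with contrast-regime metadata."""

    stimuli: list
    regime: str
    labels: list
    sample_rate_hz: float = 100.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        chans = {s.n_channels for s in self.stimuli}
        bins = {s.bin_s for s in self.stimuli}
        if len(chans) > 1 or len(bins) > 1:
            raise ValueError("all stimuli in a bank must share channel count and bin size")
        if len(self.labels) != len(self.stimuli):
            raise ValueError("one label per stimulus is required")

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def n_channels(self) -> int:
        return self.stimuli[0].n_channels

    def summed_contrast(self) -> np.ndarray:
        """Per-stimulus mean frequency-summed contrast (bank-level statistic)."""
        return np.array([
            contrast_index(compute_contrast(s)).mean() for s in self.stimuli
        ])

    def save(self, path) -> None:
        """Write the bank as a columnar ``.npz`` plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {f"levels_{i}": s.levels for i, s in enumerate(self.stimuli)}
        arrays["channel_centers_hz"] = self.stimuli[0].channel_centers_hz
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"regime": self.regime, "labels": list(self.labels),
                "sample_rate_hz": self.sample_rate_hz, "seed": self.seed,
                "n_stimuli": len(self.stimuli),
                "bin_s": self.stimuli[0].bin_s}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "StimulusBank":
        import json
        from pathlib import Path

        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        with np.load(path.with_suffix(".npz")) as data:
            centers = data["channel_centers_hz"]
            stimuli = [Spectrogram(levels=data[f"levels_{i}"],
                                   channel_centers_hz=centers,
                                   bin_s=meta["bin_s"])
                       for i in range(meta["n_stimuli"])]
        return cls(stimuli=stimuli, regime=meta["regime"], labels=meta["labels"],
                   sample_rate_hz=meta["sample_rate_hz"], seed=meta["seed"])


@dataclass
class GroundTruthNeuron:
    """A known forward model plus a trial-noise specification."""

    architecture: str
    model: FittedModel
    noise_model: str = "none"  # none | gaussian | poisson
    noise_sd: float = 0.0      # spikes/s, for gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.architecture != self.model.architecture:
            raise ValueError("neuron architecture must match its model")


@dataclass
class FitData:
    """Stimulus/response pairs in the shape the fitting stage consumes."""

    stimuli: list
    responses: list  # one (reps, T) array per stimulus, spikes/s

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.responses):
            raise ValueError("one response matrix per stimulus is required")

    def mean_responses(self) -> list:
        return [r.mean(axis=0) for r in self.responses]


@dataclass
class NeuronResponse:
    """Trial-by-trial binned responses with estimation/validation split."""

    responses: list           # one (reps, T) array per stimulus
    est_indices: np.ndarray
    val_indices: np.ndarray
    noiseless: list           # forward-model prediction per stimulus
    bin_s: float = 0.01

    def est_set(self, bank: StimulusBank) -> FitData:
        return FitData([bank.stimuli[i] for i in self.est_indices],
                       [self.responses[i] for i in self.est_indices])

    def val_set(self, bank: StimulusBank) -> FitData:
        return FitData([bank.stimuli[i] for i in self.val_indices],
                       [self.responses[i] for i in self.val_indices])


# ---------------------------------------------------------------------------
# stimulus banks
# ---------------------------------------------------------------------------

def _clean_spectrogram(rng: np.random.Generator, n_channels: int, T: int,
                       depth: float) -> np.ndarray:
    """One naturalistic log-spectrogram: ridges + texture under a slow envelope."""
    # slow multiplicative amplitude envelope (~100 ms correlation length)
    env = np.exp(0.6 * gaussian_filter1d(rng.standard_normal(T), 10.0))
    env /= env.mean()
    # occasional quiet gaps, as in natural sound samples (pauses between
    # syllables/events); they exercise adaptation recovery and contrast swings
    n_gaps = rng.poisson(T / 150.0)
    for _ in range(n_gaps):
        g0 = int(rng.uniform(0, T))
        g1 = min(T, g0 + int(rng.uniform(15, 40)))
        env[g0:g1] *= 0.05
    # smooth gap edges as the cochlear envelope extraction would (~30 ms)
    env = gaussian_filter1d(env, 1.5)

    ridges = np.zeros((n_channels, T))
    faxis = np.arange(n_channels)[:, None]
    taxis = np.arange(T)[None, :]
    n_ridges = max(3, int(T / 20))
    for _ in range(n_ridges):
        fc = rng.uniform(0.5, n_channels - 1.5)
        tc = rng.uniform(0, T)
        dur = rng.uniform(6.0, 30.0)        # bins (60-300 ms)
        bw = rng.uniform(0.8, 2.5)          # channels
        amp = rng.uniform(2.0, 5.0)
        drift = rng.uniform(-0.05, 0.05)    # channels per bin
        f_center = fc + drift * (taxis - tc)
        ridges += amp * np.exp(-0.5 * ((taxis - tc) / (dur / 2.0)) ** 2
                               - 0.5 * ((faxis - f_center) / bw) ** 2)
    texture = np.abs(gaussian_filter(rng.standard_normal((n_channels, T)),
                                     sigma=(1.0, 3.0))) * 3.0
    # slowly varying sparse/diffuse mixture, independent of the envelope:
    # sparse AM-modulated ridges are high-contrast, steady diffuse texture is
    # low-contrast, so the contrast trajectory is decoupled from overall level
    mix = 0.5 + 0.35 * np.tanh(gaussian_filter1d(rng.standard_normal(T), 25.0) * 2.0)
    # fast amplitude modulation (tens of ms), prominent in natural sounds;
    # applied to the sparse component only so that loud-but-steady and
    # quiet-but-fluctuating segments both occur
    fast = np.exp(0.5 * gaussian_filter1d(rng.standard_normal(T), 2.0))
    fast /= fast.mean()
    fast_ch = np.exp(0.4 * gaussian_filter1d(rng.standard_normal((n_channels, T)),
                                             2.0, axis=1))
    fast_ch /= fast_ch.mean(axis=1, keepdims=True)
    levels = depth * env[None, :] * (
        2.0 * (1.0 - mix) * ridges * fast[None, :] * fast_ch
        + 2.0 * mix * texture) + 0.3
    return np.maximum(levels, 0.0)


def _add_broadband_floor(levels: np.ndarray, mix: float = 1.0) -> np.ndarray:
    """Mix a spectrogram toward a flat floor of equal mean power.

    Works in the linear-power domain implied by the log levels; ``mix = 1``
    adds noise power equal to the mean signal power (a 0 dB SNR
    equivalent), which raises the mean level and lowers the coefficient of
    variation.
    """
    p = 10.0 ** levels
    floor = mix * p.mean()
    return np.log10(p + floor)


def generate_stimulus_bank(regime: str, n_stimuli: int = 20, duration_s: float = 3.0,
                           n_channels: int = 18, seed: int = 0,
                           bin_s: float = 0.01) -> StimulusBank:
    """Generate a synthetic stimulus bank in one of two contrast regimes.

    ``smooth_contrast`` draws per-stimulus modulation depth and broadband
    mixing from continuous ranges, so per-stimulus contrast spans a smooth
    continuum.  ``bimodal_clean_noisy`` alternates clean (high-contrast)
    stimuli with noisy variants mixed toward a flat broadband floor at
    equal power, producing two labeled contrast clusters.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if n_stimuli < 2:
        raise ValueError("a bank needs at least 2 stimuli")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = _rng(seed)
    T = int(round(duration_s / bin_s))
    centers = gammatone_center_frequencies(max(n_channels, 2))[:n_channels]

    stimuli, labels = [], []
    for i in range(n_stimuli):
        if regime == "smooth_contrast":
            depth = rng.uniform(0.3, 1.0)
            mix = rng.uniform(0.0, 0.3)
            levels = _clean_spectrogram(rng, n_channels, T, depth)
            if mix > 0:
                levels = _add_broadband_floor(levels, mix)
            labels.append("n/a")
        else:
            depth = rng.uniform(0.7, 1.0)
            levels = _clean_spectrogram(rng, n_channels, T, depth)
            if i % 2 == 1:
                levels = _add_broadband_floor(levels, 1.0)
                labels.append("noisy")
            else:
                labels.append("clean")
        stimuli.append(Spectrogram(levels=levels, channel_centers_hz=centers, bin_s=bin_s))
    return StimulusBank(stimuli=stimuli, regime=regime, labels=labels, seed=seed)


# ---------------------------------------------------------------------------
# ground-truth neurons
# ---------------------------------------------------------------------------

def _gauss_bump(n: int, center: float, width: float) -> np.ndarray:
    x = np.arange(n)
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _sample_strf(rng: np.random.Generator, n_channels: int, rank: int = 3,
                 n_lags: int = 15) -> StrfParams:
    W = np.zeros((n_channels, rank))
    amps = [1.0, rng.uniform(-0.6, 0.6), rng.uniform(-0.4, 0.4)]
    for r in range(rank):
        center = rng.uniform(2.0, n_channels - 3.0)
        width = rng.uniform(1.0, 2.5)
        W[:, r] = amps[r % 3] * _gauss_bump(n_channels, center, width)
    u = np.arange(n_lags)
    H = np.zeros((rank, n_lags))
    for r in range(rank):
        peak = rng.uniform(1.0, 4.0)     # bins (10-40 ms latency)
        tail = rng.uniform(1.0, 3.0)
        h = (u / peak) * np.exp(1.0 - u / peak)
        h -= rng.uniform(0.0, 0.5) * (u / (peak + tail)) * np.exp(1.0 - u / (peak + tail))
        H[r] = h * (1.0 if r == 0 else rng.uniform(-1.0, 1.0))
    strf = StrfParams(W, H)
    norm = np.linalg.norm(strf.effective_filter())
    return StrfParams(W / np.sqrt(norm), H / np.sqrt(norm))


def random_ground_truth(architecture: str, seed: int, bank: Optional[StimulusBank] = None,
                        n_channels: int = 18, noise_model: str = "none",
                        noise_sd: float = 0.0) -> GroundTruthNeuron:
    """Sample a plausible ground-truth model of the given architecture.

    If a stimulus bank is supplied, the output nonlinearity's offset and
    gain (and the GC contrast normalizer) are calibrated against the
    drive statistics on that bank, which keeps simulated responses
    informative rather than floor- or saturation-dominated.
    """
    rng = _rng(seed)
    strf = _sample_strf(rng, n_channels)
    has_stp = architecture in ("STP", "GC+STP")
    has_gc = architecture in ("GC", "GC+STP")

    stp = None
    if has_stp:
        tau = rng.uniform(0.1, 0.3, size=strf.rank)
        # release fraction is per unit of input drive: calibrate u so the
        # per-bin depletion rate u*s sits in a slow-adaptation regime
        # (depression with dynamics over ~100 ms rather than quasi-static
        # saturation), matching the strongly modulated simulation sources
        rate = rng.uniform(0.08, 0.3, size=strf.rank)
        if bank is not None:
            drive = np.concatenate(
                [strf.spectral_weights.T @ s.levels for s in bank.stimuli], axis=1)
            s_bar = np.maximum(np.maximum(drive, 0.0).mean(axis=1), 1e-6)
            u = np.minimum(rate / s_bar, 0.95)
        else:
            u = rate
        stp = StpParams(u=u, tau=tau)

    # calibrate the nonlinearity on the drive distribution, STP included
    if bank is not None:
        drives = []
        for s in bank.stimuli:
            w = strf.spectral_weights.T @ s.levels
            if stp is not None:
                w = stp_transform(w, stp, bin_s=s.bin_s)
            drives.append(_temporal_filter(w, strf.temporal_filters))
        drive = np.concatenate(drives)
        s0 = float(np.median(drive))
        k0 = float(rng.uniform(1.0, 2.0) / max(np.std(drive), 1e-9))
    else:
        s0, k0 = 0.0, 1.0
    nl = NonlinearityParams(b=float(rng.uniform(0.0, 2.0)),
                            a=float(rng.uniform(20.0, 60.0)), s=s0, k=k0)

    gc = None
    if has_gc:
        if bank is not None:
            Ks = np.concatenate([contrast_index(compute_contrast(s)) for s in bank.stimuli])
            k_norm = float(max(np.percentile(Ks, 95), 1e-9))
            # deviations are capped so that even at the bank's maximum
            # contrast the interpolated gain/amplitude never invert sign
            margin = float(k_norm / max(Ks.max(), k_norm))
        else:
            k_norm, margin = None, 0.5
        gc = GcParams(
            b1=nl.b + float(rng.uniform(0.5, 2.0)),
            a1=nl.a * float(1.0 - rng.uniform(0.6, 0.95) * margin),
            s1=nl.s,
            k1=nl.k * float(1.0 - rng.uniform(0.7, 0.98) * margin),
            k_norm=k_norm,
        )
    model = FittedModel(architecture=architecture, strf=strf, nl=nl, stp=stp, gc=gc)
    return GroundTruthNeuron(architecture=architecture, model=model,
                             noise_model=noise_model, noise_sd=noise_sd,
                             seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_neuron(neuron: GroundTruthNeuron, bank: StimulusBank,
                    n_reps_est: int = 3, n_reps_val: int = 24,
                    val_fraction: float = 0.1) -> NeuronResponse:
    """Simulate trial-by-trial responses of a ground-truth neuron.

    The last ``val_fraction`` of the bank's stimuli (at least one) form the
    high-repetition validation set; the rest are the low-repetition
    estimation set.  The expected value of every repetition equals the
    forward-model prediction (Gaussian noise is not clipped; Poisson rates
    are clamped at zero with a warning if the prediction goes negative).
    """
    rng = _rng(neuron.seed)
    n = len(bank)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx = np.arange(n - n_val, n)
    est_idx = np.arange(0, n - n_val)

    preds = [predict(neuron.model, s) for s in bank.stimuli]
    responses = []
    for i, pred in enumerate(preds):
        reps = n_reps_val if i in val_idx else n_reps_est
        if neuron.noise_model == "none":
            resp = np.tile(pred, (reps, 1))
        elif neuron.noise_model == "gaussian":
            resp = pred[None, :] + neuron.noise_sd * rng.standard_normal((reps, pred.size))
        else:  # poisson
            rate = pred
            if np.any(rate < 0):
                warnings.warn("negative rates clamped to zero for Poisson noise")
                rate = np.maximum(rate, 0.0)
            resp = rng.poisson(rate[None, :] * bank.stimuli[i].bin_s,
                               size=(reps, rate.size)) / bank.stimuli[i].bin_s
        responses.append(np.asarray(resp, dtype=float))
    return NeuronResponse(responses=responses, est_indices=est_idx,
                          val_indices=val_idx, noiseless=preds,
                          bin_s=bank.stimuli[0].bin_s)


def generate_population(n_neurons: int, class_mixture: dict, bank: StimulusBank,
                        noise_levels: Sequence[float] = (0.5, 1.0), seed: int = 0,
                        n_reps_est: int = 3, n_reps_val: int = 24) -> list:
    """Generate a reproducible population of (neuron, response) pairs.

    ``class_mixture`` maps architecture names to fractions summing to 1;
    class counts use largest-remainder rounding and the assignment order is
    a seeded permutation.  ``noise_levels`` are Gaussian trial-noise SDs
    expressed as fractions of each neuron's signal RMS, cycled across
    neurons (use an empty mixture value of 0 noise via ``noise_levels=(0,)``
    for noise-free populations).
    """
    if not class_mixture:
        raise ValueError("class mixture must not be empty")
    fracs = np.array(list(class_mixture.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    if n_neurons == 0:
        return []
    classes = list(class_mixture.keys())
    counts = np.floor(fracs * n_neurons).astype(int)
    rem = np.argsort(-(fracs * n_neurons - counts))
    for j in range(n_neurons - counts.sum()):
        counts[rem[j % len(classes)]] += 1
    labels = np.repeat(classes, counts)
    rng = _rng(seed)
    labels = labels[rng.permutation(n_neurons)]

    population = []
    for i, arch in enumerate(labels):
        sub_seed = int(rng.integers(2 ** 31))
        neuron = random_ground_truth(arch, seed=sub_seed, bank=bank)
        level = noise_levels[i % len(noise_levels)] if len(noise_levels) else 0.0
        if level > 0:
            sig = np.concatenate([predict(neuron.model, s) for s in bank.stimuli])
            neuron.noise_model = "gaussian"
            neuron.noise_sd = float(level * np.sqrt(np.mean((sig - sig.mean()) ** 2)))
        resp = simulate_neuron(neuron, bank, n_reps_est=n_reps_est, n_reps_val=n_reps_val)
        population.append((neuron, resp))
    return population
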