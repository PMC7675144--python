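"""Forward encoding models for auditory cortical neurons.

Four composable architectures map a log-spectrogram to a predicted
peristimulus time histogram (PSTH, spikes/s at 100 Hz bins):

* ``LN``      -- rank-3 spectro-temporal filter followed by a static
  double-exponential output nonlinearity.
* ``STP``     -- the three spectrally weighted channels pass through
  virtual synapses with short-term depression/facilitation before the
  temporal filters.
* ``GC``      -- the output nonlinearity's parameters are modulated
  linearly by recent frequency-summed stimulus contrast.
* ``GC+STP``  -- both mechanisms together.

The architectures are strictly nested: setting all synaptic release
fractions ``u = 0`` and all high-contrast parameter endpoints equal to
their base values reduces every architecture to LN, bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ARCHITECTURES",
    "Spectrogram",
    "StrfParams",
    "NonlinearityParams",
    "StpParams",
    "GcParams",
    "FittedModel",
    "linear_drive",
    "double_exponential",
    "stp_transform",
    "compute_contrast",
    "contrast_index",
    "modulated_nonlinearity",
    "predict",
]

ARCHITECTURES = ("LN", "STP", "GC", "GC+STP")

#: exponent guard for exp(-exp(.)); +/-500 keeps exp() finite in float64
_EXP_CLIP = 500.0


@dataclass
class Spectrogram:
    """Log-compressed level in ``F`` frequency channels x ``T`` time bins.

    ``levels[f, t]`` is a non-negative dB-like quantity (0 = compression
    floor).  ``channel_centers_hz`` are the log-spaced filter centers and
    ``bin_s`` the temporal bin size (10 ms throughout).
    """

    levels: np.ndarray
    channel_centers_hz: np.ndarray
    bin_s: float = 0.01

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.channel_centers_hz = np.asarray(self.channel_centers_hz, dtype=float)
        if self.levels.ndim != 2:
            raise ValueError("levels must be a (channels, time) matrix")
        if self.levels.shape[0] != self.channel_centers_hz.size:
            raise ValueError("channel_centers_hz length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.levels.shape[0]

    @property
    def n_bins(self) -> int:
        return self.levels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_s


def _as_levels(spec) -> np.ndarray:
    return spec.levels if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)


@dataclass
class StrfParams:
    """Rank-factored spectro-temporal receptive field.

    The effective ``F x U`` filter is ``spectral_weights @ temporal_filters``
    with ``spectral_weights`` of shape ``(F, R)`` and ``temporal_filters`` of
    shape ``(R, U)`` (defaults R=3 ranks, U=15 lags of 10 ms).
    """

    spectral_weights: np.ndarray
    temporal_filters: np.ndarray

    def __post_init__(self) -> None:
        self.spectral_weights = np.asarray(self.spectral_weights, dtype=float)
        self.temporal_filters = np.asarray(self.temporal_filters, dtype=float)
        if self.spectral_weights.ndim != 2 or self.temporal_filters.ndim != 2:
            raise ValueError("STRF factors must be 2-D")
        if self.spectral_weights.shape[1] != self.temporal_filters.shape[0]:
            raise ValueError("rank mismatch between spectral and temporal factors")
        if not (np.isfinite(self.spectral_weights).all() and np.isfinite(self.temporal_filters).all()):
            raise ValueError("STRF parameters must be finite")

    @property
    def n_channels(self) -> int:
        return self.spectral_weights.shape[0]

    @property
    def rank(self) -> int:
        return self.spectral_weights.shape[1]

    @property
    def n_lags(self) -> int:
        return self.temporal_filters.shape[1]

    def effective_filter(self) -> np.ndarray:
        """Expand the factors into the full ``F x U`` filter ``h(f, u)``."""
        return self.spectral_weights @ self.temporal_filters


@dataclass
class NonlinearityParams:
    """Double-exponential output nonlinearity parameters.

    ``b`` baseline rate (spikes/s), ``a`` amplitude (spikes/s, >= 0),
    ``s`` input offset (drive units), ``k`` gain (1/drive unit).
    """

    b: float
    a: float
    s: float
    k: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("nonlinearity amplitude a must be non-negative")


@dataclass
class StpParams:
    """Per-synapse short-term plasticity parameters.

    ``u[i]`` is the fraction of available vesicles released per unit input
    (>0 depression, <0 facilitation); ``tau[i]`` the recovery time constant
    in seconds.  One synapse per STRF rank (three in this study).
    """

    u: np.ndarray
    tau: np.ndarray
    u_max: float = 1.0

    def __post_init__(self) -> None:
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.u.shape != self.tau.shape:
            raise ValueError("u and tau must have the same length")
        if np.any(self.tau <= 0):
            raise ValueError("recovery time constants tau must be positive")
        if np.any(np.abs(self.u) > self.u_max):
            raise ValueError(f"|u| must not exceed u_max={self.u_max}")


@dataclass
class GcParams:
    """Contrast gain-control parameters.

    Each output-nonlinearity parameter theta is replaced bin-wise by
    ``theta(t) = theta0 + (theta1 - theta0) * K(t)`` where ``K`` is the
    frequency-summed contrast index.  ``b1/a1/s1/k1`` are the high-contrast
    endpoints theta1 (the base values theta0 live in the model's static
    nonlinearity).  ``k_norm`` rescales raw K to unit 95th percentile on the
    dataset the model was calibrated on; ``k_clip``, when set, caps the
    normalized index at the calibrated range so the linear parameter map is
    never extrapolated on unseen stimuli.
    """

    b1: float
    a1: float
    s1: float
    k1: float
    window_ms: float = 70.0
    offset_ms: float = 20.0
    k_norm: Optional[float] = None
    k_clip: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.offset_ms <= 0:
            raise ValueError("contrast window length and offset must be positive")
        if self.a1 < 0:
            raise ValueError("high-contrast amplitude a1 must be non-negative")


@dataclass
class FittedModel:
    """An architecture tag plus all parameter groups it requires."""

    architecture: str
    strf: StrfParams
    nl: NonlinearityParams
    stp: Optional[StpParams] = None
    gc: Optional[GcParams] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        self.validate()

    @property
    def has_stp(self) -> bool:
        return self.architecture in ("STP", "GC+STP")

    @property
    def has_gc(self) -> bool:
        return self.architecture in ("GC", "GC+STP")

    def validate(self) -> None:
        if self.has_stp and self.stp is None:
            raise ValueError(f"{self.architecture} model requires StpParams")
        if self.has_gc and self.gc is None:
            raise ValueError(f"{self.architecture} model requires GcParams")
        if not self.has_stp and self.stp is not None:
            raise ValueError(f"{self.architecture} model must not carry StpParams")
        if not self.has_gc and self.gc is not None:
            raise ValueError(f"{self.architecture} model must not carry GcParams")
        if self.has_stp and self.stp.u.size != self.strf.rank:
            raise ValueError("one STP synapse per STRF rank is required")

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        doc = {
            "architecture": self.architecture,
            "strf": {
                "spectral_weights": self.strf.spectral_weights.tolist(),
                "temporal_filters": self.strf.temporal_filters.tolist(),
            },
            "nl": {"b": self.nl.b, "a": self.nl.a, "s": self.nl.s, "k": self.nl.k},
            "meta": self.meta,
        }
        if self.stp is not None:
            doc["stp"] = {"u": self.stp.u.tolist(), "tau": self.stp.tau.tolist()}
        if self.gc is not None:
            doc["gc"] = {
                "b1": self.gc.b1, "a1": self.gc.a1, "s1": self.gc.s1, "k1": self.gc.k1,
                "window_ms": self.gc.window_ms, "offset_ms": self.gc.offset_ms,
                "k_norm": self.gc.k_norm, "k_clip": self.gc.k_clip,
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedModel":
        stp = StpParams(**doc["stp"]) if "stp" in doc else None
        gc = GcParams(**doc["gc"]) if "gc" in doc else None
        return cls(
            architecture=doc["architecture"],
            strf=StrfParams(**doc["strf"]),
            nl=NonlinearityParams(**doc["nl"]),
            stp=stp,
            gc=gc,
            meta=doc.get("meta", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------

def linear_drive(spec, strf: StrfParams) -> np.ndarray:
    """Causal rank-factored FIR filtering of the spectrogram.

    Spectral weighting (``F x R`` matrix applied channel-wise) followed by
    causal convolution with the ``R x U`` temporal filters, summed over
    ranks.  Output has the same length as the input.
    """
    levels = _as_levels(spec)
    if levels.shape[0] != strf.n_channels:
        raise ValueError(
            f"spectrogram has {levels.shape[0]} channels, STRF expects {strf.n_channels}"
        )
    weighted = strf.spectral_weights.T @ levels  # (R, T)
    return _temporal_filter(weighted, strf.temporal_filters)


def _temporal_filter(weighted: np.ndarray, temporal_filters: np.ndarray) -> np.ndarray:
    T = weighted.shape[1]
    out = np.zeros(T)
    for r in range(temporal_filters.shape[0]):
        out += np.convolve(weighted[r], temporal_filters[r])[:T]
    return out


def double_exponential(x, p: NonlinearityParams) -> np.ndarray:
    """Static sigmoid ``y = b + a * exp(-exp(-k * (x - s)))``.

    Increasing in ``x`` for ``k > 0`` and bounded in ``[b, b + a]``.
    """
    return _dexp(np.asarray(x, dtype=float), p.b, p.a, p.s, p.k)


def _dexp(x, b, a, s, k):
    inner = np.clip(-k * (x - s), -_EXP_CLIP, _EXP_CLIP)
    return b + a * np.exp(-np.exp(inner))


def _stp_loop(sig, drive, u, tau_bins, out):  # pragma: no cover - numba variant used
    n, T = sig.shape
    for i in range(n):
        d = 1.0
        ui = u[i]
        inv_tau = 1.0 / tau_bins[i]
        for t in range(T):
            out[i, t] = d * sig[i, t]
            if ui >= 0.0:
                release = ui * drive[i, t] * d
            else:
                release = ui * drive[i, t] * (2.0 - d)
            d = d - release + (1.0 - d) * inv_tau
            if d < 0.0:
                d = 0.0
            elif d > 2.0:
                d = 2.0
    return out


def _stp_loop_save(sig, drive, u, tau_bins, out, d_save, clamped):
    """Forward recursion that also records the availability trajectory.

    ``d_save[i, t]`` is the availability used at bin ``t``; ``clamped[i, t]``
    marks updates whose result hit the [0, 2] clamp (their local derivative
    is zero).  Used by the fitting gradient.
    """
    n, T = sig.shape
    for i in range(n):
        d = 1.0
        ui = u[i]
        inv_tau = 1.0 / tau_bins[i]
        for t in range(T):
            d_save[i, t] = d
            out[i, t] = d * sig[i, t]
            if ui >= 0.0:
                release = ui * drive[i, t] * d
            else:
                release = ui * drive[i, t] * (2.0 - d)
            d_new = d - release + (1.0 - d) * inv_tau
            if d_new < 0.0:
                d_new = 0.0
                clamped[i, t] = True
            elif d_new > 2.0:
                d_new = 2.0
                clamped[i, t] = True
            else:
                clamped[i, t] = False
            d = d_new


def _stp_backward(sig, drive, u, tau_bins, d_save, clamped, grad_out,
                  grad_sig, grad_u, grad_tau_bins):
    """Reverse-mode accumulation through the availability recursion."""
    n, T = sig.shape
    for i in range(n):
        ui = u[i]
        inv_tau = 1.0 / tau_bins[i]
        lam = 0.0          # dL/dD[t+1], propagated backwards
        gu = 0.0
        gbeta = 0.0
        for t in range(T - 1, -1, -1):
            d = d_save[i, t]
            s_hat = drive[i, t]
            if ui >= 0.0:
                phi = d
                dphi = 1.0
            else:
                phi = 2.0 - d
                dphi = -1.0
            if clamped[i, t]:
                dd_dd = 0.0
                du_term = 0.0
                dbeta_term = 0.0
                ds_term = 0.0
            else:
                dd_dd = 1.0 - ui * s_hat * dphi - inv_tau
                du_term = -s_hat * phi
                dbeta_term = 1.0 - d
                ds_term = -ui * phi
            gu += lam * du_term
            gbeta += lam * dbeta_term
            gs = lam * ds_term
            g_d = grad_out[i, t] * sig[i, t] + lam * dd_dd
            grad_sig[i, t] = grad_out[i, t] * d
            if sig[i, t] > 0.0:
                grad_sig[i, t] += gs
            lam = g_d
        grad_u[i] = gu
        grad_tau_bins[i] = -gbeta * inv_tau * inv_tau


try:  # optional numba acceleration of the per-bin recursions
    from numba import njit

    _stp_loop_fast = njit(cache=True)(_stp_loop)
    _stp_loop_save_fast = njit(cache=True)(_stp_loop_save)
    _stp_backward_fast = njit(cache=True)(_stp_backward)
except Exception:  # pragma: no cover
    _stp_loop_fast = _stp_loop
    _stp_loop_save_fast = _stp_loop_save
    _stp_backward_fast = _stp_backward


def stp_transform(channel_signals: np.ndarray, p: StpParams, bin_s: float = 0.01) -> np.ndarray:
    """Scale each weighted channel by its synapse's available-vesicle fraction.

    Per synapse ``i`` the availability ``d_i`` starts at 1 and evolves as

    * depression  (``u > 0``): ``d <- d - u*s*d      + (1 - d) * bin_s/tau``
    * facilitation (``u < 0``): ``d <- d - u*s*(2-d) + (1 - d) * bin_s/tau``

    with ``d`` clamped to ``[0, 2]`` and the release drive ``s`` clamped at
    zero (vesicle release is defined for non-negative stimulation).  The
    output is ``sd_i(t) = d_i(t) * s_i(t)`` applied to the *unclamped*
    signal, so ``u = 0`` reproduces the input exactly.
    """
    sig = np.asarray(channel_signals, dtype=float)
    squeeze = sig.ndim == 1
    if squeeze:
        sig = sig[None, :]
    if sig.shape[0] != p.u.size:
        raise ValueError("one parameter pair per channel signal is required")
    drive = np.maximum(sig, 0.0)
    tau_bins = p.tau / bin_s
    out = np.empty_like(sig)
    _stp_loop_fast(sig, drive, p.u, tau_bins, out)
    return out[0] if squeeze else out


def compute_contrast(spec, window_ms: float = 70.0, offset_ms: float = 20.0) -> np.ndarray:
    """Per-channel rolling coefficient of variation of the spectrogram.

    ``C_f(t) = sigma_f / mu_f`` over the window of ``window_ms`` whose most
    recent bin lags ``offset_ms`` behind ``t`` (default: the 70 ms spanning
    20-90 ms before the current bin).  Bins whose window has fewer than two
    samples, or whose mean is below a small floor guard, get ``C = 0``.
    """
    levels = _as_levels(spec)
    bin_ms = (spec.bin_s if isinstance(spec, Spectrogram) else 0.01) * 1000.0
    win = int(round(window_ms / bin_ms))
    off = int(round(offset_ms / bin_ms))
    if abs(win * bin_ms - window_ms) > 1e-6 or abs(off * bin_ms - offset_ms) > 1e-6:
        raise ValueError("window and offset must be multiples of the bin size")
    if win < 2:
        raise ValueError("contrast window must span at least 2 bins")

    F, T = levels.shape
    # window for output bin t: input bins [t-off-win+1, t-off] inclusive
    cs1 = np.concatenate([np.zeros((F, 1)), np.cumsum(levels, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((F, 1)), np.cumsum(levels ** 2, axis=1)], axis=1)
    t = np.arange(T)
    hi = t - off            # last included bin
    lo = np.maximum(hi - win + 1, 0)
    n = hi - lo + 1         # window sample count (may be truncated at start)
    valid = (hi >= 1) & (n >= 2)
    hi_c = np.clip(hi, 0, T - 1)
    lo_c = np.clip(lo, 0, T - 1)
    s1 = cs1[:, hi_c + 1] - cs1[:, lo_c]
    s2 = cs2[:, hi_c + 1] - cs2[:, lo_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s1 / n
        var = np.maximum(s2 / n - mu ** 2, 0.0)
        C = np.sqrt(var) / mu
    C[~np.isfinite(C)] = 0.0
    C[:, ~valid] = 0.0
    C[mu <= 1e-9] = 0.0
    return C


def contrast_index(C: np.ndarray, normalizer: Optional[float] = None) -> np.ndarray:
    """Frequency-summed contrast ``K(t) = sum_f C_f(t)``, optionally rescaled."""
    K = np.asarray(C, dtype=float).sum(axis=0)
    if normalizer is not None:
        if normalizer <= 0:
            raise ValueError("contrast normalizer must be positive")
        K = K / normalizer
    return K


def modulated_nonlinearity(x, K, base: NonlinearityParams, gc: GcParams) -> np.ndarray:
    """Double exponential with contrast-modulated parameters.

    Each parameter follows ``theta(t) = theta0 + (theta1 - theta0) * K(t)``;
    with all endpoints equal to their base values the result is identical to
    the static nonlinearity.
    """
    x = np.asarray(x, dtype=float)
    K = np.asarray(K, dtype=float)
    if x.shape != K.shape:
        raise ValueError("drive and contrast index must be aligned in time")
    b = base.b + (gc.b1 - base.b) * K
    a = base.a + (gc.a1 - base.a) * K
    s = base.s + (gc.s1 - base.s) * K
    k = base.k + (gc.k1 - base.k) * K
    return _dexp(x, b, a, s, k)


def predict(model: FittedModel, spec) -> np.ndarray:
    """Forward prediction of the PSTH (spikes/s) for one stimulus.

    LN: STRF -> static nonlinearity.  STP: spectral weights -> synaptic
    scaling -> temporal filters -> static nonlinearity.  GC variants use the
    contrast-modulated nonlinearity instead.  The final rate is rectified at
    zero.
    """
    model.validate()
    levels = _as_levels(spec)
    if levels.shape[0] != model.strf.n_channels:
        raise ValueError(
            f"spectrogram has {levels.shape[0]} channels, model expects {model.strf.n_channels}"
        )
    bin_s = spec.bin_s if isinstance(spec, Spectrogram) else 0.01
    weighted = model.strf.spectral_weights.T @ levels
    if model.has_stp:
        weighted = stp_transform(weighted, model.stp, bin_s=bin_s)
    ylin = _temporal_filter(weighted, model.strf.temporal_filters)
    if model.has_gc:
        C = compute_contrast(spec, model.gc.window_ms, model.gc.offset_ms)
        K = contrast_index(C, model.gc.k_norm)
        if model.gc.k_norm is None:
            warnings.warn("GC model has no stored contrast normalizer; using raw K")
        if model.gc.k_clip is not None:
            K = np.minimum(K, model.gc.k_clip)
        y = modulated_nonlinearity(ylin, K, model.nl, model.gc)
    else:
        y = double_exponential(ylin, model.nl)
    return np.maximum(y, 0.0)
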