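"""Staged model estimation and prediction scoring.

Parameters are estimated by minimizing the mean-squared error between the
model prediction and the repetition-averaged response with bounded
L-BFGS-B, following a staged schedule that warms up nested submodels
before releasing all parameters:

1. linear STRF alone (coarse stopping),
2. output nonlinearity (+ STP where present) with the STRF fixed,
3. all LN (+ STP) parameters jointly (fine stopping),
4. GC (+ STP) parameters with the LN portion fixed,
5. everything jointly (fine stopping),

skipping stages a given architecture does not need.  A stage is never
allowed to end with a higher loss than it started with.

Prediction accuracy is scored by Pearson correlation between prediction
and trial-averaged response, adjusted for finite validation sampling by a
split-half / Spearman-Brown reliability ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from . import models
from .models import (
    FittedModel,
    GcParams,
    NonlinearityParams,
    StpParams,
    StrfParams,
    compute_contrast,
    contrast_index,
    stp_transform,
    _temporal_filter,
    _dexp,
)

__all__ = ["FitConfig", "FitError", "mse", "fit_model", "noise_adjusted_correlation"]


class FitError(RuntimeError):
    """Raised when optimization encounters a non-finite loss."""


@dataclass
class FitConfig:
    """Optimizer settings for the staged fit."""

    coarse_tol: float = 1e-4      # relative loss-change stop, warm-up stages
    fine_tol: float = 1e-7        # relative loss-change stop, joint stages
    max_iter: int = 1000          # iteration cap per stage
    stage_max_iter: dict = field(default_factory=dict)  # per-stage overrides
    tau_bounds: tuple = (0.01, 1.0)  # tau >= one bin keeps the update stable
    u_max: float = 1.0
    ridge: float = 1e-3           # relative ridge penalty for the STRF init
    rank: int = 3
    n_lags: int = 15
    seed: int = 0

    @classmethod
    def fast(cls, max_iter: int = 60) -> "FitConfig":
        """Desk-scale settings: same schedule, capped iterations."""
        return cls(fine_tol=1e-6, max_iter=max_iter)

    def to_dict(self) -> dict:
        return {
            "coarse_tol": self.coarse_tol, "fine_tol": self.fine_tol,
            "max_iter": self.max_iter, "stage_max_iter": dict(self.stage_max_iter),
            "tau_bounds": list(self.tau_bounds), "u_max": self.u_max,
            "ridge": self.ridge, "rank": self.rank, "n_lags": self.n_lags,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FitConfig":
        doc = dict(doc)
        doc["tau_bounds"] = tuple(doc.get("tau_bounds", (0.01, 1.0)))
        return cls(**doc)

    def save(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FitConfig":
        import json
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def mse(pred: np.ndarray, resp_mean: np.ndarray) -> float:
    """Mean of squared bin-wise differences."""
    pred = np.asarray(pred, dtype=float)
    resp_mean = np.asarray(resp_mean, dtype=float)
    if pred.shape != resp_mean.shape:
        raise ValueError("prediction and response must have equal length")
    return float(np.mean((pred - resp_mean) ** 2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _ridge_strf_init(levels_list, ybar_list, rank: int, n_lags: int,
                     ridge: float) -> StrfParams:
    """Full-filter ridge regression, truncated to the requested rank by SVD."""
    F = levels_list[0].shape[0]
    X_rows, y_rows = [], []
    for levels, ybar in zip(levels_list, ybar_list):
        T = levels.shape[1]
        X = np.zeros((T, F, n_lags))
        for u in range(n_lags):
            X[u:, :, u] = levels[:, : T - u].T
        X_rows.append(X.reshape(T, F * n_lags))
        y_rows.append(ybar)
    X = np.concatenate(X_rows)
    y = np.concatenate(y_rows)
    Xm = X.mean(axis=0)
    Xc = X - Xm
    yc = y - y.mean()
    XtX = Xc.T @ Xc
    lam = ridge * np.trace(XtX) / XtX.shape[0]
    beta = np.linalg.solve(XtX + lam * np.eye(XtX.shape[0]), Xc.T @ yc)
    h_full = beta.reshape(F, n_lags)
    U, S, Vt = np.linalg.svd(h_full, full_matrices=False)
    r = min(rank, S.size)
    W = np.zeros((F, rank))
    H = np.zeros((rank, n_lags))
    W[:, :r] = U[:, :r] * np.sqrt(S[:r])
    H[:r] = np.sqrt(S[:r])[:, None] * Vt[:r]
    return StrfParams(W, H)


def _normalize_factors(strf: StrfParams, levels_list) -> StrfParams:
    """Canonicalize the rank factorization without changing predictions.

    Flips each (spectral column, temporal row) pair so the weighted channel
    signal has a non-negative mean (synaptic release acts on positive
    drive), and rescales spectral columns to unit norm so the per-unit-input
    release fraction u is well conditioned.
    """
    W = strf.spectral_weights.copy()
    H = strf.temporal_filters.copy()
    mean_spectrum = np.mean([lv.mean(axis=1) for lv in levels_list], axis=0)
    for r in range(W.shape[1]):
        if W[:, r] @ mean_spectrum < 0:
            W[:, r] *= -1.0
            H[r] *= -1.0
        n = np.linalg.norm(W[:, r])
        if n > 1e-12:
            W[:, r] /= n
            H[r] *= n
    return StrfParams(W, H)


def _canonicalize(model: FittedModel, levels_list, bin_s: float) -> FittedModel:
    """Prediction-invariant reparameterization that fixes the model's gauge.

    The factored STRF and the output nonlinearity leave two exact
    degeneracies: the split of scale/sign between spectral and temporal
    factors, and the trade of overall filter scale against the
    nonlinearity's offset and gain.  Both flatten the loss landscape; this
    pins them (unit-norm spectral columns with positive mean drive, unit-SD
    linear drive with s, k rescaled to compensate) without changing any
    prediction.
    """
    strf = _normalize_factors(model.strf, levels_list)
    drives = []
    for levels in levels_list:
        w = strf.spectral_weights.T @ levels
        if model.stp is not None:
            w = _stp_raw(w, model.stp.u, model.stp.tau, bin_s)
        drives.append(_temporal_filter(w, strf.temporal_filters))
    c = float(np.std(np.concatenate(drives)))
    if not np.isfinite(c) or c < 1e-12:
        c = 1.0
    strf = StrfParams(strf.spectral_weights, strf.temporal_filters / c)
    nl = NonlinearityParams(b=model.nl.b, a=model.nl.a, s=model.nl.s / c,
                            k=model.nl.k * c)
    gc = None
    if model.gc is not None:
        gc = GcParams(b1=model.gc.b1, a1=model.gc.a1, s1=model.gc.s1 / c,
                      k1=model.gc.k1 * c, window_ms=model.gc.window_ms,
                      offset_ms=model.gc.offset_ms, k_norm=model.gc.k_norm,
                      k_clip=model.gc.k_clip)
    return FittedModel(architecture=model.architecture, strf=strf, nl=nl,
                       stp=model.stp, gc=gc, meta=model.meta)


def _initial_model(architecture: str, est, config: FitConfig) -> FittedModel:
    levels_list = [models._as_levels(s) for s in est.stimuli]
    ybar_list = est.mean_responses()
    strf = _ridge_strf_init(levels_list, ybar_list, config.rank, config.n_lags,
                            config.ridge)
    strf = _normalize_factors(strf, levels_list)
    has_stp = architecture in ("STP", "GC+STP")
    has_gc = architecture in ("GC", "GC+STP")
    stp = StpParams(u=np.full(config.rank, 0.05), tau=np.full(config.rank, 0.1),
                    u_max=config.u_max) if has_stp else None

    drives = []
    for levels, s in zip(levels_list, est.stimuli):
        w = strf.spectral_weights.T @ levels
        if stp is not None:
            w = stp_transform(w, stp, bin_s=s.bin_s)
        drives.append(_temporal_filter(w, strf.temporal_filters))
    drive = np.concatenate(drives)
    resp = np.concatenate(ybar_list)
    lo, hi = np.percentile(resp, [10, 90])
    nl = NonlinearityParams(
        b=float(lo),
        a=float(max(hi - lo, 1e-3)),
        s=float(np.median(drive)),
        k=float(1.0 / max(np.std(drive), 1e-9)),
    )
    gc = None
    if has_gc:
        Ks = np.concatenate([
            contrast_index(compute_contrast(s)) for s in est.stimuli
        ])
        # normalize to the estimation-range maximum: the parameter map is
        # linear in K, so the convention is absorbed exactly by the fitted
        # endpoints while keeping extrapolation on unseen stimuli small
        k_norm = float(max(Ks.max(), 1e-9))
        gc = GcParams(b1=nl.b, a1=nl.a, s1=nl.s, k1=nl.k, k_norm=k_norm)
    return FittedModel(architecture=architecture, strf=strf, nl=nl, stp=stp, gc=gc)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _pack(model: FittedModel, groups) -> np.ndarray:
    parts = []
    for g in groups:
        if g == "w":
            parts.append(model.strf.spectral_weights.ravel())
        elif g == "h":
            parts.append(model.strf.temporal_filters.ravel())
        elif g == "nl":
            parts.append(np.array([model.nl.b, model.nl.a, model.nl.s, model.nl.k]))
        elif g == "stp":
            parts.append(np.concatenate([model.stp.u, model.stp.tau]))
        elif g == "gc":
            parts.append(np.array([model.gc.b1, model.gc.a1, model.gc.s1, model.gc.k1]))
    return np.concatenate(parts)


def _unpack(vec: np.ndarray, model: FittedModel, groups) -> dict:
    """Return a plain-dict parameter view (cheap, no dataclass validation)."""
    p = {
        "W": model.strf.spectral_weights, "H": model.strf.temporal_filters,
        "nl": np.array([model.nl.b, model.nl.a, model.nl.s, model.nl.k]),
        "u": model.stp.u if model.stp is not None else None,
        "tau": model.stp.tau if model.stp is not None else None,
        "gc": (np.array([model.gc.b1, model.gc.a1, model.gc.s1, model.gc.k1])
               if model.gc is not None else None),
    }
    i = 0
    for g in groups:
        if g == "w":
            n = p["W"].size
            p["W"] = vec[i:i + n].reshape(p["W"].shape); i += n
        elif g == "h":
            n = p["H"].size
            p["H"] = vec[i:i + n].reshape(p["H"].shape); i += n
        elif g == "nl":
            p["nl"] = vec[i:i + 4]; i += 4
        elif g == "stp":
            n = p["u"].size
            p["u"] = vec[i:i + n]; p["tau"] = vec[i + n:i + 2 * n]; i += 2 * n
        elif g == "gc":
            p["gc"] = vec[i:i + 4]; i += 4
    return p


def _bounds(model: FittedModel, groups, config: FitConfig):
    bounds = []
    for g in groups:
        if g == "w":
            bounds += [(None, None)] * model.strf.spectral_weights.size
        elif g == "h":
            bounds += [(None, None)] * model.strf.temporal_filters.size
        elif g == "nl":
            bounds += [(None, None), (0.0, None), (None, None), (None, None)]
        elif g == "stp":
            n = model.stp.u.size
            bounds += [(-config.u_max, config.u_max)] * n
            bounds += [config.tau_bounds] * n
        elif g == "gc":
            bounds += [(None, None), (0.0, None), (None, None), (None, None)]
    return bounds


def _forward(p: dict, levels, Kraw, bin_s, arch, k_norm, linear_only=False):
    w = p["W"].T @ levels
    if p["u"] is not None and not linear_only:
        w = _stp_raw(w, p["u"], p["tau"], bin_s)
    ylin = _temporal_filter(w, p["H"])
    if linear_only:
        return ylin
    b, a, s, k = p["nl"]
    if p["gc"] is not None:
        K = Kraw / k_norm
        b1, a1, s1, k1 = p["gc"]
        y = _dexp(ylin, b + (b1 - b) * K, a + (a1 - a) * K,
                  s + (s1 - s) * K, k + (k1 - k) * K)
    else:
        y = _dexp(ylin, b, a, s, k)
    return np.maximum(y, 0.0)


def _stp_raw(w, u, tau, bin_s):
    p = StpParams(u=u, tau=np.maximum(tau, 1e-6), u_max=float("inf"))
    return stp_transform(w, p, bin_s=bin_s)


def _loss_and_grad(p: dict, levels_list, Kraw_list, ybar_list, bin_s, k_norm,
                   linear_only, use_stp, use_gc):
    """MSE over all estimation bins plus its exact gradient (reverse mode).

    The forward pass reproduces :func:`audenc.models.predict` operation for
    operation; the backward pass propagates through the output rectifier,
    the (possibly contrast-modulated) double exponential, the temporal
    convolution, the synaptic availability recursion (backprop through
    time) and the spectral weighting.
    """
    W, H = p["W"], p["H"]
    F, R = W.shape
    U = H.shape[1]
    N = sum(y.size for y in ybar_list)
    use_stp = use_stp and not linear_only

    gW = np.zeros_like(W)
    gH = np.zeros_like(H)
    gnl = np.zeros(4)
    ggc = np.zeros(4)
    gu = np.zeros(R)
    gtau = np.zeros(R)
    loss_sum = 0.0

    for levels, Kraw, ybar in zip(levels_list, Kraw_list, ybar_list):
        T = levels.shape[1]
        sig = W.T @ levels                      # (R, T)
        if use_stp:
            tau_bins = np.maximum(p["tau"], 1e-6) / bin_s
            drive = np.maximum(sig, 0.0)
            chan = np.empty_like(sig)
            d_save = np.empty_like(sig)
            clamped = np.zeros(sig.shape, dtype=np.bool_)
            models._stp_loop_save_fast(sig, drive, p["u"], tau_bins, chan,
                                       d_save, clamped)
        else:
            chan = sig
        ylin = _temporal_filter(chan, H)

        if linear_only:
            resid = ylin - ybar
            loss_sum += resid @ resid
            dLdx = 2.0 * resid / N
        else:
            b, a, s, k = p["nl"]
            if use_gc:
                K = Kraw / k_norm
                b1, a1, s1, k1 = p["gc"]
                bt = b + (b1 - b) * K
                at = a + (a1 - a) * K
                st = s + (s1 - s) * K
                kt = k + (k1 - k) * K
            else:
                bt, at, st, kt = b, a, s, k
            inner = np.clip(-kt * (ylin - st), -models._EXP_CLIP, models._EXP_CLIP)
            E = np.exp(-np.exp(inner))
            z = bt + at * E
            y = np.maximum(z, 0.0)
            resid = y - ybar
            loss_sum += resid @ resid
            r_eff = np.where(z > 0, 2.0 * resid / N, 0.0)
            # exp(inner) * E underflows to 0 for large inner well before the clip
            expgE = np.where(inner > 30.0, 0.0,
                             np.exp(np.minimum(inner, 30.0)) * E)
            gb_t = r_eff
            ga_t = r_eff * E
            gs_t = r_eff * (-at * kt * expgE)
            gk_t = r_eff * (at * (ylin - st) * expgE)
            dLdx = r_eff * (at * kt * expgE)
            if use_gc:
                gnl += np.array([(gb_t * (1 - K)).sum(), (ga_t * (1 - K)).sum(),
                                 (gs_t * (1 - K)).sum(), (gk_t * (1 - K)).sum()])
                ggc += np.array([(gb_t * K).sum(), (ga_t * K).sum(),
                                 (gs_t * K).sum(), (gk_t * K).sum()])
            else:
                gnl += np.array([gb_t.sum(), ga_t.sum(), gs_t.sum(), gk_t.sum()])

        # temporal convolution backward
        gchan = np.zeros_like(chan)
        for r_idx in range(R):
            h = H[r_idx]
            ch = chan[r_idx]
            for lag in range(U):
                if lag < T:
                    gH[r_idx, lag] += dLdx[lag:] @ ch[: T - lag]
                    gchan[r_idx, : T - lag] += dLdx[lag:] * h[lag]

        if use_stp:
            gsig = np.empty_like(sig)
            gu_i = np.empty(R)
            gtau_bins = np.empty(R)
            models._stp_backward_fast(sig, drive, p["u"], tau_bins, d_save,
                                      clamped, gchan, gsig, gu_i, gtau_bins)
            gu += gu_i
            gtau += gtau_bins / bin_s
            gW += levels @ gsig.T
        else:
            gW += levels @ gchan.T

    return loss_sum / N, {"w": gW, "h": gH, "nl": gnl, "stp": np.concatenate([gu, gtau]),
                          "gc": ggc}


def _stages_for(architecture: str):
    has_stp = architecture in ("STP", "GC+STP")
    has_gc = architecture in ("GC", "GC+STP")
    stages = [("strf", ["w", "h"], "coarse", True)]
    if has_stp:
        stages.append(("nl_stp", ["nl", "stp"], "coarse", False))
    else:
        stages.append(("nl", ["nl"], "coarse", False))
    ln_groups = ["w", "h", "nl"] + (["stp"] if has_stp else [])
    stages.append(("joint_ln", ln_groups, "fine", False))
    if has_gc:
        stages.append(("gc", ["gc"] + (["stp"] if has_stp else []), "coarse", False))
        stages.append(("all", ln_groups + ["gc"], "fine", False))
    return stages


def fit_model(architecture: str, est_data, config: Optional[FitConfig] = None,
              init_from: Optional[FittedModel] = None) -> FittedModel:
    """Estimate a model of the given architecture from estimation data.

    ``est_data`` is a :class:`~audenc.datasets.FitData` (stimuli plus
    repetition matrices); fitting targets the repetition-averaged response.
    ``init_from`` warm-starts the STRF and output nonlinearity from a
    previously fitted nested model (typically the LN fit), which keeps the
    nested solution reachable and reduces local minima.  The result carries
    per-stage losses in ``meta["stage_losses"]``.
    """
    if architecture not in models.ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if config is None:
        config = FitConfig()
    if len(est_data.stimuli) < 1:
        raise ValueError("estimation data needs at least one stimulus")

    model = _initial_model(architecture, est_data, config)
    warm = init_from is not None
    if warm:
        model = FittedModel(architecture=architecture,
                            strf=StrfParams(init_from.strf.spectral_weights.copy(),
                                            init_from.strf.temporal_filters.copy()),
                            nl=NonlinearityParams(init_from.nl.b, init_from.nl.a,
                                                  init_from.nl.s, init_from.nl.k),
                            stp=model.stp, gc=(model.gc if model.gc is None else
                                               GcParams(b1=init_from.nl.b,
                                                        a1=init_from.nl.a,
                                                        s1=init_from.nl.s,
                                                        k1=init_from.nl.k,
                                                        k_norm=model.gc.k_norm,
                                                        k_clip=model.gc.k_clip)),
                            meta=model.meta)
    levels_list = [models._as_levels(s) for s in est_data.stimuli]
    bin_s = getattr(est_data.stimuli[0], "bin_s", 0.01)
    ybar_list = est_data.mean_responses()
    if model.gc is not None:
        Kraw_list = [contrast_index(compute_contrast(s)) for s in est_data.stimuli]
        k_norm = model.gc.k_norm
    else:
        Kraw_list = [None] * len(levels_list)
        k_norm = None

    def params_of(m):
        return {"W": m.strf.spectral_weights, "H": m.strf.temporal_filters,
                "nl": np.array([m.nl.b, m.nl.a, m.nl.s, m.nl.k]),
                "u": m.stp.u if m.stp is not None else None,
                "tau": m.stp.tau if m.stp is not None else None,
                "gc": (np.array([m.gc.b1, m.gc.a1, m.gc.s1, m.gc.k1])
                       if m.gc is not None else None)}

    def loss_of(m, linear_only=False):
        loss, _ = _loss_and_grad(params_of(m), levels_list, Kraw_list, ybar_list,
                                 bin_s, k_norm, linear_only,
                                 m.stp is not None, m.gc is not None)
        return loss

    def rebuild(m, p):
        return FittedModel(
            architecture=architecture,
            strf=StrfParams(p["W"].copy(), p["H"].copy()),
            nl=NonlinearityParams(*[float(v) for v in p["nl"]]),
            stp=(StpParams(u=p["u"].copy(), tau=p["tau"].copy(), u_max=config.u_max)
                 if p["u"] is not None else None),
            gc=(GcParams(*[float(v) for v in p["gc"]],
                         window_ms=m.gc.window_ms, offset_ms=m.gc.offset_ms,
                         k_norm=k_norm, k_clip=m.gc.k_clip)
                if p["gc"] is not None else None),
            meta=m.meta,
        )

    def drive_of(m):
        out = []
        for levels in levels_list:
            w = m.strf.spectral_weights.T @ levels
            if m.stp is not None:
                w = _stp_raw(w, m.stp.u, m.stp.tau, bin_s)
            out.append(_temporal_filter(w, m.strf.temporal_filters))
        return np.concatenate(out)

    def percentile_nl(m):
        d = drive_of(m)
        resp = np.concatenate(ybar_list)
        lo, hi = np.percentile(resp, [10, 90])
        return NonlinearityParams(b=float(lo), a=float(max(hi - lo, 1e-3)),
                                  s=float(np.median(d)),
                                  k=float(1.0 / max(np.std(d), 1e-9)))

    def with_nl(m, nl, sync_gc):
        gc = m.gc
        if gc is not None and sync_gc:
            gc = GcParams(b1=nl.b, a1=nl.a, s1=nl.s, k1=nl.k,
                          window_ms=gc.window_ms, offset_ms=gc.offset_ms,
                          k_norm=gc.k_norm, k_clip=gc.k_clip)
        return FittedModel(architecture=architecture, strf=m.strf, nl=nl,
                           stp=m.stp, gc=gc, meta=m.meta)

    def prediction_flat(m):
        p = params_of(m)
        preds = [_forward(p, lv, Kr, bin_s, architecture, k_norm)
                 for lv, Kr in zip(levels_list, Kraw_list)]
        return float(np.ptp(np.concatenate(preds))) < 1e-9

    def optimize_stage(m, stage_name, groups, tol, linear_only, miter):
        """Run one stage (possibly in canonical-gauge rounds); never worse."""
        use_stp = m.stp is not None
        use_gc = m.gc is not None
        joint = "w" in groups and "h" in groups and not linear_only
        if joint and miter > 0:
            # re-canonicalize every few hundred iterations: the gauge drift
            # of the factored parameterization is what slows convergence
            per_round = min(250, miter)
            n_rounds = max(1, miter // per_round)
        else:
            n_rounds = 1
            per_round = miter if miter > 0 else 0
        state = {"n_eval": 0, "model": m}

        def objective(vec, _groups=groups):
            p = _unpack(vec, state["model"], _groups)
            loss, grads = _loss_and_grad(p, levels_list, Kraw_list, ybar_list,
                                         bin_s, k_norm, linear_only,
                                         use_stp, use_gc)
            state["n_eval"] += 1
            if not np.isfinite(loss):
                raise FitError(
                    f"non-finite loss in stage {stage_name!r} after "
                    f"{state['n_eval']} evaluations"
                )
            return loss, np.concatenate([np.ravel(grads[g]) for g in _groups])

        f_start = objective(_pack(m, groups))[0]
        f_prev = f_start
        n_iter = 0
        best_m, best_f = m, f_start
        for rnd in range(n_rounds):
            if per_round == 0:
                break
            state["model"] = m
            x0 = _pack(m, groups)
            f_round_start = objective(x0)[0]
            res = minimize(objective, x0, method="L-BFGS-B", jac=True,
                           bounds=_bounds(m, groups, config),
                           options={"maxiter": per_round, "ftol": tol,
                                    "maxfun": max(200 * per_round, 2000)})
            n_iter += int(res.nit)
            if np.isfinite(res.fun) and res.fun <= f_round_start:
                m = rebuild(m, _unpack(res.x, m, groups))
                f_now = float(res.fun)
            else:
                f_now = f_round_start
            if f_now <= best_f:
                best_m, best_f = m, f_now
            if joint and rnd < n_rounds - 1:
                m = _canonicalize(m, levels_list, bin_s)
            if f_prev - f_now <= tol * max(abs(f_prev), 1.0):
                break
            f_prev = f_now
        info = {"stage": stage_name,
                "objective": "linear" if linear_only else "full",
                "loss_start": float(f_start), "loss_end": float(best_f),
                "n_iter": n_iter}
        return best_m, info

    stage_losses = []
    candidates = None  # parallel stage-2 branches, resolved at the joint stage
    if warm:
        # gauge-fix the inherited parameters so the synaptic scale is right
        model = _canonicalize(model, levels_list, bin_s)
    for stage_name, groups, tol_kind, linear_only in _stages_for(architecture):
        tol = config.coarse_tol if tol_kind == "coarse" else config.fine_tol
        miter = config.stage_max_iter.get(stage_name, config.max_iter)
        if stage_name == "strf" and warm:
            # the STRF arrives already fitted from the nested warm start
            stage_losses.append({"stage": stage_name, "objective": "linear",
                                 "loss_start": None, "loss_end": None,
                                 "n_iter": 0, "warm_start": True})
            continue
        if stage_name in ("nl", "nl_stp") and miter > 0 and not warm:
            # the STRF changed in stage 1: move to the canonical gauge and
            # restart the nonlinearity from drive/response percentiles
            model = _canonicalize(model, levels_list, bin_s)
            model = with_nl(model, percentile_nl(model), sync_gc=True)
        if stage_name == "strf":
            model, info = optimize_stage(model, stage_name, groups, tol,
                                         linear_only, miter)
            if miter > 0:
                model = FittedModel(architecture=architecture,
                                    strf=_normalize_factors(model.strf, levels_list),
                                    nl=model.nl, stp=model.stp, gc=model.gc,
                                    meta=model.meta)
        elif stage_name == "nl_stp" and miter > 0:
            # two starts: plasticity engaged vs. effectively disabled; both
            # branches are carried into the joint stage, which keeps the
            # nested LN solution reachable when the synaptic basin is poor
            candidates = []
            for u0 in (model.stp.u, np.full_like(model.stp.u, 1e-3)):
                start = FittedModel(architecture=architecture, strf=model.strf,
                                    nl=model.nl,
                                    stp=StpParams(u=u0.copy(), tau=model.stp.tau.copy(),
                                                  u_max=config.u_max),
                                    gc=model.gc, meta=model.meta)
                candidates.append(optimize_stage(start, stage_name, groups, tol,
                                                 linear_only, miter))
            model, info = min(candidates, key=lambda c: c[1]["loss_end"])
        elif stage_name == "joint_ln" and candidates is not None and miter > 0:
            sub = max(1, miter // len(candidates))
            runs = [optimize_stage(c[0], stage_name, groups, tol, linear_only, sub)
                    for c in candidates]
            model, info = min(runs, key=lambda r: r[1]["loss_end"])
            candidates = None
        else:
            model, info = optimize_stage(model, stage_name, groups, tol,
                                         linear_only, miter)
            if miter > 0 and prediction_flat(model):
                # dead saturated nonlinearity: restart it and rerun the stage
                retry = with_nl(model, percentile_nl(model),
                                sync_gc="gc" in groups)
                retry, info2 = optimize_stage(retry, stage_name, groups, tol,
                                              linear_only, miter)
                if info2["loss_end"] <= info["loss_end"] and not prediction_flat(retry):
                    model, info = retry, info2
                    info["restarted"] = True
        stage_losses.append(info)

    model.meta = {
        "stage_losses": stage_losses,
        "seed": config.seed,
        "final_mse": stage_losses[-1]["loss_end"],
    }
    return model


# ---------------------------------------------------------------------------
# noise-adjusted correlation
# ---------------------------------------------------------------------------

def noise_adjusted_correlation(pred: np.ndarray, resp_reps: np.ndarray,
                               n_splits: int = 10, seed: int = 0,
                               return_details: bool = False):
    """Prediction correlation corrected for finite validation sampling.

    The raw Pearson correlation between ``pred`` and the repetition mean is
    divided by a reliability ceiling: the expected split-half correlation
    of the response (averaged over seeded random half-partitions of the
    repetitions) is mapped through the Spearman-Brown relation to the
    reliability of the full-repetition mean, and the ceiling is its square
    root.  The result is clipped to ``[-1, 1]``.  Falls back to the raw
    correlation (with a warning) for a single repetition or a non-positive
    split-half estimate.
    """
    pred = np.asarray(pred, dtype=float)
    resp_reps = np.atleast_2d(np.asarray(resp_reps, dtype=float))
    m, T = resp_reps.shape
    if pred.size != T:
        raise ValueError("prediction and responses must have equal length")
    details = {"degenerate": False, "ceiling": 1.0, "r_raw": 0.0, "r_half": None}

    if np.ptp(pred) == 0:
        details["degenerate"] = True
        warnings.warn("zero-variance prediction; returning 0")
        return (0.0, details) if return_details else 0.0

    ybar = resp_reps.mean(axis=0)
    r_raw = _pearson(pred, ybar)
    details["r_raw"] = r_raw
    if m < 2:
        warnings.warn("single repetition: returning raw Pearson correlation")
        return (r_raw, details) if return_details else r_raw

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    half = m // 2
    r_halves = []
    n_iter = 1 if m == 2 else n_splits
    for _ in range(n_iter):
        perm = rng.permutation(m)
        r_halves.append(_pearson(resp_reps[perm[:half]].mean(axis=0),
                                 resp_reps[perm[half:]].mean(axis=0)))
    r_half = float(np.clip(np.mean(r_halves), -1.0, 1.0))
    details["r_half"] = r_half
    if r_half <= 0:
        warnings.warn("non-positive split-half reliability; returning raw correlation")
        return (r_raw, details) if return_details else r_raw

    q = m / 2.0
    r1 = r_half / (q - r_half * (q - 1.0))        # single-repetition reliability
    r1 = float(np.clip(r1, 1e-12, 1.0))
    R_m = m * r1 / (1.0 + (m - 1.0) * r1)          # reliability of the m-rep mean
    ceiling = float(np.sqrt(R_m))
    details["ceiling"] = ceiling
    R = float(np.clip(r_raw / ceiling, -1.0, 1.0))
    return (R, details) if return_details else R
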