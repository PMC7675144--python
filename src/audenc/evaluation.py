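"""Significance tests, model-equivalence analysis and response reliability.

The central quantity is the *equivalence score*: the first-order partial
correlation between the validation predictions of two augmented models
(e.g. STP and GC), controlling for the shared LN prediction.  A score of
1 means the two models deviate from the LN prediction identically; 0 means
their deviations are unrelated.  Because finite estimation data bias the
score downward, a within-model ceiling is computed by fitting the same
architecture to two halves of the estimation data and correcting with the
between-model full/half ratio: ``W+ = (B_full / B_half) * W_half``.

Response reliability is the signal-power fraction of total response power
across repeated presentations (1 = noise-free, 0 = pure noise, 0.5 = equal
signal and noise power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .fitting import _pearson, fit_model
from .models import predict

__all__ = [
    "EquivalenceResult",
    "ReliabilityResult",
    "JackknifeResult",
    "permutation_significance",
    "jackknife_improvement",
    "equivalence_partial_correlation",
    "corrected_within_equivalence",
    "reliability",
    "effect_size",
    "within_model_ceiling",
]


@dataclass
class EquivalenceResult:
    """Partial-correlation equivalence terms for one neuron/architecture."""

    partial_corr: float
    w_half: Optional[float] = None
    b_full: Optional[float] = None
    b_half: Optional[float] = None
    w_plus: Optional[float] = None
    failed: bool = False
    half_models: Optional[tuple] = None
    half_predictions: Optional[tuple] = None


@dataclass
class ReliabilityResult:
    """Per-stimulus signal-power/total-power ratios and their mean."""

    per_stimulus: np.ndarray
    overall: float
    n_skipped_reps: int = 0


class JackknifeResult(NamedTuple):
    p_value: float
    statistic: float
    delta: float


def permutation_significance(pred: np.ndarray, resp_mean: np.ndarray,
                             n_perm: int = 1000, seed: int = 0,
                             min_shift_s: float = 0.5,
                             bin_s: float = 0.01) -> float:
    """Permutation test of prediction accuracy against a shifted null.

    The null distribution is built by circularly shifting the prediction by
    random offsets of at least ``min_shift_s`` (preserving autocorrelation)
    and recomputing the Pearson correlation with the trial-averaged
    response.  ``p = (1 + #{null r >= observed r}) / (n_perm + 1)``.
    """
    pred = np.asarray(pred, dtype=float)
    resp_mean = np.asarray(resp_mean, dtype=float)
    T = pred.size
    min_shift = int(round(min_shift_s / bin_s))
    if T < 2 * min_shift:
        raise ValueError(
            f"series of {T} bins is too short for a minimum shift of {min_shift} bins"
        )
    if np.ptp(pred) == 0:
        warnings.warn("constant prediction; p = 1")
        return 1.0
    r_obs = _pearson(pred, resp_mean)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    shifts = rng.integers(min_shift, T - min_shift + 1, size=n_perm)
    null = np.array([_pearson(np.roll(pred, s), resp_mean) for s in shifts])
    return float((1 + np.sum(null >= r_obs)) / (n_perm + 1))


def jackknife_improvement(predA: np.ndarray, predB: np.ndarray,
                          resp_reps: np.ndarray, n_jack: int = 20) -> JackknifeResult:
    """Jackknife t test on the prediction-correlation difference R_B - R_A.

    Deletes one of ``n_jack`` contiguous validation blocks at a time,
    recomputes both correlations against the trial-averaged response, forms
    pseudo-values and runs a paired t test (two-sided p, df = n_jack - 1).
    A positive statistic means B predicts better than A.
    """
    if n_jack < 2:
        raise ValueError("n_jack must be at least 2")
    predA = np.asarray(predA, dtype=float)
    predB = np.asarray(predB, dtype=float)
    resp = np.atleast_2d(np.asarray(resp_reps, dtype=float))
    ybar = resp.mean(axis=0)
    T = ybar.size
    if T < n_jack:
        raise ValueError("validation series shorter than the number of jackknife blocks")

    def theta(mask):
        return _pearson(predB[mask], ybar[mask]) - _pearson(predA[mask], ybar[mask])

    full = theta(np.ones(T, dtype=bool))
    blocks = np.array_split(np.arange(T), n_jack)
    pseudo = np.empty(n_jack)
    for i, blk in enumerate(blocks):
        mask = np.ones(T, dtype=bool)
        mask[blk] = False
        pseudo[i] = n_jack * full - (n_jack - 1) * theta(mask)
    se = np.std(pseudo, ddof=1) / np.sqrt(n_jack)
    if se == 0:
        return JackknifeResult(p_value=1.0, statistic=0.0, delta=full)
    t = float(np.mean(pseudo) / se)
    p = float(2.0 * stats.t.sf(abs(t), df=n_jack - 1))
    return JackknifeResult(p_value=p, statistic=t, delta=full)


def equivalence_partial_correlation(pred_a: np.ndarray, pred_b: np.ndarray,
                                    pred_ln: np.ndarray) -> float:
    """First-order partial correlation of two predictions given the LN one.

    ``(r_ab - r_al * r_bl) / sqrt((1 - r_al^2)(1 - r_bl^2))`` with Pearson
    correlations among the three series; symmetric in the two model
    predictions.  Returns NaN (with a warning) when either prediction is
    numerically identical to the LN prediction.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    pred_ln = np.asarray(pred_ln, dtype=float)
    if not pred_a.shape == pred_b.shape == pred_ln.shape:
        raise ValueError("the three prediction series must have equal length")
    if np.array_equal(pred_a, pred_ln) or np.array_equal(pred_b, pred_ln):
        warnings.warn("model prediction identical to LN prediction; equivalence undefined")
        return float("nan")
    r_ab = _pearson(pred_a, pred_b)
    r_al = _pearson(pred_a, pred_ln)
    r_bl = _pearson(pred_b, pred_ln)
    denom = np.sqrt((1.0 - r_al ** 2) * (1.0 - r_bl ** 2))
    if denom < 1e-12:
        warnings.warn("degenerate residuals after removing the LN prediction")
        return float("nan")
    return float((r_ab - r_al * r_bl) / denom)


def corrected_within_equivalence(w_half: float, b_full: float, b_half: float) -> float:
    """Within-model ceiling corrected for half-data estimation noise.

    ``W+ = (B_full / B_half) * W_half``; the ratio is the equivalence gain
    expected if the within-model comparison used the full dataset.
    """
    if b_half == 0:
        warnings.warn("B_half is zero; corrected equivalence undefined")
        return float("nan")
    return float((b_full / b_half) * w_half)


def reliability(resp_reps) -> ReliabilityResult:
    """Signal-power fraction of total power across repeated presentations.

    For each stimulus with repetitions ``y_j`` (j = 1..m): total power is
    ``<y_j, y_j>``; signal power is the mean over k != j of ``<y_j, y_k>``;
    the per-stimulus reliability is the mean over repetitions of
    signal/total, and the overall value is the mean over stimuli.
    Repetitions with zero total power are skipped (division guard).
    """
    if isinstance(resp_reps, np.ndarray) and resp_reps.ndim == 2:
        resp_reps = [resp_reps]
    per_stim = []
    n_skipped = 0
    for y in resp_reps:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        m = y.shape[0]
        if m < 2:
            raise ValueError("reliability requires at least 2 repetitions per stimulus")
        G = y @ y.T
        total = np.diag(G)
        signal = (G.sum(axis=1) - total) / (m - 1)
        ok = total > 0
        n_skipped += int(np.sum(~ok))
        if not np.any(ok):
            warnings.warn("all repetitions have zero power; stimulus skipped")
            continue
        per_stim.append(float(np.mean(signal[ok] / total[ok])))
    per_stim = np.asarray(per_stim)
    overall = float(per_stim.mean()) if per_stim.size else float("nan")
    return ReliabilityResult(per_stimulus=per_stim, overall=overall,
                             n_skipped_reps=n_skipped)


def effect_size(r_stp: float, r_gc: float, r_ln: float) -> float:
    """Mean improvement of the two augmented models over the LN model."""
    return float(((r_stp - r_ln) + (r_gc - r_ln)) / 2.0)


def _split_halves(n: int, seed: int):
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    order = rng.permutation(n)
    return np.sort(order[0::2]), np.sort(order[1::2])


def within_model_ceiling(architecture: str, est_data, val_data, ln_model,
                         config=None, seed: int = 0) -> EquivalenceResult:
    """Half-data within-model equivalence (the raw ceiling term W_half).

    Splits the estimation stimuli into two halves (alternating assignment
    after a seeded shuffle), fits the same architecture independently to
    each half, and computes the partial correlation between the two fits'
    validation predictions relative to the supplied full-data LN model.
    The two half-fit models and predictions are returned so a caller can
    form the between-model terms B_full/B_half and apply the correction.
    """
    from .datasets import FitData  # local import to avoid a cycle

    n = len(est_data.stimuli)
    if n < 2:
        raise ValueError("estimation data must be splittable into two non-empty halves")
    idx1, idx2 = _split_halves(n, seed)
    pred_ln = np.concatenate([predict(ln_model, s) for s in val_data.stimuli])
    halves = []
    for idx in (idx1, idx2):
        sub = FitData([est_data.stimuli[i] for i in idx],
                      [est_data.responses[i] for i in idx])
        try:
            # warm-start from an LN fit on the same half: stabilizes the
            # half-data fit without coupling the two halves
            ln_half = fit_model("LN", sub, config)
            m = fit_model(architecture, sub, config, init_from=ln_half)
        except Exception as exc:  # fit failure on a half -> flagged result
            warnings.warn(f"half-data fit failed: {exc}")
            return EquivalenceResult(partial_corr=float("nan"), failed=True)
        halves.append(m)
    preds = tuple(
        np.concatenate([predict(m, s) for s in val_data.stimuli]) for m in halves
    )
    w_half = equivalence_partial_correlation(preds[0], preds[1], pred_ln)
    return EquivalenceResult(partial_corr=w_half, w_half=w_half,
                             half_models=tuple(halves), half_predictions=preds)
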