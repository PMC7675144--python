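"""Equivalence scores and response reliability on constructed series.

Shows the two calibration points of the partial-correlation equivalence
score (1.0 for identical deviations from the LN prediction, 0.0 for
orthogonal deviations) and the reliability metric's interpretation
(0.5 = response that is half signal, half noise).
"""

import numpy as np

from audenc import equivalence_partial_correlation, reliability

rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(5)))
T = 1000
ln = rng.standard_normal(T).cumsum()           # a reference LN prediction

# two "models" that deviate from LN in exactly the same way
res = np.sin(np.arange(T) / 10.0)
print("identical deviations:",
      round(equivalence_partial_correlation(ln + res, ln + res, ln), 4))

# two models whose deviations are mutually orthogonal
def orthogonalize(v, others):
    v = v - v.mean()
    for o in others:
        o = o - o.mean()
        v = v - (v @ o) / (o @ o) * o
    return v

r1 = orthogonalize(rng.standard_normal(T), [ln])
r2 = orthogonalize(rng.standard_normal(T), [ln, r1])
print("orthogonal deviations:",
      round(equivalence_partial_correlation(ln + r1, ln + r2, ln), 6))

# reliability: noise power equal to signal power -> 0.5
signal = np.abs(rng.standard_normal(T)) * 4
sd = np.sqrt(np.mean(signal ** 2))
reps = signal[None, :] + sd * rng.standard_normal((100, T))
print("reliability at 0 dB SNR:", round(reliability(reps).overall, 3),
      "(0.5 = half signal, half noise)")
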