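"""Fit the fuzzy sharp-RDD model and read off the Average Causal Effect.

Builds a small synthetic cohort: an AUDIT-like score x around the cutoff
15, a counseling effect that shifts the outcome intercept by 1.5 at the
threshold, and imprecise (triangular fuzzy) recordings of both variables.
"""

import numpy as np

from modsrd import (
    FuzzyObservation,
    RDDDataset,
    TriangularFuzzyNumber,
    estimate_discontinuity_two_sided,
    fit_modified,
    fit_side,
    fuzzify,
)

rng = np.random.default_rng(7)
n = 150
x = np.clip(rng.normal(15, 5, n), 0, 40)
d = (x >= 15).astype(float)
y = 9.0 + 0.5 * (1 - d) * (x - 15) + 0.3 * d * (x - 15) + 1.5 * d
y = y + rng.normal(0, 1, n)

observations = [
    FuzzyObservation(fuzzify(yi, 0.5, rng=rng), fuzzify(xi, 0.5, rng=rng))
    for yi, xi in zip(y, x)
]
data = RDDDataset(observations, TriangularFuzzyNumber.crisp(15.0))

fit = fit_modified(data)
print("psi_hat (alpha, beta, gamma, delta):",
      tuple(round(p, 4) for p in fit.psi_hat))
print("standard errors:                   ",
      tuple(round(s, 4) for s in fit.standard_errors))
print(f"ACE = delta = {fit.ace:.4f}  (true jump in this example: 1.5)")

# the same jump via two independent side fits
jump = estimate_discontinuity_two_sided(
    fit_side(data, "above"), fit_side(data, "below")
)
print(f"two-sided jump alpha_above - alpha_below = {jump:.4f}  "
      "(identical to delta by construction)")
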