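# modsrd — sharp regression discontinuity with fuzzy observations

`modsrd` estimates causal effects in a **sharp regression discontinuity
design (RDD)** when both the outcome and the running variable are recorded
imprecisely as **triangular fuzzy numbers**.

The motivating setting is epidemiological: patients are screened with an
AUDIT alcohol-use score and everyone scoring at or above a cutoff (15)
enters a counseling program, while nobody below it does.  The jump in the
conditional outcome mean at the cutoff then identifies the **Average Causal
Effect (ACE)** of the program.  Clinical measurements such as screening
scores and CD4-linked outcomes are, however, imprecise; here each recorded
value is a triple `(lower, mode, upper)` describing a triangular membership
function, with a crisp value as the degenerate triple.

## The model

For subject *ij* with fuzzy outcome *y\**, fuzzy running value *x\** and
(possibly fuzzy) cutoff *x′\**, let *d* = 1 when the defuzzified running
value reaches the defuzzified cutoff, else 0. The estimator fits

```
y* = α + β(1 − d)(x* − x′*) + γ d (x* − x′*) + δ d + e**
```

by ordinary least squares after defuzzifying every triple to its centroid
`(lower + mode + upper)/3`.  β and γ are the untreated and treated slopes;
**δ is the ACE**, the jump in the outcome mean at the cutoff, since the
fitted mean at *x\** = *x′\** is α without treatment and α + δ with it.
Equivalent routes — two independent side fits whose intercepts are
differenced, or the classical pooled interaction regression — are provided
and agree exactly.

The package also ships:

* a **McCrary-style density test** for manipulation of the running
  variable: a cutoff-aligned histogram is smoothed by triangular-kernel
  local linear regression on each side, and the log-density difference at
  the cutoff θ = log f̂₊ − log f̂₋ is referred to a normal with the
  asymptotic standard error √((24/5)(1/nh)(1/f̂₊ + 1/f̂₋));
* a **synthetic-data generator and Monte Carlo harness** reproducing the
  estimator's consistency/normality study: cutoff 15, true
  ν = α + δ = 10, β = 0.5, γ = 0.3, 1000 replications at
  n ∈ {30, 50, 100, 200}.

## Worked example

```python
import numpy as np
from modsrd import (FuzzyObservation, RDDDataset, TriangularFuzzyNumber,
                    fit_modified, fuzzify)

rng = np.random.default_rng(7)
n = 150
x = np.clip(rng.normal(15, 5, n), 0, 40)          # AUDIT-like score
d = (x >= 15).astype(float)                        # sharp assignment
y = 9.0 + 0.5*(1-d)*(x-15) + 0.3*d*(x-15) + 1.5*d + rng.normal(0, 1, n)

obs = [FuzzyObservation(fuzzify(yi, 0.5, rng=rng), fuzzify(xi, 0.5, rng=rng))
       for yi, xi in zip(y, x)]
data = RDDDataset(obs, TriangularFuzzyNumber.crisp(15.0))
fit = fit_modified(data)
print(fit.psi_hat, fit.ace)
```

Running `python examples/fit_fuzzy_rdd.py` (the same cohort) prints

```
psi_hat (alpha, beta, gamma, delta): (8.9903, 0.5262, 0.3336, 1.2807)
standard errors:                    (0.1631, 0.0343, 0.047, 0.2539)
ACE = delta = 1.2807  (true jump in this example: 1.5)
two-sided jump alpha_above - alpha_below = 1.2807  (identical to delta by construction)
```

The estimated jump 1.28 (SE 0.25) is the causal effect read off at the
cutoff; the true simulated jump 1.5 lies well inside one standard error.
The two-sided route returns the identical number because the pooled
regression nests the two side lines exactly.

Two more narrative scripts live in `examples/`:
`density_diagnostic.py` (manipulation check: θ ≈ 0 on a clean sample,
θ ≈ +1.87 with p ≈ 6e-26 after pushing 30% of the just-below mass over the
threshold) and `monte_carlo_study.py` (1000-replication study showing
sd(ν̂) falling 0.45 → 0.36 → 0.24 → 0.17 as n grows 30 → 200, with the ν̂
distribution passing an omnibus normality test).

## Command line

The same three capabilities are exposed as a thin CLI:

```sh
modsrd fit data.csv --cutoff 15 --out fit.txt
modsrd density-test data.csv --cutoff 15
modsrd simulate --n 200 --reps 1000 --seed 42 --out estimates.csv
```

Input CSVs carry either fuzzy columns
`y_lower,y_mode,y_upper,x_lower,x_mode,x_upper[,cluster_id]` or crisp
`y,x` columns (promoted to degenerate triples).

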