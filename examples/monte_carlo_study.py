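"""Consistency and normality of the fuzzy sharp-RDD estimator.

Reruns the estimator's Monte Carlo study: 1000 replications per sample
size at the design cutoff 15 with true (nu, beta, gamma) = (10, 0.5, 0.3),
nu = alpha + delta.  A consistent estimator shows the dispersion of
nu-hat shrinking as n grows, and its sampling distribution looks normal.
"""

from modsrd import (
    SimulationConfig,
    consistency_study,
    run_monte_carlo,
    summarize_simulation,
)

config = SimulationConfig(n=200, reps=1000, seed=42)

summary = summarize_simulation(run_monte_carlo(config))
print("n = 200, 1000 replications:")
print(summary.table.to_string(float_format=lambda v: f"{v:.4f}"))
print(f"normality of nu_hat (D'Agostino-Pearson): "
      f"stat = {summary.normality_stat:.3f}, p = {summary.normality_p:.3f}")
print("bias within ~3 sd/sqrt(reps) of 0 means the estimator recovers the "
      "true parameters on average.\n")

table = consistency_study(config, sample_sizes=(30, 50, 100, 200))
print("dispersion of nu_hat by sample size (1000 replications each):")
print(table.to_string(float_format=lambda v: f"{v:.4f}"))
print("sd and rmse fall monotonically with n: the consistency of the "
      "Average Causal Effect estimator.")
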