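"""Synthetic data generation and the Monte Carlo study.

The generator emulates the study design the estimator targets: an
AUDIT-like running variable centred on the cutoff, sharp assignment at the
threshold, a piecewise-linear conditional outcome mean with an intercept
jump, additive Gaussian noise, and symmetric random fuzzification of both
recorded variables.  The default configuration is the reference simulation
design: cutoff x' = 15 and true parameters ν = α + δ = 10, β = 0.5
(untreated slope), γ = 0.3 (treated slope).

``run_monte_carlo`` repeats simulate-then-fit and collects (ν̂, β̂, γ̂) per
replication; ``summarize_simulation`` reports bias / SD / RMSE and an
omnibus normality check, the quantities behind the estimator's consistency
and asymptotic-normality claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import RDDDataset, fit_modified
from .fuzzy import FuzzyObservation, TriangularFuzzyNumber, fuzzify

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationSummary",
    "simulate_dataset",
    "replication_rng",
    "run_monte_carlo",
    "summarize_simulation",
    "consistency_study",
]

PARAM_NAMES = ("nu_hat", "beta_hat", "gamma_hat")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one Monte Carlo run.

    ``nu_true`` is the composite ν = α + δ; α is derived as ν − δ, so any
    (α, δ) split with the same sum targets the same ν.  The running
    variable is Normal(x_mean, x_sd) truncated to x_bounds — an AUDIT-like
    0–40 score centred on the cutoff so both sides stay populated.
    Fuzzification spreads are symmetric and apply to the recorded values of
    both variables.
    """

    n: int = 200
    reps: int = 1000
    seed: int = 0
    nu_true: float = 10.0
    beta_true: float = 0.5
    gamma_true: float = 0.3
    delta_true: float = 1.0
    cutoff: float = 15.0
    noise_sd: float = 1.0
    x_mean: float = 15.0
    x_sd: float = 5.0
    x_bounds: tuple[float, float] = (0.0, 40.0)
    fuzz_spread_y: float = 0.5
    fuzz_spread_x: float = 0.5
    side_policy: Literal["fail", "resample"] = "fail"
    max_resamples: int = 100

    @property
    def alpha_true(self) -> float:
        return self.nu_true - self.delta_true

    @property
    def truth(self) -> tuple[float, float, float]:
        """True (ν, β, γ)."""
        return (self.nu_true, self.beta_true, self.gamma_true)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n < 4:
            raise ValueError("n must be >= 4 (two observations per side)")
        if self.noise_sd < 0 or self.fuzz_spread_x < 0 or self.fuzz_spread_y < 0:
            raise ValueError("noise_sd and fuzz spreads must be non-negative")
        lo, hi = self.x_bounds
        if not lo < self.cutoff < hi:
            raise ValueError("cutoff must lie strictly inside x_bounds")


@dataclass(frozen=True)
class SimulationResult:
    """Per-replication estimates (rows) of (ν̂, β̂, γ̂)."""

    estimates: pd.DataFrame
    config: SimulationConfig


@dataclass(frozen=True)
class SimulationSummary:
    """Bias / SD / RMSE per parameter plus a normality check on ν̂."""

    table: pd.DataFrame  # index: nu_hat/beta_hat/gamma_hat; cols: mean,bias,sd,rmse
    normality_stat: float
    normality_p: float
    reps: int

    def mc_standard_error(self, param: str) -> float:
        """Monte-Carlo standard error of the mean: sd / sqrt(reps)."""
        return float(self.table.loc[param, "sd"] / np.sqrt(self.reps))


def replication_rng(master_seed: int, replication: int) -> np.random.Generator:
    """Generator for one replication, reproducible in isolation.

    Uses the SeedSequence spawn tree: replication r of master seed s is
    ``SeedSequence(s, spawn_key=(r,))``, identical to the r-th child the
    Monte Carlo harness draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(replication,))
    )


def _draw_truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: tuple[float, float]
) -> np.ndarray:
    """Rejection-sample a truncated normal (acceptance ~1 for wide bounds)."""
    lo, hi = bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> RDDDataset:
    """Generate one fuzzy RDD dataset under the configured conditions.

    Steps: draw n running values from the truncated normal; fuzzify each
    into x*; assign d = 1 iff the defuzzified (centroid) x* reaches the
    cutoff; generate y = α + β(1−d)(x−x') + γ·d(x−x') + δ·d + ε with the
    mean evaluated at the defuzzified running value and ε ~ N(0, noise_sd²);
    fuzzify y into y*.  The same generator state always yields the same
    dataset.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for _attempt in range(config.max_resamples):
        x_true = _draw_truncated_normal(
            gen, config.n, config.x_mean, config.x_sd, config.x_bounds
        )
        x_star = [fuzzify(xi, config.fuzz_spread_x, rng=gen) for xi in x_true]
        x_rec = np.array([fz.centroid() for fz in x_star])
        d = (x_rec >= config.cutoff).astype(float)
        if d.sum() >= 2 and (1 - d).sum() >= 2:
            break
        if config.side_policy == "fail":
            raise RuntimeError(
                f"simulated dataset left a side with < 2 observations "
                f"(n={config.n}); set side_policy='resample' to redraw"
            )
    else:
        raise RuntimeError(
            f"could not populate both sides after {config.max_resamples} redraws"
        )
    xc = x_rec - config.cutoff
    mean = (
        config.alpha_true
        + config.beta_true * (1 - d) * xc
        + config.gamma_true * d * xc
        + config.delta_true * d
    )
    y = mean + gen.normal(0.0, config.noise_sd, size=config.n) if config.noise_sd > 0 else mean
    obs = [
        FuzzyObservation(
            y_star=fuzzify(yi, config.fuzz_spread_y, rng=gen),
            x_star=fz,
        )
        for yi, fz in zip(np.atleast_1d(y), x_star)
    ]
    return RDDDataset(obs, TriangularFuzzyNumber.crisp(config.cutoff))


def run_monte_carlo(
    config: SimulationConfig,
    on_error: Literal["abort", "skip"] = "abort",
) -> SimulationResult:
    """Simulate-and-fit ``config.reps`` independent replications.

    Each replication gets its own generator spawned deterministically from
    the master seed (see ``replication_rng``), is fitted with the fuzzy
    sharp-RDD estimator, and contributes one row (ν̂, β̂, γ̂) with
    ν̂ = α̂ + δ̂.  Per-replication fit failures abort the run by default;
    ``on_error='skip'`` drops the replication instead.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    rows = []
    for r, child in enumerate(children):
        gen = np.random.default_rng(child)
        try:
            data = simulate_dataset(config, gen)
            fit = fit_modified(data)
        except Exception:
            if on_error == "abort":
                raise
            continue
        rows.append((r, fit.alpha + fit.delta, fit.beta, fit.gamma))
    est = pd.DataFrame(
        [r[1:] for r in rows],
        columns=list(PARAM_NAMES),
        index=pd.Index([r[0] for r in rows], name="replication"),
    )
    return SimulationResult(estimates=est, config=config)


def summarize_simulation(
    result: SimulationResult,
    truth: Sequence[float] | None = None,
) -> SimulationSummary:
    """Bias, SD, RMSE per parameter and an omnibus normality test on ν̂.

    ``rmse`` is sqrt(mean squared error about the truth), so
    rmse² = bias² + sd²·(reps−1)/reps exactly (sd uses the n−1 divisor).
    Normality is assessed on the ν̂ column with the D'Agostino–Pearson
    omnibus statistic.
    """
    est = result.estimates
    if len(est) < 2:
        raise ValueError("need at least 2 replications to summarise")
    if truth is None:
        truth = result.config.truth
    truth = np.asarray(truth, dtype=float)
    if truth.shape != (3,):
        raise ValueError("truth must be a (nu, beta, gamma) triple")
    rows = {}
    for name, tv in zip(PARAM_NAMES, truth):
        col = est[name].to_numpy()
        mean = col.mean()
        rows[name] = {
            "truth": tv,
            "mean": mean,
            "bias": mean - tv,
            "sd": col.std(ddof=1),
            "rmse": float(np.sqrt(np.mean((col - tv) ** 2))),
        }
    if len(est) >= 8:  # omnibus test needs enough rows for the kurtosis part
        stat, p = stats.normaltest(est["nu_hat"].to_numpy())
    else:
        stat, p = float("nan"), float("nan")
    return SimulationSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        normality_stat=float(stat),
        normality_p=float(p),
        reps=len(est),
    )


def consistency_study(
    base_config: SimulationConfig,
    sample_sizes: Sequence[int] = (30, 50, 100, 200),
) -> pd.DataFrame:
    """SD and RMSE of ν̂ across sample sizes — the consistency diagnostic.

    Runs an independent Monte Carlo at each n (sub-seeded from the base
    seed by offsetting with the sample size) and tabulates the dispersion
    of ν̂; a consistent estimator shows both shrinking as n grows.
    """
    records = []
    for n in sample_sizes:
        cfg = replace(base_config, n=n, seed=base_config.seed + n)
        summ = summarize_simulation(run_monte_carlo(cfg))
        row = summ.table.loc["nu_hat"]
        records.append(
            {
                "n": n,
                "mean_nu_hat": row["mean"],
                "bias_nu_hat": row["bias"],
                "sd_nu_hat": row["sd"],
                "rmse_nu_hat": row["rmse"],
                "reps": summ.reps,
            }
        )
    return pd.DataFrame.from_records(records).set_index("n")
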