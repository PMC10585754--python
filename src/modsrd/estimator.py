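"""Sharp regression discontinuity estimation with fuzzy observations.

The design: subjects with running value at or above a cutoff x' receive
treatment (d = 1), everyone below does not (d = 0) — a sharp design, so the
jump in the conditional outcome mean at the cutoff identifies the Average
Causal Effect (ACE).  Both the outcome y* and the running variable x* may be
recorded imprecisely as triangular fuzzy numbers; estimation defuzzifies
them (centroid by default) and solves the resulting least-squares problem.

Three equivalent routes to the jump are provided:

* ``fit_side`` / ``estimate_discontinuity_two_sided`` — separate local
  linear fits below and above the cutoff; the jump is the difference of the
  fitted intercepts at x'.
* ``fit_pooled`` — one pooled OLS regression.  Two parameterizations of the
  same model space are supported: ``"interaction"`` regresses y on
  [1, x^c, d·x^c, d] (treated slope = β + γ) and ``"sidewise"`` regresses y
  on [1, (1−d)·x^c, d·x^c, d] (treated slope = γ directly), where
  x^c = x − x'.  Both produce identical fitted values and the same jump δ.
* ``fit_modified`` — the fuzzy-variable model: defuzzify y*, x* and the
  (possibly fuzzy) cutoff x'*, then run the sidewise pooled fit.  δ is the
  ACE.

Internally coefficients and standard errors come from statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .fuzzy import (
    FuzzyObservation,
    TriangularFuzzyNumber,
    get_defuzzifier,
)

__all__ = [
    "RDDDataset",
    "SideFit",
    "SRDFit",
    "InsufficientDataError",
    "SingularDesignError",
    "assign_treatment",
    "fit_side",
    "estimate_discontinuity_two_sided",
    "fit_pooled",
    "fit_modified",
    "treatment_effect",
    "PARAM_INTERACTION",
    "PARAM_SIDEWISE",
]

# parameterization labels: "interaction" follows the classical pooled
# regression y = α + β x^c + γ d x^c + δ d; "sidewise" follows the
# modified model y = α + β(1−d)x^c + γ d x^c + δ d.
PARAM_INTERACTION = "interaction"
PARAM_SIDEWISE = "sidewise"
_PARAMETERIZATIONS = (PARAM_INTERACTION, PARAM_SIDEWISE)

Parameterization = Literal["interaction", "sidewise"]


class InsufficientDataError(ValueError):
    """Too few usable observations in the estimation window."""


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (e.g. no variation in x)."""


def assign_treatment(x_value: float, cutoff_value: float) -> int:
    """Sharp assignment rule: treated iff the running value reaches the cutoff.

    Subjects scoring at or above the threshold enter the program, so the
    tie x == cutoff is treated (d = 1).
    """
    if not (np.isfinite(x_value) and np.isfinite(cutoff_value)):
        raise ValueError(
            f"non-finite input to assign_treatment: x={x_value}, cutoff={cutoff_value}"
        )
    return 1 if x_value >= cutoff_value else 0


@dataclass
class RDDDataset:
    """Fuzzy (y*, x*) observations together with the cutoff.

    The treatment indicator d is derived, not supplied: d = 1 exactly when
    the defuzzified running value reaches the defuzzified cutoff.

    Parameters
    ----------
    observations : sequence of FuzzyObservation
    cutoff : TriangularFuzzyNumber or float
        The threshold x'.  A plain number is promoted to a crisp triple.
    defuzzification : str
        Strategy used to turn triples into crisp values ('centroid' or
        'mode'); applied consistently to y*, x* and the cutoff.
    """

    observations: Sequence[FuzzyObservation]
    cutoff: TriangularFuzzyNumber
    defuzzification: str = "centroid"

    def __post_init__(self) -> None:
        if not isinstance(self.cutoff, TriangularFuzzyNumber):
            self.cutoff = TriangularFuzzyNumber.crisp(float(self.cutoff))
        self.observations = list(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def cutoff_value(self) -> float:
        return get_defuzzifier(self.defuzzification)(self.cutoff)

    def defuzzified(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, x, d) as crisp arrays under the configured strategy."""
        dfz = get_defuzzifier(self.defuzzification)
        y = np.array([dfz(o.y_star) for o in self.observations], dtype=float)
        x = np.array([dfz(o.x_star) for o in self.observations], dtype=float)
        c = dfz(self.cutoff)
        d = np.array([assign_treatment(xi, c) for xi in x], dtype=float)
        return y, x, d

    def cluster_ids(self) -> Optional[np.ndarray]:
        ids = [o.cluster_id for o in self.observations]
        if all(i is None for i in ids):
            return None
        if any(i is None for i in ids):
            raise ValueError("cluster_id must be set for all observations or none")
        return np.asarray(ids)

    @classmethod
    def from_crisp(
        cls,
        y: Sequence[float],
        x: Sequence[float],
        cutoff: float,
        cluster_ids: Optional[Sequence[object]] = None,
        defuzzification: str = "centroid",
    ) -> "RDDDataset":
        """Build a dataset of degenerate (crisp) triples from plain arrays."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        if y.shape != x.shape:
            raise ValueError("y and x must have the same length")
        if cluster_ids is None:
            cluster_ids = [None] * len(y)
        obs = [
            FuzzyObservation(
                TriangularFuzzyNumber.crisp(yi),
                TriangularFuzzyNumber.crisp(xi),
                cid,
            )
            for yi, xi, cid in zip(y, x, cluster_ids)
        ]
        return cls(obs, TriangularFuzzyNumber.crisp(cutoff), defuzzification)


@dataclass(frozen=True)
class SideFit:
    """Local linear fit on one side of the cutoff.

    ``alpha_hat`` is the fitted conditional mean at x = x' for its side;
    ``beta_hat`` the slope in (x − x').
    """

    side: Literal["below", "above"]
    alpha_hat: float
    beta_hat: float
    n_used: int
    bandwidth_h: float
    alpha_se: float = float("nan")
    beta_se: float = float("nan")


@dataclass(frozen=True)
class SRDFit:
    """Pooled sharp-RDD fit.  ``psi_hat`` = (alpha, beta, gamma, delta).

    ``delta`` is the Average Causal Effect: the jump in the conditional
    outcome mean at the cutoff.
    """

    parameterization: str
    psi_hat: tuple[float, float, float, float]
    standard_errors: tuple[float, float, float, float]
    residuals: np.ndarray
    bandwidth_h: float
    n_left: int
    n_right: int
    cutoff_value: float
    cov_type: str = "nonrobust"
    in_window: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def alpha(self) -> float:
        return self.psi_hat[0]

    @property
    def beta(self) -> float:
        return self.psi_hat[1]

    @property
    def gamma(self) -> float:
        return self.psi_hat[2]

    @property
    def delta(self) -> float:
        return self.psi_hat[3]

    @property
    def ace(self) -> float:
        """The Average Causal Effect δ."""
        return self.psi_hat[3]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Model-predicted outcome at running values x (d from the cutoff rule)."""
        x = np.asarray(x, dtype=float)
        xc = x - self.cutoff_value
        d = (x >= self.cutoff_value).astype(float)
        a, b, g, dl = self.psi_hat
        if self.parameterization == PARAM_SIDEWISE:
            return a + b * (1 - d) * xc + g * d * xc + dl * d
        return a + b * xc + g * d * xc + dl * d


def _window_mask(x: np.ndarray, cutoff: float, h: float) -> np.ndarray:
    if h <= 0:
        raise ValueError(f"bandwidth_h must be positive (or inf), got {h}")
    if np.isinf(h):
        return np.ones_like(x, dtype=bool)
    return (x > cutoff - h) & (x < cutoff + h)


def _ols(X: np.ndarray, y: np.ndarray, cov_type: str, cov_kwds=None):
    """OLS through statsmodels with an explicit rank check."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank deficient; check for identical running "
            "values or an empty treatment side in the window"
        )
    model = sm.OLS(y, X)
    if cov_type == "nonrobust":
        return model.fit()
    return model.fit(cov_type=cov_type, cov_kwds=cov_kwds)


def fit_side(
    data: RDDDataset,
    side: Literal["below", "above"],
    bandwidth_h: float = np.inf,
) -> SideFit:
    """Local linear OLS on one side of the cutoff.

    Minimises sum over the side's window of (y − α − β(x − x'))², with
    window (x'−h, x') below and [x', x'+h) above — the cutoff itself
    belongs to the treated/above side, matching the assignment rule.
    ``alpha_hat`` is the fitted value at x = x'.
    """
    if side not in ("below", "above"):
        raise ValueError(f"side must be 'below' or 'above', got {side!r}")
    y, x, _ = data.defuzzified()
    c = data.cutoff_value
    inside = _window_mask(x, c, bandwidth_h)
    mask = inside & ((x < c) if side == "below" else (x >= c))
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(
            f"side {side!r}: {n} observation(s) in window, need at least 2"
        )
    xc = x[mask] - c
    X = np.column_stack([np.ones(n), xc])
    res = _ols(X, y[mask], "nonrobust")
    with np.errstate(divide="ignore", invalid="ignore"):  # n==2 leaves 0 dof
        se = res.bse
    return SideFit(
        side=side,
        alpha_hat=float(res.params[0]),
        beta_hat=float(res.params[1]),
        n_used=n,
        bandwidth_h=float(bandwidth_h),
        alpha_se=float(se[0]),
        beta_se=float(se[1]),
    )


def estimate_discontinuity_two_sided(fit_above: SideFit, fit_below: SideFit) -> float:
    """Size of the outcome jump at the cutoff: α̂_above − α̂_below."""
    if fit_above.side != "above" or fit_below.side != "below":
        raise ValueError(
            f"expected an 'above' and a 'below' fit, got "
            f"{fit_above.side!r} and {fit_below.side!r}"
        )
    return fit_above.alpha_hat - fit_below.alpha_hat


def _build_design(
    xc: np.ndarray, d: np.ndarray, parameterization: str
) -> np.ndarray:
    ones = np.ones_like(xc)
    if parameterization == PARAM_SIDEWISE:
        return np.column_stack([ones, (1 - d) * xc, d * xc, d])
    if parameterization == PARAM_INTERACTION:
        return np.column_stack([ones, xc, d * xc, d])
    raise ValueError(
        f"unknown parameterization {parameterization!r}; "
        f"choose from {_PARAMETERIZATIONS}"
    )


def fit_pooled(
    data: RDDDataset,
    bandwidth_h: float = np.inf,
    parameterization: Parameterization = PARAM_SIDEWISE,
    cluster_robust: bool = False,
) -> SRDFit:
    """Pooled OLS fit of the piecewise-linear RDD model inside the window.

    Under ``"interaction"`` the regressors are [1, x^c, d·x^c, d]: β is the
    common slope and γ the treated-side slope offset.  Under ``"sidewise"``
    they are [1, (1−d)·x^c, d·x^c, d]: β is the untreated slope and γ the
    treated slope.  The two are reparameterizations of the same model, so
    fitted values, residuals and the jump δ coincide;
    γ_interaction = γ_sidewise − β.

    With ``cluster_robust=True`` standard errors are clustered on the
    observations' cluster_id (classical homoskedastic errors otherwise).
    """
    y, x, d = data.defuzzified()
    c = data.cutoff_value
    mask = _window_mask(x, c, bandwidth_h)
    n_left = int((mask & (d == 0)).sum())
    n_right = int((mask & (d == 1)).sum())
    if n_left < 2 or n_right < 2:
        raise InsufficientDataError(
            f"need at least 2 observations on each side inside the window; "
            f"got {n_left} untreated, {n_right} treated"
        )
    xc = x[mask] - c
    X = _build_design(xc, d[mask], parameterization)
    if cluster_robust:
        ids = data.cluster_ids()
        if ids is None:
            raise ValueError("cluster_robust=True requires cluster_id on observations")
        res = _ols(X, y[mask], "cluster", {"groups": ids[mask]})
        cov_label = "cluster"
    else:
        res = _ols(X, y[mask], "nonrobust")
        cov_label = "nonrobust"
    return SRDFit(
        parameterization=parameterization,
        psi_hat=tuple(float(p) for p in res.params),
        standard_errors=tuple(float(s) for s in res.bse),
        residuals=np.asarray(res.resid, dtype=float),
        bandwidth_h=float(bandwidth_h),
        n_left=n_left,
        n_right=n_right,
        cutoff_value=c,
        cov_type=cov_label,
        in_window=mask,
    )


def fit_modified(
    data: RDDDataset,
    bandwidth_h: float = np.inf,
    cluster_robust: bool = False,
) -> SRDFit:
    """The fuzzy-variable sharp-RDD model.

    Defuzzifies the fuzzy outcome y*, running variable x* and cutoff x'*
    with the dataset's configured strategy, then fits the sidewise pooled
    regression y* = α + β(1−d)(x*−x'*) + γ d(x*−x'*) + δ d + e**.  The
    residuals of the defuzzified fit are reported as e**.  At x* = x'* the
    predicted outcome is α untreated and α + δ treated, so δ is the ACE.

    On crisp (zero-spread) data this reproduces ``fit_pooled`` exactly.
    """
    return fit_pooled(
        data,
        bandwidth_h=bandwidth_h,
        parameterization=PARAM_SIDEWISE,
        cluster_robust=cluster_robust,
    )


def treatment_effect(fit: SRDFit) -> float:
    """The Average Causal Effect: δ, the jump in predicted outcome at x'."""
    return fit.ace
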