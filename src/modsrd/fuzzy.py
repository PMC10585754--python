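"""Triangular fuzzy numbers and defuzzification.

An imprecise measurement is represented as a triangular fuzzy number
``(lower, mode, upper)``: the membership function rises linearly from 0 at
``lower`` to 1 at ``mode`` and falls back to 0 at ``upper``.  A crisp (exact)
value is the degenerate triple ``lower == mode == upper``.

Every estimator in this package consumes fuzzy observations through a
*defuzzification strategy* that maps a triple to a single representative
value.  The default is the centroid of the triangular membership function,
``(lower + mode + upper) / 3``; the mode is offered as an alternative so that
other readings of "imprecise observation" can be compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TriangularFuzzyNumber",
    "FuzzyObservation",
    "InvalidFuzzyNumberError",
    "defuzzify_centroid",
    "defuzzify_mode",
    "get_defuzzifier",
    "fuzzify",
]


class InvalidFuzzyNumberError(ValueError):
    """Raised when a triple violates the lower <= mode <= upper ordering."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A fuzzy observation summarised by its triangular membership function.

    Parameters
    ----------
    lower, mode, upper : float
        Support endpoints and peak of the membership function, in the units
        of the underlying variable.  Must satisfy ``lower <= mode <= upper``.
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        lo, m, up = float(self.lower), float(self.mode), float(self.upper)
        if not (math.isfinite(lo) and math.isfinite(m) and math.isfinite(up)):
            raise InvalidFuzzyNumberError(
                f"non-finite fuzzy triple ({lo}, {m}, {up})"
            )
        if not (lo <= m <= up):
            raise InvalidFuzzyNumberError(
                f"fuzzy triple must satisfy lower <= mode <= upper, "
                f"got ({lo}, {m}, {up})"
            )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "mode", m)
        object.__setattr__(self, "upper", up)

    @classmethod
    def crisp(cls, value: float) -> "TriangularFuzzyNumber":
        """Degenerate triple representing an exactly known value."""
        return cls(value, value, value)

    @property
    def is_crisp(self) -> bool:
        return self.lower == self.mode == self.upper

    def centroid(self) -> float:
        return defuzzify_centroid(self)

    def shifted(self, c: float) -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.lower + c, self.mode + c, self.upper + c)


@dataclass(frozen=True)
class FuzzyObservation:
    """One subject: fuzzy outcome, fuzzy running value, optional cluster id."""

    y_star: TriangularFuzzyNumber
    x_star: TriangularFuzzyNumber
    cluster_id: Optional[object] = None


def defuzzify_centroid(fz: TriangularFuzzyNumber) -> float:
    """Centroid (centre of mass) of the triangular membership function.

    For a triangle on support [lower, upper] with apex at mode this is
    exactly ``(lower + mode + upper) / 3``; a crisp triple returns its value.
    """
    return (fz.lower + fz.mode + fz.upper) / 3.0


def defuzzify_mode(fz: TriangularFuzzyNumber) -> float:
    """Most plausible value: the peak of the membership function."""
    return fz.mode


_DEFUZZIFIERS: dict[str, Callable[[TriangularFuzzyNumber], float]] = {
    "centroid": defuzzify_centroid,
    "mode": defuzzify_mode,
}


def get_defuzzifier(name: str) -> Callable[[TriangularFuzzyNumber], float]:
    """Look up a defuzzification strategy by name ('centroid' or 'mode')."""
    try:
        return _DEFUZZIFIERS[name]
    except KeyError:
        raise ValueError(
            f"unknown defuzzification strategy {name!r}; "
            f"choose from {sorted(_DEFUZZIFIERS)}"
        ) from None


def fuzzify(
    value: float,
    spread: float,
    asymmetry: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TriangularFuzzyNumber:
    """Blur a crisp value into a random triangular fuzzy number.

    The mode stays at ``value``; the support endpoints are drawn as

        lower = value - spread * (1 + asymmetry) * u1
        upper = value + spread * (1 - asymmetry) * u2

    with ``u1, u2`` independent Uniform(0, 1] from the seeded generator.
    ``spread = 0`` returns the crisp triple deterministically.

    Parameters
    ----------
    value : float
        The underlying crisp measurement.
    spread : float
        Maximal half-width of the support; must be >= 0.
    asymmetry : float
        In [-1, 1]; positive values stretch the support below the mode.
    rng : numpy Generator, int seed, or None
        Source of randomness; an int is used as a seed.
    """
    if spread < 0:
        raise ValueError(f"spread must be non-negative, got {spread}")
    if not -1.0 <= asymmetry <= 1.0:
        raise ValueError(f"asymmetry must lie in [-1, 1], got {asymmetry}")
    if spread == 0:
        return TriangularFuzzyNumber.crisp(value)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # uniform on (0, 1]: flip the half-open interval of random()
    u1, u2 = 1.0 - gen.random(2)
    lower = value - spread * (1.0 + asymmetry) * u1
    upper = value + spread * (1.0 - asymmetry) * u2
    return TriangularFuzzyNumber(lower, value, upper)
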