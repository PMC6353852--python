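"""The arousal crossover effect.

Two gain curves G_i(delta) = alpha_i delta^2 + beta_i for different
uncertainty levels s_p1 != s_p2 at shared noise s_l intersect at a positive
prediction error iff

    s_p1 * s_p2 > s_l^2.

Below the crossover the higher-uncertainty curve is above (beta grows with
s_p); beyond it the ordering flips — higher uncertainty then means *less*
gain.  This module decides existence, solves for the crossover point

    delta* = sqrt((beta_2 - beta_1) / (alpha_1 - alpha_2)),

and tabulates curve families over a delta grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import _check_variance
from .errors import DegenerateInputError, InvalidParameterError
from .gain import gain_coefficients

__all__ = [
    "CrossoverResult",
    "GainCurveTable",
    "crossover_exists",
    "crossover_point",
    "gain_curve_family",
]


@dataclass(frozen=True)
class CrossoverResult:
    """Whether two gain curves cross at delta > 0, and if so where.

    ``delta_star`` is the non-negative root; the curves are even in delta so
    the mirror-image crossing at -delta_star is implied.  ``delta_star`` and
    ``gain_at_crossover`` are ``None`` exactly when ``exists`` is False.
    """

    exists: bool
    delta_star: Optional[float] = None
    gain_at_crossover: Optional[float] = None


@dataclass(frozen=True)
class GainCurveTable:
    """Family of gain curves G(delta; s_p) over a shared delta grid."""

    delta_grid: np.ndarray
    uncertainties: tuple[float, ...]
    gains: dict[float, np.ndarray] = field(repr=False)
    s_l: float = 0.1

    def to_frame(self) -> pd.DataFrame:
        """One ``delta`` column plus one gain column per uncertainty level."""
        data = {"delta": self.delta_grid}
        for s_p in self.uncertainties:
            data[f"sp_{s_p:g}"] = self.gains[s_p]
        return pd.DataFrame(data)


def _check_triple(s_p1: float, s_p2: float, s_l: float) -> None:
    _check_variance(s_p1, "s_p1")
    _check_variance(s_p2, "s_p2")
    _check_variance(s_l, "s_l")
    if s_p1 == s_p2:
        raise DegenerateInputError(
            "s_p1 == s_p2: the two gain curves coincide, no crossover is defined"
        )


def crossover_exists(s_p1: float, s_p2: float, s_l: float) -> bool:
    """True iff the two gain curves intersect at some delta > 0.

    Holds iff s_p1 * s_p2 > s_l**2.  At exact equality the quadratic
    coefficients coincide and the curves are parallel — no crossing.
    """
    _check_triple(s_p1, s_p2, s_l)
    return s_p1 * s_p2 > s_l * s_l


def crossover_point(s_p1: float, s_p2: float, s_l: float) -> CrossoverResult:
    """Solve for the crossover of the two gain curves, if it exists.

    Returns ``exists=False`` (no error) on the measure-zero boundary
    s_p1 * s_p2 == s_l**2 where the quadratics are parallel but offset.
    """
    _check_triple(s_p1, s_p2, s_l)
    if not (s_p1 * s_p2 > s_l * s_l):
        return CrossoverResult(exists=False)
    a1, b1 = gain_coefficients(s_p1, s_l)
    a2, b2 = gain_coefficients(s_p2, s_l)
    delta_sq = (b2 - b1) / (a1 - a2)
    delta_star = math.sqrt(delta_sq)
    return CrossoverResult(
        exists=True,
        delta_star=delta_star,
        gain_at_crossover=a1 * delta_sq + b1,
    )


def gain_curve_family(
    s_p_list: Sequence[float],
    s_l: float,
    delta_max: float = 5.0,
    n_points: int = 500,
) -> GainCurveTable:
    """Tabulate G(delta; s_p) on an even grid delta in [0, delta_max].

    At delta = 0 the curves are ordered like their uncertainties (beta is
    increasing in s_p); each curve is non-decreasing along the grid.
    """
    if len(s_p_list) == 0:
        raise InvalidParameterError("s_p_list must contain at least one uncertainty")
    for s_p in s_p_list:
        _check_variance(s_p, "s_p")
    _check_variance(s_l, "s_l")
    if n_points < 2:
        raise InvalidParameterError(f"n_points must be >= 2, got {n_points}")
    if not (delta_max > 0):
        raise InvalidParameterError(f"delta_max must be > 0, got {delta_max}")

    grid = np.linspace(0.0, delta_max, n_points)
    gains: dict[float, np.ndarray] = {}
    for s_p in s_p_list:
        alpha, beta = gain_coefficients(s_p, s_l)
        gains[s_p] = alpha * grid**2 + beta
    return GainCurveTable(
        delta_grid=grid,
        uncertainties=tuple(s_p_list),
        gains=gains,
        s_l=s_l,
    )
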