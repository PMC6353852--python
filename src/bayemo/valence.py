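"""Hedonic valence as competing reward and aversion sigmoids of gain.

Following the two-incentive-system account of hedonic response (the classic
Wundt/Berlyne inverse-U), valence is the sum of a positive reward sigmoid and
a negative aversion sigmoid of information gain G:

    Reward(G)   =  h_r / (1 + exp(-c_r G + G_r))
    Aversion(G) = -h_a / (1 + exp(-c_a G + G_a))
    Valence(G)  =  Reward(G) + Aversion(G)

G_r and G_a are activation thresholds, h_r and h_a the asymptotic magnitudes,
c_r and c_a the gradients.  Two ordering constraints are structural: the
reward system activates first (G_r < G_a) and the aversion asymptote
dominates (h_r < h_a), so extreme gain ends in net negative valence while a
moderate "sweet spot" maximizes positive valence.

Note the thresholds enter the exponent unscaled, so the sigmoid midpoint sits
at G = G_r / c_r (resp. G_a / c_a), not at G = G_r.  The formula gives a
small nonzero valence at G = 0 for finite thresholds; no baseline is
subtracted to force exact neutrality there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .errors import ConstraintViolationError, InvalidParameterError, NoUniqueOptimumError

__all__ = [
    "ValenceParams",
    "DEFAULT_VALENCE_PARAMS",
    "validate_params",
    "reward",
    "aversion",
    "valence",
    "optimal_gain",
]


@dataclass(frozen=True)
class ValenceParams:
    """Parameters of the reward and aversion sigmoids.

    Defaults satisfy both ordering constraints and produce a clearly
    inverse-U valence curve with its peak between the two sigmoid midpoints.
    """

    reward_threshold: float = 2.0  # G_r
    aversion_threshold: float = 6.0  # G_a
    reward_max: float = 1.0  # h_r
    aversion_max: float = 1.5  # h_a
    reward_gradient: float = 1.0  # c_r
    aversion_gradient: float = 1.0  # c_a

    def __post_init__(self) -> None:
        validate_params(self)


def validate_params(p: ValenceParams) -> None:
    """Check every structural constraint, naming each violation.

    Raises :class:`ConstraintViolationError` listing all failed constraints:
    positive maxima and gradients, reward_threshold < aversion_threshold,
    reward_max < aversion_max.
    """
    problems: list[str] = []
    for name in ("reward_max", "aversion_max", "reward_gradient", "aversion_gradient"):
        value = getattr(p, name)
        if not np.isfinite(value) or value <= 0:
            problems.append(f"{name} must be > 0 (got {value!r})")
    for name in ("reward_threshold", "aversion_threshold"):
        if not np.isfinite(getattr(p, name)):
            problems.append(f"{name} must be finite")
    if not problems:
        if not p.reward_threshold < p.aversion_threshold:
            problems.append(
                "threshold ordering violated: reward_threshold must be < "
                f"aversion_threshold (got {p.reward_threshold!r} >= "
                f"{p.aversion_threshold!r})"
            )
        if not p.reward_max < p.aversion_max:
            problems.append(
                "maxima ordering violated: reward_max must be < aversion_max "
                f"(got {p.reward_max!r} >= {p.aversion_max!r})"
            )
    if problems:
        raise ConstraintViolationError("; ".join(problems))


DEFAULT_VALENCE_PARAMS = ValenceParams()


def reward(G, p: ValenceParams = DEFAULT_VALENCE_PARAMS):
    """Reward-system activation, in (0, h_r), increasing in G."""
    return p.reward_max * expit(p.reward_gradient * np.asarray(G) - p.reward_threshold)


def aversion(G, p: ValenceParams = DEFAULT_VALENCE_PARAMS):
    """Aversion-system activation, in (-h_a, 0), decreasing in G."""
    return -p.aversion_max * expit(
        p.aversion_gradient * np.asarray(G) - p.aversion_threshold
    )


def valence(G, p: ValenceParams = DEFAULT_VALENCE_PARAMS):
    """Net valence Reward(G) + Aversion(G); tends to h_r - h_a < 0 as G grows."""
    return reward(G, p) + aversion(G, p)


def optimal_gain(
    p: ValenceParams = DEFAULT_VALENCE_PARAMS,
    search_bound: float = 20.0,
    n_grid: int = 10_001,
    tol: float = 1e-8,
) -> float:
    """Argmax of valence over [0, search_bound].

    Dense-grid scan followed by bounded golden-section refinement around the
    best grid point (tolerance ``tol`` in G).  Raises
    :class:`NoUniqueOptimumError` if the valence curve is numerically flat
    over the interval.
    """
    validate_params(p)
    if not (search_bound > 0):
        raise InvalidParameterError(f"search_bound must be > 0, got {search_bound!r}")
    grid = np.linspace(0.0, search_bound, n_grid)
    values = valence(grid, p)
    if np.ptp(values) < 1e-12:
        raise NoUniqueOptimumError(
            "valence is flat over the search interval; no unique optimum"
        )
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if lo == hi:  # argmax at an interval endpoint
        return float(grid[i])
    res = minimize_scalar(
        lambda g: -float(valence(g, p)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)
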