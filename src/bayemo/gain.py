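"""Information gain: KL divergence of the posterior from the prior.

Information gain G is the package's quantitative proxy for emotional arousal
(surprise).  For the conjugate Gaussian pair it has the closed form

    G(delta, s_p, s_l) = 1/2 [ s_p * delta^2 / (s_p + s_l)^2
                               + ln((s_p + s_l) / s_l)
                               - s_p / (s_p + s_l) ]

where delta = xbar - eta is the prediction error (reality minus expectation),
s_p the prior uncertainty and s_l the external noise.  G is quadratic in the
prediction error,

    G = alpha * delta^2 + beta,
    alpha = s_p / (2 (s_p + s_l)^2) > 0,
    beta  = 1/2 [ ln((s_p + s_l)/s_l) - s_p/(s_p + s_l) ] >= 0,

with d(beta)/d(s_p) = s_p / (2 (s_p + s_l)^2) > 0: at zero prediction error,
more uncertainty means more gain.  All gains are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .bayes import GaussianBelief, Observation, _check_variance, update_belief
from .errors import InvalidParameterError

__all__ = [
    "GainDecomposition",
    "kl_gaussian",
    "information_gain",
    "gain_coefficients",
    "gain_from_update",
]


@dataclass(frozen=True)
class GainDecomposition:
    """Information gain together with its quadratic decomposition.

    Fields mirror the quantities that make up the closed form: the prediction
    error ``delta``, the uncertainty ``s_p``, the noise ``s_l``, the quadratic
    coefficient ``alpha``, the intercept ``beta`` and the gain
    ``gain = alpha * delta**2 + beta`` (the identity holds exactly by
    construction).
    """

    prediction_error: float
    uncertainty: float
    noise: float
    alpha: float
    beta: float
    gain: float

    @property
    def delta(self) -> float:
        return self.prediction_error


def kl_gaussian(p_mean: float, p_var: float, q_mean: float, q_var: float) -> float:
    """KL divergence D(p || q) between two univariate Gaussians, in nats.

    Non-negative; zero iff the two distributions are identical; asymmetric in
    its arguments.
    """
    _check_variance(p_var, "p_var")
    _check_variance(q_var, "q_var")
    return 0.5 * (
        math.log(q_var / p_var) + (p_var + (p_mean - q_mean) ** 2) / q_var - 1.0
    )


def gain_coefficients(s_p: float, s_l: float) -> tuple[float, float]:
    """Quadratic coefficients (alpha, beta) of G as a function of delta."""
    _check_variance(s_p, "s_p")
    _check_variance(s_l, "s_l")
    total = s_p + s_l
    alpha = s_p / (2.0 * total * total)
    beta = 0.5 * (math.log(total / s_l) - s_p / total)
    return alpha, beta


def information_gain(delta: float, s_p: float, s_l: float) -> GainDecomposition:
    """Closed-form information gain for prediction error ``delta``.

    Even in ``delta`` and strictly increasing in ``delta**2``; equals the KL
    divergence of the conjugate posterior from the prior.
    """
    if not math.isfinite(delta):
        raise InvalidParameterError(f"delta must be finite, got {delta!r}")
    alpha, beta = gain_coefficients(s_p, s_l)
    return GainDecomposition(
        prediction_error=delta,
        uncertainty=s_p,
        noise=s_l,
        alpha=alpha,
        beta=beta,
        gain=alpha * delta * delta + beta,
    )


def gain_from_update(prior: GaussianBelief, obs: Observation) -> GainDecomposition:
    """Information gain of the Bayes update of ``prior`` by ``obs``.

    Sets delta = sample_mean - prior mean; the returned gain equals
    ``kl_gaussian(update_belief(prior, obs), prior)`` up to rounding.
    """
    return information_gain(obs.sample_mean - prior.mean, prior.variance, obs.s_l)


def _kl_of_update(prior: GaussianBelief, obs: Observation) -> float:
    """Generic-KL route to the same quantity (used as an internal cross-check)."""
    post = update_belief(prior, obs)
    return kl_gaussian(post.mean, post.variance, prior.mean, prior.variance)
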