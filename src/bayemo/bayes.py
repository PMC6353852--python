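"""Conjugate Gaussian belief updating.

The model of the observer is the textbook normal–normal conjugate pair: the
latent quantity being estimated (the "meaning" of a stimulus, e.g. the sound a
percussion instrument will make) carries a Gaussian prior N(eta, s_p), and an
event delivers ``n`` samples with per-sample variance sigma^2, i.e. a Gaussian
likelihood for the sample mean with variance s_l = sigma^2 / n.  The prior
variance s_p is the observer's *uncertainty*; s_l is the *external noise*.
Updating is precision-weighted averaging:

    mean_post = (s_p * xbar + s_l * eta) / (s_p + s_l)
    var_post  = s_p * s_l / (s_p + s_l)          (1/var_post = 1/s_p + 1/s_l)

Everything downstream (information gain, the crossover effect, the exposure
simulator) is built on this state transition.  All entropies and divergences
in the package are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "GaussianBelief",
    "Observation",
    "PosteriorBelief",
    "update_belief",
    "prior_entropy",
    "density",
]


def _check_variance(value: float, name: str) -> None:
    if not math.isfinite(value) or value <= 0.0:
        raise InvalidParameterError(
            f"{name} must be finite and strictly positive, got {value!r}"
        )


@dataclass(frozen=True)
class GaussianBelief:
    """Gaussian belief N(mean, variance) about a latent scalar.

    ``variance`` is the uncertainty s_p of the belief; it must be finite and
    strictly positive (a zero-variance belief has no finite entropy and never
    updates, so it is rejected rather than clamped).
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise InvalidParameterError(f"mean must be finite, got {self.mean!r}")
        _check_variance(self.variance, "variance")

    def entropy(self) -> float:
        """Differential entropy in nats: 0.5 * ln(2 pi e * variance)."""
        return 0.5 * math.log(2.0 * math.pi * math.e * self.variance)

    def density(self, x: float) -> float:
        """Gaussian probability density at ``x``."""
        z = (x - self.mean) ** 2 / (2.0 * self.variance)
        return math.exp(-z) / math.sqrt(2.0 * math.pi * self.variance)


@dataclass(frozen=True)
class Observation:
    """Event data: sample mean, per-sample variance and sample count.

    The likelihood-function variance for the mean is ``s_l = per_sample_variance
    / n``.  Use :meth:`from_noise` when you already have s_l as a variance and
    do not care about the (sigma^2, n) split.
    """

    sample_mean: float
    per_sample_variance: float
    n: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.sample_mean):
            raise InvalidParameterError(
                f"sample_mean must be finite, got {self.sample_mean!r}"
            )
        _check_variance(self.per_sample_variance, "per_sample_variance")
        if int(self.n) != self.n or self.n < 1:
            raise InvalidParameterError(f"n must be an integer >= 1, got {self.n!r}")

    @classmethod
    def from_noise(cls, sample_mean: float, s_l: float) -> "Observation":
        """Build an observation directly from a noise variance s_l (n = 1)."""
        return cls(sample_mean=sample_mean, per_sample_variance=s_l, n=1)

    @property
    def s_l(self) -> float:
        """Noise: variance of the likelihood for the sample mean, sigma^2/n."""
        return self.per_sample_variance / self.n


class PosteriorBelief(GaussianBelief):
    """Gaussian posterior produced by :func:`update_belief`.

    A posterior is itself a valid :class:`GaussianBelief`, so it can serve as
    the prior of the next update (the exposure simulator relies on this).
    """


def update_belief(prior: GaussianBelief, obs: Observation) -> PosteriorBelief:
    """Conjugate update of a Gaussian prior by a Gaussian-likelihood event.

    Returns the posterior with precision-weighted mean and harmonic variance.
    The posterior mean always lies between the prior mean and the sample mean,
    and the posterior precision is the sum of prior and likelihood precisions.
    """
    s_p = prior.variance
    s_l = obs.s_l
    total = s_p + s_l
    # convex-combination form: exact when the observation equals the prior mean
    mean = prior.mean + (s_p / total) * (obs.sample_mean - prior.mean)
    variance = s_p * s_l / total
    return PosteriorBelief(mean=mean, variance=variance)


def prior_entropy(belief: GaussianBelief) -> float:
    """Differential entropy of a belief in nats, 0.5 * ln(2 pi e s_p).

    Strictly increasing in the variance: quadrupling s_p (doubling the
    standard deviation) adds exactly ln 2.
    """
    return belief.entropy()


def density(belief: GaussianBelief, x: float) -> float:
    """Density of ``belief`` at ``x`` (supports the quadrature oracles)."""
    return belief.density(x)
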