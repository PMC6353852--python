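"""Repeated-exposure simulator: emotional desensitization.

Repeatedly presenting the same stimulus and letting the posterior of each
update become the next prior shrinks both the uncertainty and the prediction
error, so the per-update information gain falls — the model's account of
desensitization.  In the noise-free case everything is exact:

    variance after k updates:  1 / (1/s_p0 + k/s_l)   (precision additivity)
    error before update k+1:   delta_k * s_l / (s_p,k + s_l)   (geometric)

With observation noise the per-step sample mean is stimulus_value plus
Gaussian noise under an explicit seed; the variance sequence is unchanged
(the Gaussian variance update is data-independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import GaussianBelief, Observation, update_belief
from .errors import InvalidParameterError
from .gain import gain_from_update
from .valence import DEFAULT_VALENCE_PARAMS, ValenceParams, valence as valence_fn

__all__ = ["ExposureStep", "ExposureTrajectory", "simulate_exposures"]


@dataclass(frozen=True)
class ExposureStep:
    """State of one exposure: the prior going in, and what the update yielded."""

    exposure_index: int  # 1-based
    prior_mean: float
    prior_variance: float
    prediction_error: float
    gain: float
    valence: float


@dataclass(frozen=True)
class ExposureTrajectory:
    steps: tuple[ExposureStep, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def simulate_exposures(
    initial: GaussianBelief,
    stimulus_value: float,
    s_l: float,
    n_steps: int,
    valence_params: ValenceParams = DEFAULT_VALENCE_PARAMS,
    observation_noise_sd: float = 0.0,
    seed: int | None = None,
) -> ExposureTrajectory:
    """Iterate Bayes updates against a fixed stimulus.

    With ``observation_noise_sd == 0`` every step observes exactly
    ``stimulus_value`` and the run is deterministic; otherwise a seed is
    required and each step observes stimulus_value + N(0, sd^2) noise drawn
    from that seed (bit-reproducible).
    """
    if n_steps < 1:
        raise InvalidParameterError(f"n_steps must be >= 1, got {n_steps}")
    if observation_noise_sd < 0:
        raise InvalidParameterError(
            f"observation_noise_sd must be >= 0, got {observation_noise_sd}"
        )
    if observation_noise_sd > 0 and seed is None:
        raise InvalidParameterError("a seed is required when observation noise is > 0")

    rng = np.random.default_rng(seed)
    belief = initial
    steps: list[ExposureStep] = []
    for k in range(1, n_steps + 1):
        xbar = stimulus_value
        if observation_noise_sd > 0:
            xbar += float(rng.normal(0.0, observation_noise_sd))
        obs = Observation.from_noise(xbar, s_l)
        dec = gain_from_update(belief, obs)
        steps.append(
            ExposureStep(
                exposure_index=k,
                prior_mean=belief.mean,
                prior_variance=belief.variance,
                prediction_error=dec.prediction_error,
                gain=dec.gain,
                valence=float(valence_fn(dec.gain, valence_params)),
            )
        )
        belief = update_belief(belief, obs)
    return ExposureTrajectory(steps=tuple(steps))
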