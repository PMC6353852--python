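"""Synthetic replica of the audiovisual-incongruity ERP experiment.

The design is a 2x2 within-subject factorial: instrument familiarity
(familiar A / unfamiliar B) crossed with sound congruity (congruent X /
incongruent Y).  Familiarity sets the observer's prior uncertainty s_p about
the sound an instrument will make; congruity sets the prediction error delta
between the expected and the delivered sound.  Eight video stimuli (two
instruments per cell) are shown in randomized presentation sets with jittered
inter-stimulus intervals; each trial yields a 4-level Likert surprise rating
and a synthetic EEG epoch from which a P300 peak is extracted.

The forward ERP model per epoch is

    signal(t) = drift(t) + A * exp(-(t - t_peak)^2 / (2 w^2)) + noise(t)
    A = a0 + a1 * G(condition) + subject offset + subject-by-condition offset

with the P300 bump centred ~350 ms after the sound event (itself 500 ms after
video onset), band-limited background noise, and amplitude scaling linearly
with the model's information gain G.  Extraction then follows standard ERP
practice: baseline-correct on the 200 ms pre-onset window, reject epochs with
any raw sample beyond +/-100 uV, and take the largest positive peak 250-600 ms
after the sound.

Epoch timebase convention: sample i sits at t = -200 + 2*i ms for
i = 0..849 (500 Hz, half-open grid; the +1500 ms endpoint is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .crossover import crossover_point
from .errors import (
    ConfigurationError,
    EmptyGroupError,
    InvalidParameterError,
)
from .gain import information_gain

__all__ = [
    "StimulusCondition",
    "DEFAULT_STIMULI",
    "TrialSchedule",
    "ConditionMapping",
    "LikertConfig",
    "ErpConfig",
    "ErpEpoch",
    "P300Measurement",
    "ExperimentConfig",
    "ExperimentResult",
    "build_schedule",
    "condition_params",
    "simulate_likert",
    "synthesize_epoch",
    "simulate_erp_epochs",
    "extract_p300",
    "extract_p300_batch",
    "average_erp",
    "run_experiment",
]

FAMILIAR, UNFAMILIAR = "A", "B"
CONGRUENT, INCONGRUENT = "X", "Y"


@dataclass(frozen=True)
class StimulusCondition:
    """One video stimulus: an instrument and the sound that is played."""

    familiarity: str  # "A" familiar / "B" unfamiliar
    congruity: str  # "X" congruent / "Y" incongruent
    instrument_label: str

    def __post_init__(self) -> None:
        if self.familiarity not in (FAMILIAR, UNFAMILIAR):
            raise InvalidParameterError(f"familiarity must be A or B, got {self.familiarity!r}")
        if self.congruity not in (CONGRUENT, INCONGRUENT):
            raise InvalidParameterError(f"congruity must be X or Y, got {self.congruity!r}")

    @property
    def cell(self) -> str:
        return self.familiarity + self.congruity


# Default stimulus set: two familiar instruments (clave, hand drum), two
# unfamiliar (jawbone, slit drum), each paired with its own sound (congruent)
# and with a mismatched sound (incongruent) — 8 videos, 2 per cell.
DEFAULT_STIMULI: tuple[StimulusCondition, ...] = (
    StimulusCondition(FAMILIAR, CONGRUENT, "clave/clave"),
    StimulusCondition(FAMILIAR, CONGRUENT, "hand drum/hand drum"),
    StimulusCondition(FAMILIAR, INCONGRUENT, "clave/bell"),
    StimulusCondition(FAMILIAR, INCONGRUENT, "hand drum/guiro"),
    StimulusCondition(UNFAMILIAR, CONGRUENT, "jawbone/jawbone"),
    StimulusCondition(UNFAMILIAR, CONGRUENT, "slit drum/slit drum"),
    StimulusCondition(UNFAMILIAR, INCONGRUENT, "jawbone/vibraphone"),
    StimulusCondition(UNFAMILIAR, INCONGRUENT, "slit drum/snare"),
)


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial records for all subjects.

    ``trials`` columns: subject_id, trial_index (1-based within subject),
    presentation_set (1-based), familiarity, congruity, instrument, condition,
    isi_ms.  Within each presentation set every stimulus appears exactly once
    in randomized order.
    """

    trials: pd.DataFrame
    n_subjects: int
    n_sets: int
    stimuli: tuple[StimulusCondition, ...]
    isi_range_ms: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return self.trials.copy()

    def __len__(self) -> int:
        return len(self.trials)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise InvalidParameterError("an explicit seed is required for stochastic runs")
    return np.random.default_rng(seed)


def build_schedule(
    stimuli: Sequence[StimulusCondition] = DEFAULT_STIMULI,
    n_sets: int = 20,
    isi_range_ms: tuple[float, float] = (1000.0, 2000.0),
    n_subjects: int = 9,
    seed=None,
) -> TrialSchedule:
    """Randomized-block trial schedule: per subject, ``n_sets`` permutations
    of the stimulus list with ISIs drawn uniformly from ``isi_range_ms``.
    """
    stimuli = tuple(stimuli)
    if len(stimuli) == 0:
        raise InvalidParameterError("stimulus list must not be empty")
    if n_sets < 1 or n_subjects < 1:
        raise InvalidParameterError("n_sets and n_subjects must be >= 1")
    lo, hi = isi_range_ms
    if not (0 <= lo <= hi):
        raise InvalidParameterError(f"invalid ISI range {isi_range_ms!r}")
    rng = _as_rng(seed)

    rows = []
    n_stim = len(stimuli)
    for subject in range(1, n_subjects + 1):
        trial = 0
        for pset in range(1, n_sets + 1):
            order = rng.permutation(n_stim)
            isis = rng.uniform(lo, hi, size=n_stim)
            for j, idx in enumerate(order):
                trial += 1
                s = stimuli[idx]
                rows.append(
                    (subject, trial, pset, s.familiarity, s.congruity,
                     s.instrument_label, s.cell, isis[j])
                )
    trials = pd.DataFrame(
        rows,
        columns=["subject_id", "trial_index", "presentation_set", "familiarity",
                 "congruity", "instrument", "condition", "isi_ms"],
    )
    return TrialSchedule(
        trials=trials,
        n_subjects=n_subjects,
        n_sets=n_sets,
        stimuli=stimuli,
        isi_range_ms=(float(lo), float(hi)),
    )


@dataclass(frozen=True)
class ConditionMapping:
    """Maps the 2x2 design onto the model's (s_p, delta) plane.

    Familiarity manipulates uncertainty (unfamiliar > familiar); congruity
    manipulates prediction error (incongruent > congruent >= 0); a shared
    noise level s_l applies to every cell.  The defaults put the incongruent
    prediction error beyond the crossover point of the two uncertainty
    curves, which is exactly the regime where the interaction flips sign.
    """

    s_p_familiar: float = 0.2
    s_p_unfamiliar: float = 1.0
    delta_congruent: float = 0.0
    delta_incongruent: float = 2.0
    s_l: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.s_p_familiar, self.s_p_unfamiliar, self.s_l) <= 0:
            raise ConfigurationError("uncertainties and noise must be > 0")
        if not self.s_p_unfamiliar > self.s_p_familiar:
            raise ConfigurationError(
                "uncertainty ordering violated: s_p_unfamiliar must exceed "
                f"s_p_familiar (got {self.s_p_unfamiliar!r} <= {self.s_p_familiar!r})"
            )
        if not (self.delta_incongruent > self.delta_congruent >= 0):
            raise ConfigurationError(
                "prediction-error ordering violated: need "
                "delta_incongruent > delta_congruent >= 0 "
                f"(got {self.delta_incongruent!r}, {self.delta_congruent!r})"
            )
        cp = crossover_point(self.s_p_familiar, self.s_p_unfamiliar, self.s_l)
        if not cp.exists:
            raise ConfigurationError(
                "no crossover exists for this mapping (s_p_familiar * "
                "s_p_unfamiliar <= s_l**2); the design cannot produce the "
                "crossover pattern"
            )
        if not self.delta_incongruent > cp.delta_star:
            raise ConfigurationError(
                f"delta_incongruent ({self.delta_incongruent!r}) must exceed the "
                f"crossover point delta* = {cp.delta_star:.6g}"
            )

    def crossover_delta(self) -> float:
        return crossover_point(self.s_p_familiar, self.s_p_unfamiliar, self.s_l).delta_star

    def gain_table(self) -> dict[str, float]:
        """Model-predicted information gain per design cell (AX, AY, BX, BY)."""
        out = {}
        for fam in (FAMILIAR, UNFAMILIAR):
            for cong in (CONGRUENT, INCONGRUENT):
                s_p, delta = condition_params(
                    StimulusCondition(fam, cong, "-"), self
                )
                out[fam + cong] = information_gain(delta, s_p, self.s_l).gain
        return out


def condition_params(
    cond: StimulusCondition, mapping: ConditionMapping = ConditionMapping()
) -> tuple[float, float]:
    """Deterministic lookup of (uncertainty s_p, prediction error delta)."""
    s_p = mapping.s_p_familiar if cond.familiarity == FAMILIAR else mapping.s_p_unfamiliar
    delta = (
        mapping.delta_congruent if cond.congruity == CONGRUENT else mapping.delta_incongruent
    )
    return s_p, delta


@dataclass(frozen=True)
class LikertConfig:
    """4-level Likert surprise-rating generator.

    The latent surprise is ``intercept + slope * G + subject effect + noise``
    and is discretized by the fixed, equally spaced cut points.  With the
    default condition mapping the noise-free latent values per cell are
    AX ~1.2, BX ~1.7, BY ~3.4, AY ~5.7, i.e. ratings 1, 2, 3, 4.
    """

    intercept: float = 1.0
    slope: float = 1.0  # rating units per nat of gain
    response_noise_sd: float = 0.5
    subject_sd: float = 0.3
    cutpoints: tuple[float, float, float] = (1.5, 2.5, 3.5)


def simulate_likert(
    schedule: TrialSchedule,
    mapping: ConditionMapping = ConditionMapping(),
    config: LikertConfig = LikertConfig(),
    seed=None,
) -> pd.DataFrame:
    """Per-trial ratings in {1..4}; reproducible given the seed.

    Returns the schedule's trial table with latent and rating columns added.
    """
    if config.response_noise_sd < 0 or config.subject_sd < 0:
        raise InvalidParameterError("noise standard deviations must be >= 0")
    stochastic = config.response_noise_sd > 0 or config.subject_sd > 0
    rng = _as_rng(seed) if (stochastic or seed is not None) else np.random.default_rng(0)

    gains = mapping.gain_table()
    trials = schedule.trials
    g = trials["condition"].map(gains).to_numpy()

    subj_ids = np.sort(trials["subject_id"].unique())
    offsets = dict(zip(subj_ids, rng.normal(0.0, config.subject_sd, size=len(subj_ids))))
    subj_eff = trials["subject_id"].map(offsets).to_numpy()
    noise = rng.normal(0.0, config.response_noise_sd, size=len(trials))

    latent = config.intercept + config.slope * g + subj_eff + noise
    rating = np.ones(len(trials), dtype=int)
    for c in config.cutpoints:
        rating += (latent > c).astype(int)

    out = trials.copy()
    out["gain"] = g
    out["latent_surprise"] = latent
    out["rating"] = rating
    return out


@dataclass(frozen=True)
class ErpConfig:
    """Forward model and extraction parameters for synthetic ERP epochs.

    Times are in ms relative to video onset; the percussive sound occurs at
    ``sound_onset_ms``.  Amplitudes are in uV.
    """

    fs_hz: float = 500.0
    t_start_ms: float = -200.0
    t_stop_ms: float = 1500.0  # exclusive endpoint
    sound_onset_ms: float = 500.0
    channel_label: str = "Pz"

    p300_latency_mean_ms: float = 350.0  # post-sound
    p300_latency_sd_ms: float = 20.0
    p300_width_ms: float = 50.0
    amplitude_base_uv: float = 4.0  # a0
    amplitude_per_nat_uv: float = 2.0  # a1, uV per nat of information gain
    noise_sd_uv: float = 2.0
    noise_smooth_ms: float = 8.0  # Gaussian smoothing of the background noise
    drift_uv: float = 0.0  # linear drift from 0 to this value over the epoch
    subject_sd_uv: float = 1.0
    subject_condition_sd_uv: float = 0.8

    artifact_threshold_uv: float = 100.0
    search_window_ms: tuple[float, float] = (250.0, 600.0)  # post-sound
    baseline_ms: float = 200.0  # pre-onset baseline length

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.p300_width_ms <= 0:
            raise ConfigurationError("fs_hz and p300_width_ms must be > 0")
        if self.noise_sd_uv < 0 or self.p300_latency_sd_ms < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        lo, hi = self.search_window_ms
        if not (self.t_start_ms <= self.sound_onset_ms + lo
                and self.sound_onset_ms + hi < self.t_stop_ms):
            raise ConfigurationError("P300 search window falls outside the epoch")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def n_samples(self) -> int:
        # half-open grid: t_stop itself excluded
        return int(round((self.t_stop_ms - self.t_start_ms) / self.dt_ms))

    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + self.dt_ms * np.arange(self.n_samples)

    def window_indices(self) -> tuple[int, int]:
        """Inclusive index range of the post-sound search window."""
        t = self.times_ms()
        lo = self.sound_onset_ms + self.search_window_ms[0]
        hi = self.sound_onset_ms + self.search_window_ms[1]
        idx = np.nonzero((t >= lo) & (t <= hi))[0]
        if len(idx) == 0:
            raise InvalidParameterError("search window contains no samples")
        return int(idx[0]), int(idx[-1])

    def baseline_indices(self) -> np.ndarray:
        t = self.times_ms()
        return np.nonzero((t >= -self.baseline_ms) & (t < 0.0))[0]


@dataclass(frozen=True)
class ErpEpoch:
    """One synthetic EEG epoch (uV) on the config's fixed timebase."""

    samples: np.ndarray
    config: ErpConfig = field(default_factory=ErpConfig)
    channel_label: str = "Pz"

    def __post_init__(self) -> None:
        if len(self.samples) != self.config.n_samples:
            raise InvalidParameterError(
                f"epoch must have {self.config.n_samples} samples, "
                f"got {len(self.samples)}"
            )

    def times_ms(self) -> np.ndarray:
        return self.config.times_ms()


@dataclass(frozen=True)
class P300Measurement:
    """Extracted P300 peak; amplitude/latency are undefined when rejected."""

    amplitude_uv: Optional[float]
    latency_ms: Optional[float]  # relative to the sound onset
    rejected: bool


def _noise_scale(config: ErpConfig) -> float:
    """Std-dev shrinkage factor of Gaussian smoothing applied to white noise."""
    sigma = config.noise_smooth_ms / config.dt_ms
    if sigma <= 0:
        return 1.0
    impulse = np.zeros(max(int(8 * sigma) + 1, 9))
    impulse[len(impulse) // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma)
    return float(np.sqrt(np.sum(kernel**2)))


def _synthesize_batch(
    gains: np.ndarray,
    amp_offsets: np.ndarray,
    latencies_ms: np.ndarray,
    config: ErpConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized epoch synthesis for ``len(gains)`` trials."""
    t = config.times_ms()
    n_trials = len(gains)
    amp = config.amplitude_base_uv + config.amplitude_per_nat_uv * gains + amp_offsets
    centre = config.sound_onset_ms + latencies_ms
    bump = amp[:, None] * np.exp(
        -((t[None, :] - centre[:, None]) ** 2) / (2.0 * config.p300_width_ms**2)
    )
    epochs = bump
    if config.drift_uv != 0.0:
        frac = (t - t[0]) / (t[-1] - t[0])
        epochs = epochs + config.drift_uv * frac[None, :]
    if config.noise_sd_uv > 0:
        noise = rng.standard_normal((n_trials, config.n_samples))
        sigma = config.noise_smooth_ms / config.dt_ms
        if sigma > 0:
            noise = gaussian_filter1d(noise, sigma, axis=1)
            noise /= _noise_scale(config)
        epochs = epochs + config.noise_sd_uv * noise
    return epochs


def synthesize_epoch(
    trial=None,
    G: float = 0.0,
    config: ErpConfig = ErpConfig(),
    seed=None,
) -> ErpEpoch:
    """Synthesize a single epoch for one trial with information gain ``G``.

    The P300 latency is drawn from N(latency mean, latency sd) under the
    seed (deterministic when the sd is zero); subject-level offsets are not
    applied at this granularity — use :func:`simulate_erp_epochs` for a full
    schedule.  ``trial`` is accepted for symmetry with the batch path and may
    carry a per-trial record; it does not alter the forward model.
    """
    stochastic = config.noise_sd_uv > 0 or config.p300_latency_sd_ms > 0
    rng = _as_rng(seed) if (stochastic or seed is not None) else np.random.default_rng(0)
    lat = config.p300_latency_mean_ms
    if config.p300_latency_sd_ms > 0:
        lat = float(rng.normal(lat, config.p300_latency_sd_ms))
    lo, hi = config.search_window_ms
    lat = float(np.clip(lat, lo + 10.0, hi - 10.0))
    samples = _synthesize_batch(
        np.array([G]), np.zeros(1), np.array([lat]), config, rng
    )[0]
    return ErpEpoch(samples=samples, config=config, channel_label=config.channel_label)


def simulate_erp_epochs(
    schedule: TrialSchedule,
    mapping: ConditionMapping = ConditionMapping(),
    config: ErpConfig = ErpConfig(),
    seed=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize epochs for every trial of a schedule (vectorized).

    Returns ``(epochs, info)`` where ``epochs`` is a (n_trials, n_samples)
    uV matrix in schedule order and ``info`` is the trial table with the
    per-trial gain, amplitude offset and latency appended.  Reproducible
    given the seed: draws happen in a fixed order (subject offsets,
    subject-by-condition offsets, latencies, background noise).
    """
    rng = _as_rng(seed)
    trials = schedule.trials
    gains_by_cell = mapping.gain_table()
    g = trials["condition"].map(gains_by_cell).to_numpy()

    subj_ids = np.sort(trials["subject_id"].unique())
    cells = sorted(trials["condition"].unique())
    subj_off = dict(zip(subj_ids, rng.normal(0.0, config.subject_sd_uv, len(subj_ids))))
    sc_off = {
        (s, c): v
        for (s, c), v in zip(
            [(s, c) for s in subj_ids for c in cells],
            rng.normal(0.0, config.subject_condition_sd_uv, len(subj_ids) * len(cells)),
        )
    }
    amp_off = np.array(
        [
            subj_off[s] + sc_off[(s, c)]
            for s, c in zip(trials["subject_id"], trials["condition"])
        ]
    )
    lat = rng.normal(config.p300_latency_mean_ms, config.p300_latency_sd_ms, len(trials))
    lo, hi = config.search_window_ms
    lat = np.clip(lat, lo + 10.0, hi - 10.0)

    epochs = _synthesize_batch(g, amp_off, lat, config, rng)
    info = trials.copy()
    info["gain"] = g
    info["amplitude_offset_uv"] = amp_off
    info["p300_latency_true_ms"] = lat
    return epochs, info


def extract_p300(epoch: ErpEpoch) -> P300Measurement:
    """Baseline-correct, artifact-reject and peak-pick a single epoch.

    Baseline is the mean over the 200 ms pre-onset window; any raw sample
    beyond the +/-100 uV artifact threshold rejects the epoch; otherwise the
    amplitude is the maximum of the corrected signal 250-600 ms after the
    sound and the latency is the time of that maximum (earliest sample wins
    ties).
    """
    table = extract_p300_batch(epoch.samples[None, :], epoch.config)
    row = table.iloc[0]
    if row["rejected"]:
        return P300Measurement(None, None, True)
    return P300Measurement(float(row["amplitude_uv"]), float(row["latency_ms"]), False)


def extract_p300_batch(epochs: np.ndarray, config: ErpConfig = ErpConfig()) -> pd.DataFrame:
    """Vectorized P300 extraction; one row per epoch.

    Columns: amplitude_uv, latency_ms (post-sound; NaN when rejected),
    rejected.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2 or epochs.shape[1] != config.n_samples:
        raise InvalidParameterError(
            f"epochs must be (n, {config.n_samples}), got {epochs.shape}"
        )
    base_idx = config.baseline_indices()
    baseline = epochs[:, base_idx].mean(axis=1)
    corrected = epochs - baseline[:, None]
    rejected = np.abs(epochs).max(axis=1) > config.artifact_threshold_uv

    i0, i1 = config.window_indices()
    window = corrected[:, i0 : i1 + 1]
    # argmax returns the first (earliest) index among ties
    peak_idx = window.argmax(axis=1)
    amplitude = window[np.arange(len(epochs)), peak_idx]
    t = config.times_ms()
    latency = t[i0 + peak_idx] - config.sound_onset_ms

    out = pd.DataFrame(
        {
            "amplitude_uv": np.where(rejected, np.nan, amplitude),
            "latency_ms": np.where(rejected, np.nan, latency),
            "rejected": rejected,
        }
    )
    return out


def average_erp(
    epochs: np.ndarray,
    trials: pd.DataFrame,
    group_keys: Sequence[str],
    config: ErpConfig = ErpConfig(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Grand-mean waveforms per group, excluding artifact-rejected epochs.

    Returns ``(means, counts)``: ``means`` has one row per group (indexed by
    the group keys) and one column per time sample; ``counts`` reports group
    sizes after rejection.  A group left empty by rejection raises
    :class:`EmptyGroupError`.
    """
    epochs = np.asarray(epochs, dtype=float)
    if len(epochs) != len(trials):
        raise InvalidParameterError("epochs and trials must have equal length")
    rejected = np.abs(epochs).max(axis=1) > config.artifact_threshold_uv

    keys = list(group_keys)
    groups = trials.groupby(keys, sort=True).indices
    means = {}
    counts = {}
    for name, idx in groups.items():
        keep = np.asarray(idx)[~rejected[np.asarray(idx)]]
        if len(keep) == 0:
            raise EmptyGroupError(f"group {name!r} has no epochs after rejection")
        means[name] = epochs[keep].mean(axis=0)
        counts[name] = len(keep)
    mean_df = pd.DataFrame.from_dict(means, orient="index")
    mean_df.columns = config.times_ms()
    if len(keys) > 1:
        mean_df.index = pd.MultiIndex.from_tuples(mean_df.index, names=keys)
    else:
        mean_df.index.name = keys[0]
    return mean_df, pd.Series(counts, name="n")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full design of one synthetic run of the main video session."""

    n_subjects: int = 9
    n_sets: int = 20
    stimuli: tuple[StimulusCondition, ...] = DEFAULT_STIMULI
    isi_range_ms: tuple[float, float] = (1000.0, 2000.0)
    mapping: ConditionMapping = field(default_factory=ConditionMapping)
    likert: LikertConfig = field(default_factory=LikertConfig)
    erp: ErpConfig = field(default_factory=ErpConfig)


@dataclass
class ExperimentResult:
    """Everything one simulated session produced."""

    config: ExperimentConfig
    seed: int
    schedule: TrialSchedule
    ratings: pd.DataFrame
    p300: pd.DataFrame  # trial table + amplitude_uv, latency_ms, rejected
    epochs: Optional[np.ndarray] = None

    def p300_cell_table(self) -> pd.DataFrame:
        """Per-subject cell means of P300 amplitude (long format for ANOVA)."""
        ok = self.p300[~self.p300["rejected"]]
        out = (
            ok.groupby(["subject_id", "familiarity", "congruity"], sort=True)[
                "amplitude_uv"
            ]
            .mean()
            .reset_index()
            .rename(columns={"amplitude_uv": "value"})
        )
        return out

    def likert_cell_table(self) -> pd.DataFrame:
        """Per-subject cell means of the Likert surprise ratings."""
        out = (
            self.ratings.groupby(["subject_id", "familiarity", "congruity"], sort=True)[
                "rating"
            ]
            .mean()
            .reset_index()
            .rename(columns={"rating": "value"})
        )
        return out


def run_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    seed: int | None = None,
    keep_epochs: bool = False,
) -> ExperimentResult:
    """Simulate one full session: schedule -> ratings + epochs -> P300 table.

    All randomness flows from ``seed`` through independent child streams for
    the schedule, the ratings and the EEG, so e.g. changing the Likert noise
    does not perturb the EEG draw.
    """
    if seed is None:
        raise InvalidParameterError("run_experiment requires an explicit seed")
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_likert, rng_erp = (np.random.default_rng(s) for s in ss.spawn(3))

    schedule = build_schedule(
        stimuli=config.stimuli,
        n_sets=config.n_sets,
        isi_range_ms=config.isi_range_ms,
        n_subjects=config.n_subjects,
        seed=rng_sched,
    )
    ratings = simulate_likert(schedule, config.mapping, config.likert, seed=rng_likert)
    epochs, info = simulate_erp_epochs(schedule, config.mapping, config.erp, seed=rng_erp)
    peaks = extract_p300_batch(epochs, config.erp)
    p300 = pd.concat([info.reset_index(drop=True), peaks], axis=1)
    return ExperimentResult(
        config=config,
        seed=seed,
        schedule=schedule,
        ratings=ratings,
        p300=p300,
        epochs=epochs if keep_epochs else None,
    )
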