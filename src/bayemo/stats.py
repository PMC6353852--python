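"""Within-subject factorial ANOVA and the crossover-pattern detector.

Implements the two-way repeated-measures ANOVA used to analyze the 2x2
(familiarity x congruity) design: each effect is tested against its own
subject-by-effect error stratum,

    F_A  = MS_A  / MS_{A x S},   F_B = MS_B / MS_{B x S},
    F_AB = MS_AB / MS_{A x B x S},

with sums of squares computed from cell and marginal means of the balanced
(subject x cell) table.  Multiple trials per cell are averaged per subject
first (standard ERP practice).  No sphericity correction is applied: in a
2x2 design every within factor has a single degree of freedom, so the
correction is moot.  Simple main effects are one-way within-subject ANOVAs
on each slice, using the per-slice error stratum.

The crossover-pattern detector encodes the model's qualitative prediction
for the 2x2 cell means: unfamiliar > familiar under congruent sounds, and
familiar > unfamiliar under incongruent sounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    InvalidParameterError,
    UnbalancedDesignError,
)

__all__ = [
    "AnovaResult",
    "PatternResult",
    "two_way_rm_anova",
    "simple_main_effects",
    "detect_crossover_pattern",
]


@dataclass(frozen=True)
class AnovaResult:
    """One F test: effect and error sums of squares, df, F and p."""

    effect_name: str
    ss_effect: float
    ss_error: float
    df_num: int
    df_den: int
    f_value: float
    p_value: float


def _f_test(name: str, ss_eff: float, df_num: int, ss_err: float, df_den: int) -> AnovaResult:
    # Degenerate error stratum: zero residual variance.  A nonzero effect over
    # a zero error is reported as F = inf, p = 0; a zero effect over zero
    # error is undefined (F = nan, p = nan).
    if ss_err <= 0.0:
        if ss_eff > 0.0:
            f, p = math.inf, 0.0
        else:
            f, p = math.nan, math.nan
    else:
        f = (ss_eff / df_num) / (ss_err / df_den)
        p = float(sps.f.sf(f, df_num, df_den))
    return AnovaResult(name, float(ss_eff), float(ss_err), df_num, df_den, f, p)


def _pivot_balanced(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factors: Sequence[str],
) -> tuple[np.ndarray, list, list[list]]:
    """Average trials per cell and pivot to a dense (subject, levels...) array.

    Raises :class:`UnbalancedDesignError` if any subject x cell combination is
    missing.
    """
    for col in (dv, subject, *factors):
        if col not in data.columns:
            raise InvalidParameterError(f"column {col!r} missing from data")
    cell = data.groupby([subject, *factors], sort=True)[dv].mean()
    subjects = sorted(data[subject].unique())
    levels = [sorted(data[f].unique()) for f in factors]
    full = pd.MultiIndex.from_product([subjects, *levels], names=[subject, *factors])
    if len(cell) != len(full) or cell.index.difference(full).size or full.difference(cell.index).size:
        missing = full.difference(cell.index)
        raise UnbalancedDesignError(
            f"design is unbalanced: {len(missing)} missing subject x cell "
            f"combinations (first: {list(missing[:3])})"
        )
    arr = cell.reindex(full).to_numpy().reshape(len(subjects), *map(len, levels))
    return arr, subjects, levels


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    factors: Sequence[str] = ("familiarity", "congruity"),
) -> list[AnovaResult]:
    """Two-way within-subjects ANOVA: main effects of both factors and their
    interaction, each against its subject-by-effect error stratum.

    ``data`` is long format; multiple rows per subject x cell are averaged
    before the analysis.  Requires a fully balanced design with >= 2 subjects
    and >= 2 levels per factor.
    """
    fa, fb = factors
    Y, subjects, (la, lb) = _pivot_balanced(data, dv, subject, factors)
    nS, nA, nB = Y.shape
    if nS < 2 or nA < 2 or nB < 2:
        raise InvalidParameterError(
            f"need >= 2 subjects and >= 2 levels per factor, got {Y.shape}"
        )

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))  # per subject
    m_a = Y.mean(axis=(0, 2))  # per A level
    m_b = Y.mean(axis=(0, 1))  # per B level
    m_sa = Y.mean(axis=2)  # subject x A
    m_sb = Y.mean(axis=1)  # subject x B
    m_ab = Y.mean(axis=0)  # A x B

    ss_a = nS * nB * np.sum((m_a - grand) ** 2)
    ss_b = nS * nA * np.sum((m_b - grand) ** 2)
    ss_ab = nS * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = nB * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = nA * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    return [
        _f_test(fa, ss_a, nA - 1, ss_as, (nA - 1) * (nS - 1)),
        _f_test(fb, ss_b, nB - 1, ss_bs, (nB - 1) * (nS - 1)),
        _f_test(
            f"{fa} x {fb}",
            ss_ab,
            (nA - 1) * (nB - 1),
            ss_abs,
            (nA - 1) * (nB - 1) * (nS - 1),
        ),
    ]


def _one_way_rm(Y: np.ndarray, name: str) -> AnovaResult:
    """One-way within-subjects ANOVA on a (subjects, levels) array."""
    nS, nA = Y.shape
    if np.ptp(Y) == 0.0:
        raise DegenerateDataError(f"slice {name!r} has zero variance")
    grand = Y.mean()
    m_s = Y.mean(axis=1)
    m_a = Y.mean(axis=0)
    ss_eff = nS * np.sum((m_a - grand) ** 2)
    ss_err = np.sum((Y - m_s[:, None] - m_a[None, :] + grand) ** 2)
    return _f_test(name, ss_eff, nA - 1, ss_err, (nA - 1) * (nS - 1))


def simple_main_effects(
    data: pd.DataFrame,
    of_factor: str,
    at_factor: str,
    dv: str = "value",
    subject: str = "subject_id",
) -> dict[str, AnovaResult]:
    """Simple main effect of ``of_factor`` at each level of ``at_factor``.

    Per-slice error strata: each level's test is a one-way within-subjects
    ANOVA of the sliced sub-table.  A zero-variance slice raises
    :class:`DegenerateDataError`.
    """
    Y, subjects, (lof, lat) = _pivot_balanced(data, dv, subject, (of_factor, at_factor))
    out: dict[str, AnovaResult] = {}
    for j, level in enumerate(lat):
        out[level] = _one_way_rm(Y[:, :, j], f"{of_factor} at {at_factor}={level}")
    return out


@dataclass(frozen=True)
class PatternResult:
    """Outcome of the crossover-pattern check on 2x2 cell means."""

    detected: bool
    tie: bool = False

    def __bool__(self) -> bool:
        return self.detected


def detect_crossover_pattern(
    cell_means: Mapping[tuple[str, str], float] | pd.DataFrame,
) -> PatternResult:
    """True iff mean(B,X) > mean(A,X) and mean(A,Y) > mean(B,Y).

    ``cell_means`` maps (familiarity, congruity) -> mean, with familiarity in
    {A, B} and congruity in {X, Y}; a DataFrame with those index/columns is
    also accepted.  Any tie in either comparison yields
    ``PatternResult(False, tie=True)``.
    """
    if isinstance(cell_means, pd.DataFrame):
        cm = {
            (f, c): float(cell_means.loc[f, c])
            for f in ("A", "B")
            for c in ("X", "Y")
        }
    else:
        cm = {k: float(v) for k, v in cell_means.items()}
    try:
        ax, bx = cm[("A", "X")], cm[("B", "X")]
        ay, by = cm[("A", "Y")], cm[("B", "Y")]
    except KeyError as e:
        raise InvalidParameterError(f"missing cell mean for {e.args[0]!r}") from e
    for v in (ax, bx, ay, by):
        if not math.isfinite(v):
            raise InvalidParameterError("cell means must be finite")
    if bx == ax or ay == by:
        return PatternResult(False, tie=True)
    return PatternResult(bx > ax and ay > by)
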