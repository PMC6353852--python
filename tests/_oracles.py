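"""Independent numerical oracles used by the test suite.

Everything here deliberately avoids the package's closed forms: posterior
moments come from normalizing a product of densities on a dense grid, KL
divergences and entropies from adaptive quadrature, crossovers from
sign-change scans plus root bracketing, and ANOVA sums of squares from the
definitional mean-deviation formulas computed with explicit loops.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from bayemo.gain import gain_coefficients


def grid_posterior_moments(
    prior_mean: float,
    prior_var: float,
    sample_mean: float,
    s_l: float,
    n_grid: int = 200_001,
    half_width_sds: float = 12.0,
) -> tuple[float, float]:
    """Mean/variance of the normalized product of prior and likelihood
    densities, by brute-force grid integration."""
    sd = math.sqrt(max(prior_var, s_l))
    centre = 0.5 * (prior_mean + sample_mean)
    span = half_width_sds * sd + abs(sample_mean - prior_mean)
    x = np.linspace(centre - span, centre + span, n_grid)
    unnorm = norm.pdf(x, prior_mean, math.sqrt(prior_var)) * norm.pdf(
        x, sample_mean, math.sqrt(s_l)
    )
    w = unnorm / np.trapezoid(unnorm, x)
    mean = np.trapezoid(w * x, x)
    var = np.trapezoid(w * (x - mean) ** 2, x)
    return float(mean), float(var)


def quad_kl(p_mean: float, p_var: float, q_mean: float, q_var: float) -> float:
    """KL divergence D(p||q) by adaptive quadrature of p * ln(p/q)."""
    p_sd, q_sd = math.sqrt(p_var), math.sqrt(q_var)

    def integrand(x: float) -> float:
        p = norm.pdf(x, p_mean, p_sd)
        if p == 0.0:
            return 0.0
        q = norm.pdf(x, q_mean, q_sd)
        return p * math.log(p / q)

    lo = min(p_mean - 12 * p_sd, q_mean - 12 * q_sd)
    hi = max(p_mean + 12 * p_sd, q_mean + 12 * q_sd)
    value, _ = quad(integrand, lo, hi, limit=200)
    return value


def quad_entropy(mean: float, var: float) -> float:
    """Differential entropy by quadrature of -p * ln(p)."""
    sd = math.sqrt(var)

    def integrand(x: float) -> float:
        p = norm.pdf(x, mean, sd)
        return 0.0 if p == 0.0 else -p * math.log(p)

    value, _ = quad(integrand, mean - 14 * sd, mean + 14 * sd, limit=200)
    return value


def gain_difference(delta, s_p1: float, s_p2: float, s_l: float):
    a1, b1 = gain_coefficients(s_p1, s_l)
    a2, b2 = gain_coefficients(s_p2, s_l)
    return (a1 - a2) * np.square(delta) + (b1 - b2)


def scan_crossover(
    s_p1: float, s_p2: float, s_l: float, delta_max: float = 50.0, n: int = 200_001
) -> bool:
    """Existence of a sign change of G1 - G2 over delta in (0, delta_max]."""
    grid = np.linspace(0.0, delta_max, n)
    diff = gain_difference(grid, s_p1, s_p2, s_l)
    signs = np.sign(diff)
    return bool(np.any(signs[1:] * signs[:-1] < 0) or np.any(diff[1:] == 0.0))


def bisect_crossover(
    s_p1: float, s_p2: float, s_l: float, delta_max: float = 50.0
) -> float:
    """Locate the positive root of G1 - G2 by scan bracketing + brentq."""
    grid = np.linspace(0.0, delta_max, 200_001)
    diff = gain_difference(grid, s_p1, s_p2, s_l)
    idx = np.nonzero(np.sign(diff[1:]) * np.sign(diff[:-1]) < 0)[0]
    if len(idx) == 0:
        raise ValueError("no sign change in scan range")
    i = int(idx[0])
    return float(
        brentq(
            lambda d: gain_difference(d, s_p1, s_p2, s_l),
            grid[i],
            grid[i + 1],
            xtol=1e-12,
        )
    )


def grid_argmax(fn, lo: float, hi: float, n: int = 100_001) -> float:
    """Two-stage pure grid search: coarse scan over [lo, hi], then an equally
    dense fine scan over the bracketing interval.  Final resolution is
    ((hi-lo)/n) * (2/n) — far below 1e-6 for the intervals used here."""
    grid = np.linspace(lo, hi, n)
    i = int(np.argmax(fn(grid)))
    flo, fhi = grid[max(i - 1, 0)], grid[min(i + 1, n - 1)]
    fine = np.linspace(flo, fhi, n)
    return float(fine[int(np.argmax(fn(fine)))])


def brute_force_rm_ss(data: pd.DataFrame) -> dict[str, float]:
    """Definitional sums of squares of the fully-crossed within design,
    computed with explicit loops over subjects and factor levels."""
    subjects = sorted(data["subject_id"].unique())
    la = sorted(data["familiarity"].unique())
    lb = sorted(data["congruity"].unique())

    def cell(s, a, b) -> float:
        sel = data[
            (data["subject_id"] == s)
            & (data["familiarity"] == a)
            & (data["congruity"] == b)
        ]["value"]
        return float(sel.mean())

    Y = {(s, a, b): cell(s, a, b) for s in subjects for a in la for b in lb}
    nS, nA, nB = len(subjects), len(la), len(lb)
    grand = sum(Y.values()) / len(Y)
    m_s = {s: sum(Y[(s, a, b)] for a in la for b in lb) / (nA * nB) for s in subjects}
    m_a = {a: sum(Y[(s, a, b)] for s in subjects for b in lb) / (nS * nB) for a in la}
    m_b = {b: sum(Y[(s, a, b)] for s in subjects for a in la) / (nS * nA) for b in lb}
    m_sa = {(s, a): sum(Y[(s, a, b)] for b in lb) / nB for s in subjects for a in la}
    m_sb = {(s, b): sum(Y[(s, a, b)] for a in la) / nA for s in subjects for b in lb}
    m_ab = {(a, b): sum(Y[(s, a, b)] for s in subjects) / nS for a in la for b in lb}

    ss = {
        "total": sum((y - grand) ** 2 for y in Y.values()),
        "subjects": nA * nB * sum((m - grand) ** 2 for m in m_s.values()),
        "A": nS * nB * sum((m - grand) ** 2 for m in m_a.values()),
        "B": nS * nA * sum((m - grand) ** 2 for m in m_b.values()),
        "AB": nS
        * sum(
            (m_ab[(a, b)] - m_a[a] - m_b[b] + grand) ** 2 for a in la for b in lb
        ),
        "AS": nB
        * sum(
            (m_sa[(s, a)] - m_s[s] - m_a[a] + grand) ** 2
            for s in subjects
            for a in la
        ),
        "BS": nA
        * sum(
            (m_sb[(s, b)] - m_s[s] - m_b[b] + grand) ** 2
            for s in subjects
            for b in lb
        ),
    }
    ss["ABS"] = sum(
        (
            Y[(s, a, b)]
            - m_sa[(s, a)]
            - m_sb[(s, b)]
            - m_ab[(a, b)]
            + m_s[s]
            + m_a[a]
            + m_b[b]
            - grand
        )
        ** 2
        for s in subjects
        for a in la
        for b in lb
    )
    return ss
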