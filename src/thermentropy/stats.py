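"""Statistical layer: Spearman correlation (exact permutation p for small
n), repeated-measures one-way ANOVA across timepoints, and two-breakpoint
ventilatory-threshold detection on VE curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .timeline import GroupSeries

__all__ = [
    "CorrelationResult",
    "RMAnovaResult",
    "ThresholdResult",
    "spearman",
    "repeated_anova",
    "detect_ventilatory_thresholds",
    "correlate_feature_vs_time",
    "correlate_entropy_ve",
]

_EXACT_N_MAX = 8


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    method: str  # "exact-permutation" | "t-approximation"


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_time: int
    df_error: int
    p_value: float
    ss_time: float
    ss_subject: float
    ss_error: float
    degenerate: bool = False


@dataclass(frozen=True)
class ThresholdResult:
    """Two VE breakpoints as percent of exercise duration, from an
    exhaustive continuous three-segment piecewise-linear fit."""

    vt1_pct: float
    vt2_pct: float
    sse: float
    slopes: tuple[float, float, float]
    low_confidence: bool = False


def _check_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("inputs must be 1-D")
    return x


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a dual p-value rule.

    rho is the Pearson correlation of average-ranked values (ties receive
    mean ranks).  The p-value is an exact two-sided permutation probability
    (all n! rank orders) for n <= 8 and the t-distribution approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` otherwise.
    """
    x, y = _check_vector(x), _check_vector(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a Spearman p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_N_MAX:
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        if abs(rho) >= 1.0 - 1e-15:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return CorrelationResult(rho=rho, n=n, p_value=p, method=method)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: fraction of the n! permutations of the y ranks
    whose |rho| reaches |rho_obs| (tie-aware: ranks, not values, permute)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)))
    xc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(pc[0])
    rhos = pc @ xc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def repeated_anova(data) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects × timepoints
    matrix.

    SS_time = s * sum_j (m_j - m)^2, SS_subject = k * sum_i (m_i - m)^2,
    SS_error = SS_total - SS_time - SS_subject,
    F = (SS_time / (k-1)) / (SS_error / ((k-1)(s-1))).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a subjects × timepoints matrix")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    s, k = data.shape
    if s < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    grand = data.mean()
    m_time = data.mean(axis=0)
    m_subj = data.mean(axis=1)
    ss_time = s * float(np.sum((m_time - grand) ** 2))
    ss_subject = k * float(np.sum((m_subj - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_error = ss_total - ss_time - ss_subject
    df_time, df_error = k - 1, (k - 1) * (s - 1)
    tol = 1e-12 * max(1.0, ss_total)
    if ss_time <= tol:
        # no time effect at all (covers the all-equal matrix): F = 0
        return RMAnovaResult(0.0, df_time, df_error, 1.0, ss_time, ss_subject,
                             max(ss_error, 0.0), degenerate=ss_error <= tol)
    if ss_error <= tol:
        return RMAnovaResult(float("inf"), df_time, df_error, 0.0, ss_time,
                             ss_subject, max(ss_error, 0.0), degenerate=True)
    F = (ss_time / df_time) / (ss_error / df_error)
    p = float(sps.f.sf(F, df_time, df_error))
    return RMAnovaResult(float(F), df_time, df_error, p, ss_time, ss_subject, ss_error)


def _piecewise_design(t: np.ndarray, k1: float, k2: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(t), t, np.clip(t - k1, 0.0, None), np.clip(t - k2, 0.0, None)]
    )


def detect_ventilatory_thresholds(
    pct: np.ndarray, ve: np.ndarray, min_gap: int = 2
) -> ThresholdResult:
    """Locate the two VE breakpoints (VT1, VT2) on a percent-of-exercise
    grid by exhaustive search over ordered knot pairs at sample positions.

    For every candidate pair (each knot >= ``min_gap`` samples from the
    ends and from the other knot) a continuous three-segment piecewise
    linear model is fitted by least squares; the global-SSE minimizer wins,
    ties broken by the earliest (vt1, then vt2).  A non-increasing overall
    trend, or an SSE tie across placements, sets ``low_confidence``.
    """
    pct = _check_vector(pct)
    ve = _check_vector(ve)
    if pct.size != ve.size:
        raise ValueError("pct and ve must have equal length")
    n = pct.size
    if n < 8:
        raise ValueError(f"need >= 8 samples to place two breakpoints, got {n}")
    if pct[-1] - pct[0] < 50.0:
        raise ValueError("samples must span >= 50 percent of the exercise")
    best = None  # (sse, i, j, coefs)
    tied = False
    for i in range(min_gap, n - min_gap):
        for j in range(i + min_gap, n - min_gap):
            X = _piecewise_design(pct, pct[i], pct[j])
            coefs, _, _, _ = np.linalg.lstsq(X, ve, rcond=None)
            resid = ve - X @ coefs
            sse = float(resid @ resid)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, i, j, coefs)
                tied = False
            elif abs(sse - best[0]) <= 1e-12:
                tied = True
    assert best is not None
    sse, i, j, coefs = best
    b0, b1, b2, b3 = coefs
    slopes = (float(b1), float(b1 + b2), float(b1 + b2 + b3))
    trend_down = ve[-1] <= ve[0]
    return ThresholdResult(
        vt1_pct=float(pct[i]),
        vt2_pct=float(pct[j]),
        sse=sse,
        slopes=slopes,
        low_confidence=bool(tied or trend_down),
    )


def correlate_feature_vs_time(group: GroupSeries) -> CorrelationResult:
    """Spearman correlation of a group-mean trajectory against percent time."""
    return spearman(group.grid, group.mean)


def correlate_entropy_ve(entropy_group: GroupSeries, ve_group: GroupSeries) -> CorrelationResult:
    """Spearman correlation of group entropy against group VE on a shared grid."""
    if entropy_group.grid.shape != ve_group.grid.shape or not np.allclose(
        entropy_group.grid, ve_group.grid
    ):
        raise ValueError("entropy and VE group series must share the same grid")
    return spearman(entropy_group.mean, ve_group.mean)
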