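"""Percent-of-exhaustion time normalization and group aggregation.

Graded tests end at different times for different subjects, so per-subject
trajectories are rescaled to percent of exercise duration (test end =
100 %), resampled onto a common percent grid by linear interpolation, and
averaged pointwise across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FeatureSeries",
    "GroupSeries",
    "DEFAULT_GRID",
    "normalize_time",
    "resample_to_grid",
    "group_mean",
]

#: Common percent grid: 5 % steps from 5 to 100 (matches a ~30 s cadence
#: over a ~10 min test, i.e. about 20 exercise frames per subject).
DEFAULT_GRID = np.arange(5.0, 100.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class FeatureSeries:
    """One subject's trajectory of one feature in one ROI."""

    subject_id: str
    roi_label: str
    feature_name: str  # mean_temp | entropy | ve
    times_s: np.ndarray
    values: np.ndarray
    exercise_end_s: float
    pct_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass(frozen=True)
class GroupSeries:
    """Pointwise mean ± sd over subjects on a common percent grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    feature_name: str
    roi_label: str


def normalize_time(series: FeatureSeries) -> FeatureSeries:
    """Attach ``pct_time = 100 * t / exercise_end`` and drop post-exercise
    samples, so the last exercise sample maps to <= 100 %."""
    if series.exercise_end_s <= 0:
        raise ValueError("exercise duration must be positive")
    keep = series.times_s <= series.exercise_end_s + 1e-9
    t = series.times_s[keep]
    v = series.values[keep]
    pct = 100.0 * t / series.exercise_end_s
    return replace(series, times_s=t, values=v, pct_time=pct)


def resample_to_grid(series: FeatureSeries, grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """Linear interpolation of a normalized series onto ``grid`` (percent).

    Exact at sample points; grid points outside the observed percent range
    are an error (no extrapolation).
    """
    if series.pct_time is None:
        series = normalize_time(series)
    pct = series.pct_time
    if pct.size < 2:
        raise ValueError("need >= 2 samples to resample")
    grid = np.asarray(grid, dtype=float)
    lo, hi = pct[0], pct[-1]
    out_of_range = (grid < lo - 1e-9) | (grid > hi + 1e-9)
    if out_of_range.any():
        bad = grid[out_of_range]
        raise ValueError(
            f"grid points {bad.tolist()} outside observed percent range [{lo:.2f}, {hi:.2f}]"
        )
    return np.interp(grid, pct, series.values)


def group_mean(series_list: list[FeatureSeries], grid: np.ndarray = DEFAULT_GRID) -> GroupSeries:
    """Pointwise mean, sd (n−1 denominator; 0 when n = 1) and n across
    subjects resampled to the common grid.

    Grid points preceding a subject's first capture are dropped for that
    subject only; ``n`` tracks contributions per point.
    """
    if not series_list:
        raise ValueError("need at least one series")
    grid = np.asarray(grid, dtype=float)
    vals = np.full((len(series_list), grid.size), np.nan)
    for i, s in enumerate(series_list):
        if s.pct_time is None:
            s = normalize_time(s)
        pct = s.pct_time
        inside = (grid >= pct[0] - 1e-9) & (grid <= pct[-1] + 1e-9)
        if inside.any():
            vals[i, inside] = np.interp(grid[inside], pct, s.values)
    n = np.sum(~np.isnan(vals), axis=0)
    if (n < 1).any():
        raise ValueError("some grid points have no contributing subject")
    mean = np.nanmean(vals, axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # columns with n == 1
        sd = np.where(n > 1, np.nanstd(vals, axis=0, ddof=1), 0.0)
    first = series_list[0]
    return GroupSeries(
        grid=grid,
        mean=mean,
        sd=sd,
        n=n.astype(int),
        feature_name=first.feature_name,
        roi_label=first.roi_label,
    )
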