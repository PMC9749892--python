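"""Circadian locomotor analysis.

Chi-square (Sokolove-Bushell) periodogram with rhythmicity scoring, cohort
summaries, morning/evening anticipation indices, eduction profiles and
actogram matrices, all operating on 1-minute beam-crossing series.

The periodogram statistic for a candidate period of ``P`` bins folds the
series into ``K = floor(N/P)`` complete cycles (the incomplete final cycle
is trimmed), takes column means ``M_h`` and grand mean ``M`` over the
``N' = K*P`` retained bins, and computes

    Qp = K * sum_h (M_h - M)^2 / sigma^2,     sigma^2 = (1/N') sum (x - M)^2

which is referred to the chi-square quantile with ``P - 1`` degrees of
freedom.  A fly is scored rhythmic when the peak exceeds the alpha = 0.05
chi-square line AND peak power (Qp minus the line) is at least 20 AND the
contiguous supra-threshold span around the peak is at least 2 h; boundary
values pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .types import BINS_PER_DAY, ActivitySeries

__all__ = [
    "PeriodogramResult",
    "RhythmicityCriteria",
    "CohortRhythmicity",
    "AnticipationResult",
    "default_period_grid",
    "chi_square_periodogram",
    "classify_rhythmic",
    "cohort_summary",
    "anticipation_index",
    "eduction",
    "actogram_matrix",
]


def default_period_grid() -> np.ndarray:
    """Candidate periods 16-32 h in 0.1-h steps (1-min bin resolution)."""
    return np.round(np.arange(160, 321) * 0.1, 1)


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    chi2_threshold: np.ndarray
    alpha: float
    significant: bool
    tau_h: Optional[float] = None
    power: Optional[float] = None
    width_h: Optional[float] = None
    peak_index: Optional[int] = None
    degenerate_variance: bool = False


@dataclass(frozen=True)
class RhythmicityCriteria:
    """Scoring thresholds for calling a fly rhythmic in DD."""

    min_power: float = 20.0
    min_width_h: float = 2.0
    alpha: float = 0.05


@dataclass
class CohortRhythmicity:
    n: int
    n_rhythmic: int
    percent_rhythmic: float
    tau_mean: Optional[float] = None
    tau_sem: Optional[float] = None
    power_mean: Optional[float] = None
    power_sem: Optional[float] = None
    width_mean: Optional[float] = None
    width_sem: Optional[float] = None


@dataclass
class AnticipationResult:
    fly_id: str
    transition: str  # "morning" or "evening"
    ai: Optional[float]
    per_day_ai: List[float]
    days_used: int
    defined: bool


def _fold_qp(x: np.ndarray, p_bins: int) -> float:
    """Qp for one candidate period of ``p_bins`` bins (trim-fold-compare)."""
    k = x.size // p_bins
    xr = x[: k * p_bins]
    col_means = xr.reshape(k, p_bins).mean(axis=0)
    grand = xr.mean()
    var = np.mean((xr - grand) ** 2)
    if var == 0:
        return 0.0
    return float(k * np.sum((col_means - grand) ** 2) / var)


def chi_square_periodogram(
    series: ActivitySeries | np.ndarray,
    dd_only: bool = True,
    period_grid_h: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Chi-square periodogram of one fly's activity.

    Parameters
    ----------
    series:
        An :class:`~crylight.types.ActivitySeries` or a raw 1-min count
        array.
    dd_only:
        Use only the constant-darkness portion of the series (requires the
        schedule to carry ``dd_start_bin``); free-running period should not
        be estimated from entrained data.
    period_grid_h:
        Candidate periods in hours; default 16-32 h in 0.1-h steps.
        Periods are folded at the nearest whole number of 1-min bins.
    alpha:
        Significance level for the chi-square line.

    Raises
    ------
    ValueError
        If fewer than two complete cycles are available at the longest
        candidate period.
    """
    if isinstance(series, ActivitySeries):
        x = series.dd_counts() if dd_only else series.counts
        if dd_only and x.size == 0:
            raise ValueError(
                f"series {series.fly_id} has no DD segment (dd_only=True)"
            )
    else:
        x = np.asarray(series)
    x = x.astype(np.float64)
    if (x < 0).any():
        raise ValueError("activity counts must be nonnegative")
    grid = default_period_grid() if period_grid_h is None else \
        np.asarray(period_grid_h, dtype=float)
    p_bins = np.rint(grid * 60.0).astype(int)
    if (p_bins < 2).any():
        raise ValueError("candidate periods must span at least 2 bins")
    if x.size < 2 * p_bins.max():
        raise ValueError(
            f"need >= 2 complete cycles at the longest period "
            f"({2 * p_bins.max()} bins), have {x.size}"
        )

    threshold = sstats.chi2.ppf(1.0 - alpha, df=p_bins - 1)
    if np.ptp(x) == 0:
        qp = np.zeros(grid.size)
        return PeriodogramResult(
            periods_h=grid, qp=qp, chi2_threshold=threshold, alpha=alpha,
            significant=False, degenerate_variance=True,
        )

    qp = np.array([_fold_qp(x, p) for p in p_bins])
    excess = qp - threshold
    supra = excess > 0
    if not supra.any():
        return PeriodogramResult(
            periods_h=grid, qp=qp, chi2_threshold=threshold, alpha=alpha,
            significant=False,
        )
    peak = int(np.argmax(np.where(supra, excess, -np.inf)))
    lo = peak
    while lo > 0 and supra[lo - 1]:
        lo -= 1
    hi = peak
    while hi < grid.size - 1 and supra[hi + 1]:
        hi += 1
    step = float(np.median(np.diff(grid))) if grid.size > 1 else 0.1
    width = float(grid[hi] - grid[lo] + step)
    return PeriodogramResult(
        periods_h=grid, qp=qp, chi2_threshold=threshold, alpha=alpha,
        significant=True, tau_h=float(grid[peak]),
        power=float(excess[peak]), width_h=width, peak_index=peak,
    )


def classify_rhythmic(
    result: PeriodogramResult,
    criteria: RhythmicityCriteria = RhythmicityCriteria(),
) -> Tuple[bool, List[str]]:
    """Score one periodogram against the rhythmicity criteria.

    Returns the rhythmic flag plus the list of failed criteria
    (any of ``"significance"``, ``"power"``, ``"width"``).
    """
    failed: List[str] = []
    if not result.significant:
        failed.append("significance")
        return False, failed
    if result.power is None or result.power < criteria.min_power:
        failed.append("power")
    if result.width_h is None or result.width_h < criteria.min_width_h:
        failed.append("width")
    return (not failed), failed


def _mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def cohort_summary(
    results: Sequence[PeriodogramResult],
    criteria: RhythmicityCriteria = RhythmicityCriteria(),
) -> CohortRhythmicity:
    """Percent rhythmicity plus mean +/- SEM of tau/power/width over the
    rhythmic flies only."""
    if not results:
        raise ValueError("cohort_summary needs at least one fly")
    rhythmic = [r for r in results if classify_rhythmic(r, criteria)[0]]
    n = len(results)
    out = CohortRhythmicity(
        n=n, n_rhythmic=len(rhythmic),
        percent_rhythmic=100.0 * len(rhythmic) / n,
    )
    if rhythmic:
        out.tau_mean, out.tau_sem = _mean_sem([r.tau_h for r in rhythmic])
        out.power_mean, out.power_sem = _mean_sem(
            [r.power for r in rhythmic])
        out.width_mean, out.width_sem = _mean_sem(
            [r.width_h for r in rhythmic])
    return out


def _ld_transition_bins(series: ActivitySeries,
                        transition: str) -> np.ndarray:
    """Bin indices of the requested LD transition, oldest first, restricted
    to transitions whose 6-h look-back window lies inside the LD segment."""
    offset = series.zt0_offset_bins()
    if transition == "morning":
        first = offset
    elif transition == "evening":
        first = offset + int(round(series.schedule.photoperiod_h * 60))
    else:
        raise ValueError("transition must be 'morning' or 'evening'")
    ld_end = series.schedule.dd_start_bin
    if ld_end is None:
        ld_end = len(series)
    ts = np.arange(first, ld_end + 1, BINS_PER_DAY)
    return ts[ts >= 360]


def anticipation_index(
    series: ActivitySeries,
    transition: Literal["morning", "evening"],
    n_days: int = 5,
) -> AnticipationResult:
    """Anticipation index for one fly over the last ``n_days`` entrained
    days: mean activity in the 3 h before the light transition divided by
    mean activity in the 6 h before it, computed per day then averaged.

    Both windows end at, and exclude, the transition bin; a day with zero
    activity in its 6-h window is excluded; if all days are excluded the
    index is undefined (``defined=False``).  For nonnegative counts the
    index lies in [0, 2]: 1 means no ramping, 2 means all activity fell in
    the final 3 h.
    """
    ts = _ld_transition_bins(series, transition)
    if ts.size < n_days:
        raise ValueError(
            f"need {n_days} complete LD days with a full 6-h window before "
            f"each {transition} transition, have {ts.size}"
        )
    per_day: List[float] = []
    for t in ts[-n_days:]:
        w6 = series.counts[t - 360:t].astype(float)
        w3 = series.counts[t - 180:t].astype(float)
        if w6.sum() == 0:
            continue
        per_day.append(float(w3.mean() / w6.mean()))
    ai = float(np.mean(per_day)) if per_day else None
    return AnticipationResult(
        fly_id=series.fly_id, transition=transition, ai=ai,
        per_day_ai=per_day, days_used=len(per_day), defined=bool(per_day),
    )


def eduction(series: ActivitySeries,
             n_days: Optional[int] = None) -> np.ndarray:
    """Average daily activity profile: per-bin mean over whole days,
    aligned so that bin 0 is ZT0 (lights-on).

    A partial trailing day is trimmed with a warning.  ``n_days`` limits
    the average to the first that many whole days.
    """
    offset = series.zt0_offset_bins()
    x = series.counts[offset:]
    days = x.size // BINS_PER_DAY
    if days < 1:
        raise ValueError("eduction needs at least one whole day")
    if x.size % BINS_PER_DAY:
        warnings.warn("partial trailing day trimmed from eduction")
    if n_days is not None:
        days = min(days, n_days)
    return x[: days * BINS_PER_DAY].reshape(days, BINS_PER_DAY).mean(axis=0)


def actogram_matrix(series: ActivitySeries,
                    double_plot: bool = False) -> np.ndarray:
    """Days x 1440 matrix of daily activity rows (days x 2880 when
    double-plotted: each row is day d followed by day d+1)."""
    x = series.counts
    days = x.size // BINS_PER_DAY
    if days < 1:
        raise ValueError("actogram needs at least one whole day")
    m = x[: days * BINS_PER_DAY].reshape(days, BINS_PER_DAY).astype(float)
    if not double_plot:
        return m
    nxt = np.vstack([m[1:], np.full((1, BINS_PER_DAY), np.nan)])
    return np.hstack([m, nxt])
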