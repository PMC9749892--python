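"""Light attraction/avoidance preference analysis.

Preference in the two-environment assay is the percentage of a fly's
activity spent in each environment per 1-minute bin; bins with no
activity carry no positional information and are left undefined rather
than imputed as 50/50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import ChoiceSeries

__all__ = [
    "PreferenceResult",
    "CohortPreference",
    "preference_timeseries",
    "mean_percent_activity",
    "cohort_mean_percent",
]


@dataclass
class PreferenceResult:
    """Per-bin preference of one fly; NaN marks undefined (zero-activity)
    bins.  Where defined, lit + dark percentages sum to 100 exactly."""

    fly_id: str
    percent_lit: np.ndarray
    percent_dark: np.ndarray


@dataclass
class CohortPreference:
    n: int
    n_excluded: int
    mean_percent_lit: float
    sem_percent_lit: float
    per_fly_means: List[float]
    excluded_fly_ids: List[str]


def preference_timeseries(series: ChoiceSeries) -> PreferenceResult:
    """Percent activity in the lit environment per bin:
    ``100 * lit / (lit + dark)`` where the bin total is positive, NaN
    otherwise."""
    total = series.total_counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_lit = np.where(total > 0,
                           100.0 * series.lit_counts / total, np.nan)
    return PreferenceResult(series.fly_id, pct_lit, 100.0 - pct_lit)


def mean_percent_activity(
    result: PreferenceResult,
    window_min: int = 30,
) -> Optional[float]:
    """Per-fly mean percent-lit over the defined bins in the first
    ``window_min`` minutes, or None when every bin in the window is
    undefined (fly inactive)."""
    if window_min > result.percent_lit.size:
        raise ValueError(
            f"window of {window_min} min exceeds series length "
            f"{result.percent_lit.size}"
        )
    w = result.percent_lit[:window_min]
    defined = ~np.isnan(w)
    if not defined.any():
        return None
    return float(w[defined].mean())


def cohort_mean_percent(
    cohort: Sequence[ChoiceSeries],
    window_min: int = 30,
) -> CohortPreference:
    """Cohort mean +/- SEM of the per-fly window means; flies with no
    activity in the window are excluded and reported."""
    means: List[float] = []
    excluded: List[str] = []
    for s in cohort:
        m = mean_percent_activity(preference_timeseries(s), window_min)
        if m is None:
            excluded.append(s.fly_id)
        else:
            means.append(m)
    if not means:
        raise ValueError("no active flies in the analysis window")
    arr = np.asarray(means)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return CohortPreference(
        n=len(means), n_excluded=len(excluded),
        mean_percent_lit=float(arr.mean()), sem_percent_lit=sem,
        per_fly_means=means, excluded_fly_ids=excluded,
    )
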