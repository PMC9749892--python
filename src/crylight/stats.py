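"""Group-comparison statistical workflow.

Two-group contrasts are dispatched on normality: if both samples pass an
Anderson-Darling test (case of estimated mean and variance) at alpha 0.05,
an F-test on the variances selects a pooled or unequal-variance one-tailed
t-test; otherwise a Mann-Whitney U-test is used (exact enumeration for
small tie-free samples).  Families of raw p-values are then adjusted by
Benjamini-Hochberg step-up at an FDR threshold of q = 0.1, and contrasts
receive two significance tiers: black symbols from the raw p
(p <= .05/.005/.001) and red symbols from the FDR-adjusted p
(q <= .1/.05/.01), thresholds inclusive.

The one-tailed direction must be declared per contrast; inferring it from
the data would double the type-I error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "FDRConfig",
    "compare_two_groups",
    "bh_adjust",
    "assign_tiers",
    "adjust_family",
]

Tail = Literal["greater", "less"]

BLACK_TIERS = ((0.001, "p<=0.001"), (0.005, "p<=0.005"), (0.05, "p<=0.05"))
RED_TIERS = ((0.01, "q<=0.01"), (0.05, "q<=0.05"), (0.1, "q<=0.1"))


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test_used: Literal["t_pooled", "t_welch", "mann_whitney"]
    statistic: float
    p_raw: float
    tail: Tail
    p_fdr: Optional[float] = None
    tier_black: str = "ns"
    tier_red: str = "ns"


@dataclass(frozen=True)
class FDRConfig:
    """Benjamini-Hochberg configuration: threshold ``q`` and the family
    key naming which contrasts are adjusted together (one figure-panel
    analysis per family)."""

    q: float = 0.1
    family: str = "default"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must be in (0, 1), got {self.q}")


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Anderson-Darling normality with estimated mean/variance, decided
    against the tabulated critical values for that case."""
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 suggests p-value methods; the critical-value
        # comparison is the intended decision rule here
        warnings.simplefilter("ignore", FutureWarning)
        res = sstats.anderson(x, dist="norm")
    crit = dict(zip(res.significance_level, res.critical_values))
    level = alpha * 100.0
    if level not in crit:
        raise ValueError(
            f"alpha_normality must be one of "
            f"{sorted(res.significance_level / 100.0)}, got {alpha}"
        )
    return bool(res.statistic < crit[level])


def compare_two_groups(
    x: Sequence[float],
    y: Sequence[float],
    tail: Tail,
    group_a: str = "a",
    group_b: str = "b",
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
) -> ComparisonResult:
    """One two-group contrast with normality-dispatched test selection.

    ``tail="greater"`` tests whether ``x`` exceeds ``y``; ``"less"`` the
    reverse.  Samples must each have at least 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; no two-group "
                         "test is defined")

    if _is_normal(x, alpha_normality) and _is_normal(y, alpha_normality):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        f = vx / vy if vy > 0 else np.inf
        p_f = 2.0 * min(
            sstats.f.cdf(f, x.size - 1, y.size - 1),
            sstats.f.sf(f, x.size - 1, y.size - 1),
        )
        equal_var = p_f >= alpha_variance
        stat, p = sstats.ttest_ind(x, y, equal_var=equal_var,
                                   alternative=tail)
        test = "t_pooled" if equal_var else "t_welch"
    else:
        exact = x.size <= 8 and y.size <= 8 and \
            np.unique(np.concatenate([x, y])).size == x.size + y.size
        stat, p = sstats.mannwhitneyu(
            x, y, alternative=tail,
            method="exact" if exact else "asymptotic",
        )
        test = "mann_whitney"
    return ComparisonResult(
        group_a=group_a, group_b=group_b, n_a=int(x.size), n_b=int(y.size),
        test_used=test, statistic=float(stat), p_raw=float(p), tail=tail,
    )


def bh_adjust(
    p_values: Sequence[float],
    config: FDRConfig = FDRConfig(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment of one family of p-values.

    Returns the adjusted p-values (``min_{j>=i} m*p_(j)/j`` capped at 1,
    in the input order) and boolean pass flags at ``config.q``
    (inclusive).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted, adjusted <= config.q


def assign_tiers(result: ComparisonResult) -> ComparisonResult:
    """Fill the black (raw-p) and red (FDR-p) significance tiers in place
    and return the result.  Thresholds are inclusive, as printed on the
    figure captions this mirrors."""
    result.tier_black = "ns"
    for thr, label in BLACK_TIERS:
        if result.p_raw <= thr:
            result.tier_black = label
            break
    result.tier_red = "ns"
    if result.p_fdr is not None:
        for thr, label in RED_TIERS:
            if result.p_fdr <= thr:
                result.tier_red = label
                break
    return result


def adjust_family(
    results: List[ComparisonResult],
    config: FDRConfig = FDRConfig(),
) -> List[ComparisonResult]:
    """BH-adjust one family of contrasts and assign both tiers."""
    adjusted, _ = bh_adjust([r.p_raw for r in results], config)
    for r, p in zip(results, adjusted):
        r.p_fdr = float(p)
        assign_tiers(r)
    return results
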