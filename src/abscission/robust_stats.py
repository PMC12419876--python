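"""Robust summary statistics for abscission-force populations.

Abscission forces are strongly right-skewed (they span two orders of
magnitude across pull directions), so populations are summarised by
medians and interquartile ranges, uncertainty on the median by a
1000-replicate percentile bootstrap (25th and 975th of the sorted
replicate statistics — an ≈95% interval), and pairs of populations are
compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForceSample",
    "SummaryStats",
    "BIN_ORDER",
    "median_iqr",
    "bootstrap_ci",
    "wilcoxon_ranksum",
    "pairwise_direction_tests",
    "samples_to_frame",
]

#: Canonical angle-bin order per experiment; pairwise comparisons follow it.
BIN_ORDER: dict[str, tuple[str, str, str]] = {
    "sideways": ("0", "+90", "-90"),
    "azimuth": ("0", "~45", "~90"),
    "elevation": ("0", "acute", "obtuse"),
}


@dataclass(frozen=True)
class ForceSample:
    """One load-cell observation: experiment, angle bin and force in mN."""

    experiment: str
    angle_bin: str
    force: float

    def __post_init__(self) -> None:
        if not self.force > 0:
            raise ValueError("force must be positive (mN)")


@dataclass(frozen=True)
class SummaryStats:
    """Median/IQR summary of one force population, optionally with a
    bootstrapped confidence interval on the median (mN)."""

    n: int
    median: float
    q1: float
    q3: float
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")


def samples_to_frame(samples: Iterable[ForceSample]) -> pd.DataFrame:
    """Tidy DataFrame with columns experiment, angle_bin, force_mN."""
    return pd.DataFrame(
        [(s.experiment, s.angle_bin, s.force) for s in samples],
        columns=["experiment", "angle_bin", "force_mN"],
    )


def median_iqr(samples: Sequence[float]) -> SummaryStats:
    """Median and quartiles of a force population.

    The median is the middle order statistic (mean of the middle two for
    even n); quartiles interpolate linearly between order statistics.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr requires at least one sample")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0], method="linear")
    return SummaryStats(n=int(x.size), median=float(med), q1=float(q1), q3=float(q3))


def bootstrap_ci(
    samples: Sequence[float],
    statistic: Callable[[np.ndarray], float] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of the sample.

    Draws ``B`` resamples with replacement, evaluates the statistic on
    each, sorts the replicates and returns the ⌊0.025·B⌋-th and
    ⌊0.975·B⌋-th order statistics (1-based) — for B=1000 the 25th and
    975th values, an ≈95% interval.  The input is sorted before resampling
    so the interval depends only on the sample multiset and the seed, not
    on input order.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 2:
        raise ValueError("bootstrap_ci requires at least two samples")
    if B < 40:
        raise ValueError("B must be at least 40 for the percentile order statistics")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    if statistic is None:
        reps = np.median(x[idx], axis=1)
    else:
        reps = np.array([statistic(x[row]) for row in idx])
    reps.sort()
    k_lo = max(int(0.025 * B), 1)
    k_hi = int(0.975 * B)
    return float(reps[k_lo - 1]), float(reps[k_hi - 1])


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Uses the exact null distribution (enumeration over rank assignments)
    when min(n_x, n_y) ≤ 10 and the pooled data are tie-free; otherwise
    the normal approximation with tie and continuity corrections.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(xa.size, ya.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    rank_sum = float(res.statistic) + xa.size * (xa.size + 1) / 2.0
    return rank_sum, float(res.pvalue)


def pairwise_direction_tests(samples: Iterable[ForceSample]) -> pd.DataFrame:
    """All three pairwise angle-bin comparisons within each experiment.

    Returns one row per comparison with columns ``experiment``, ``bin_a``,
    ``bin_b``, ``n_a``, ``n_b``, ``statistic``, ``p_value``, ``note``.
    P-values are unadjusted two-sided rank-sum values.  A bin that is
    absent from the data yields an explicit ``missing-bin`` row (NaN
    statistic/p) rather than a silent skip.
    """
    frame = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    rows = []
    for experiment, order in BIN_ORDER.items():
        sub = frame[frame["experiment"] == experiment]
        if sub.empty:
            continue
        groups = {
            bin_label: sub.loc[sub["angle_bin"] == bin_label, "force_mN"].to_numpy()
            for bin_label in order
        }
        pairs = [(order[0], order[1]), (order[0], order[2]), (order[1], order[2])]
        for a, b in pairs:
            xa, xb = groups[a], groups[b]
            if xa.size == 0 or xb.size == 0:
                rows.append(
                    (experiment, a, b, xa.size, xb.size, np.nan, np.nan, "missing-bin")
                )
                continue
            w, p = wilcoxon_ranksum(xa, xb)
            rows.append((experiment, a, b, xa.size, xb.size, w, p, ""))
    return pd.DataFrame(
        rows,
        columns=[
            "experiment", "bin_a", "bin_b", "n_a", "n_b",
            "statistic", "p_value", "note",
        ],
    )
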