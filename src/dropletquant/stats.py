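"""Statistical procedures used in the study's quantification.

Doubling times from plate-reader growth curves (DT = 1/k with k the slope of
log2 optical density during exponential growth), one-sided t-tests (paired
and Welch unpaired), the one-sided Wilcoxon rank-sum test (exact for small
tie-free samples, normal approximation with tie correction otherwise) and
the one-sided Fisher exact test on 2x2 contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GrowthCurve",
    "DoublingTimeFit",
    "TestResult",
    "NoGrowthError",
    "doubling_time",
    "t_test_one_sided",
    "wilcoxon_rank_sum_one_sided",
    "fisher_exact_one_sided",
]


class NoGrowthError(ValueError):
    """The fitted window shows a non-positive growth rate."""


@dataclass
class GrowthCurve:
    """A plate-reader time series: time in hours, optical density at 595 nm."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if times.shape != od.shape or times.ndim != 1:
            raise ValueError("times and od must be 1D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("optical densities must be positive")
        self.times, self.od = times, od

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DoublingTimeFit:
    """Log-linear growth fit: slope ``k`` of log2(OD) vs time, DT = 1/k."""

    k: float
    dt: float
    window: tuple[int, int]  # [start, stop) indices into the curve
    r2: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def _prefix(x: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(x)])


def doubling_time(curve: GrowthCurve,
                  window: tuple[int, int] | str = "auto") -> DoublingTimeFit:
    """Estimate the culture doubling time from a growth curve.

    A least-squares line is fitted to log2(OD) against time over the chosen
    window; its slope ``k`` (per hour) gives DT = 1/k hours. ``window`` is
    either an explicit ``(start, stop)`` index range (stop exclusive) or
    ``"auto"``, which selects the contiguous stretch of at least a quarter
    of the series maximizing the r^2 of the log-linear fit — an automatic
    stand-in for manually picking the exponential phase.
    """
    t = curve.times
    y = np.log2(curve.od)
    n = len(curve)
    if window == "auto":
        min_len = max(3, int(np.ceil(n / 4)))
        if n < min_len:
            raise ValueError("too few points for auto-window fitting")
        start, stop = _best_window(t, y, min_len)
    else:
        start, stop = window
        if stop - start < 3:
            raise ValueError("window must contain at least 3 points")
    tw, yw = t[start:stop], y[start:stop]
    slope, intercept, r, _, _ = sps.linregress(tw, yw)
    if slope <= 0 or not np.isfinite(slope):
        raise NoGrowthError(f"non-positive growth rate in window {start}:{stop}")
    return DoublingTimeFit(k=float(slope), dt=float(1.0 / slope),
                           window=(int(start), int(stop)), r2=float(r**2))


def _best_window(t: np.ndarray, y: np.ndarray, min_len: int) -> tuple[int, int]:
    """Contiguous window (length >= min_len) maximizing log-linear r^2.

    Prefix-sum formulation: for window w, r^2 = S_ty^2 / (S_tt * S_yy) with
    the centered second moments of the window. Ties broken toward longer,
    then earlier, windows. Windows with zero variance in y are skipped.
    """
    n = t.size
    p1t, p1y = _prefix(t), _prefix(y)
    p2t, p2y, pty = _prefix(t * t), _prefix(y * y), _prefix(t * y)
    best = None  # (r2, length, -start)
    best_win = (0, n)
    for length in range(min_len, n + 1):
        starts = np.arange(0, n - length + 1)
        stops = starts + length
        st = p1t[stops] - p1t[starts]
        sy = p1y[stops] - p1y[starts]
        stt = p2t[stops] - p2t[starts] - st * st / length
        syy = p2y[stops] - p2y[starts] - sy * sy / length
        sty = pty[stops] - pty[starts] - st * sy / length
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(syy > 0, sty**2 / (stt * syy), -np.inf)
        i = int(np.argmax(r2))
        if not np.isfinite(r2[i]):
            continue
        key = (round(float(r2[i]), 12), length, -int(starts[i]))
        if best is None or key > best:
            best = key
            best_win = (int(starts[i]), int(stops[i]))
    return best_win


def t_test_one_sided(x, y, paired: bool = False,
                     alternative: str = "less") -> TestResult:
    """One-sided t-test: paired, or Welch's unequal-variance unpaired.

    For paired data with all differences exactly zero the statistic is 0 and
    p = 0.5 by the symmetry of the null. Two constant equal samples carry no
    information and raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        if x.size < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        if np.all(d == 0):
            return TestResult(0.0, 0.5, alternative, "paired t-test",
                              (x.size, y.size))
        res = sps.ttest_rel(x, y, alternative=alternative)
        method = "paired t-test"
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("need at least 2 observations per sample")
        if np.var(x) == 0 and np.var(y) == 0:
            raise ValueError("degenerate input: zero variance in both samples")
        res = sps.ttest_ind(x, y, equal_var=False, alternative=alternative)
        method = "Welch unpaired t-test"
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      method, (x.size, y.size))


def wilcoxon_rank_sum_one_sided(x, y, alternative: str = "less",
                                exact_max_n: int = 20) -> TestResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample has at most
    ``exact_max_n`` observations and no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (pooled.size <= exact_max_n) and not has_ties
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    method = "Wilcoxon rank-sum (exact)" if exact else "Wilcoxon rank-sum (normal approx.)"
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      method, (x.size, y.size))


def fisher_exact_one_sided(table, alternative: str = "greater") -> TestResult:
    """One-sided Fisher exact test on a 2x2 table of counts.

    The p-value is the hypergeometric tail probability of tables at least as
    extreme under fixed marginals. A zero marginal makes every table under
    the null identical, so p = 1 by convention.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must hold non-negative integer counts")
    if table.sum() == 0:
        raise ValueError("table must have a positive grand total")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    ns = (int(table.sum()),)
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        return TestResult(np.nan, 1.0, alternative, "Fisher exact", ns)
    odds, p = sps.fisher_exact(table, alternative=alternative)
    return TestResult(float(odds), float(p), alternative, "Fisher exact", ns)
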