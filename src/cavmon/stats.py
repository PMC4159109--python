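"""Statistical procedures for the rupture experiments.

Paired rupture-time comparisons use the one-sided Wilcoxon signed-rank test
with the Pratt convention for zero differences: zero differences enter the
joint ranking of absolute differences and are then dropped from the rank
sums.  (A censored-at-300-s pair with no rupture in either arm yields a
genuine zero difference, so the convention matters.)  The exact null
distribution is computed by enumerating sign assignments of the non-zero
ranks for n <= 15; a tie-corrected normal approximation is used above.

Everything else is standard: sample descriptives, Pearson correlation,
pooled-variance Student t tests, paired one-sided t tests, and Fisher's
exact test, delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

__all__ = [
    "PairedSample",
    "descriptive",
    "pearson",
    "wilcoxon_paired_one_sided",
    "t_test_independent",
    "t_test_paired_one_sided",
    "fisher_exact",
    "exposure_summary",
]

CENSOR_TIME_S = 300.0


@dataclass(frozen=True)
class PairedSample:
    """Paired rupture times in seconds, censored at 300 s.

    ``values_a`` is the reference arm (controller inactive), ``values_b``
    the treated arm (controller active); ``vessel_type`` one entry per pair.
    """

    labels: tuple
    values_a: np.ndarray
    values_b: np.ndarray
    vessel_type: tuple = ()

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=np.float64)
        b = np.asarray(self.values_b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired samples must be equal-length 1-D arrays")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.values_b - self.values_a


def descriptive(values) -> dict:
    """Mean, sample SD (n-1), min and max."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    if x.size < 2:
        raise ValueError("sample SD needs n >= 2")
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = ss.pearsonr(x, y)
    return float(r), float(p)


def _pratt_ranks(d: np.ndarray) -> np.ndarray:
    """Ranks of |d| with zeros included in the ranking, then dropped."""
    ranks = ss.rankdata(np.abs(d))
    return ranks[d != 0], d[d != 0]


def _exact_tminus_cdf(ranks: np.ndarray, t_obs: float) -> float:
    """P(T- <= t_obs) by dynamic programming over 2**m sign assignments.

    Ranks may be half-integral under midranks; everything is doubled to an
    integer lattice.
    """
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    t2 = int(np.floor(2.0 * t_obs + 1e-9))
    return float(counts[: t2 + 1].sum() / 2.0 ** len(r2))


def wilcoxon_paired_one_sided(sample: PairedSample, exact_max_n: int = 15) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test that arm b exceeds arm a.

    Returns ``(T_minus, p)`` where ``T_minus`` is the sum of Pratt ranks of
    negative differences; small values support the alternative b > a.
    Exact enumeration for n <= ``exact_max_n`` non-zero differences, else a
    tie-corrected normal approximation with continuity correction.
    """
    d = sample.differences
    if d.size < 5:
        raise ValueError("wilcoxon needs at least 5 pairs")
    if np.all(d == 0):
        raise ValueError("all differences are zero")
    ranks_nz, d_nz = _pratt_ranks(d)
    t_minus = float(ranks_nz[d_nz < 0].sum())
    m = d_nz.size
    if m <= exact_max_n:
        p = _exact_tminus_cdf(ranks_nz, t_minus)
    else:
        n = d.size
        n0 = n - m
        mu = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
        var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
        _, tie_counts = np.unique(np.abs(d_nz), return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        z = (t_minus + 0.5 - mu) / np.sqrt(var)
        p = float(ss.norm.cdf(z))
    return t_minus, p


def t_test_independent(a, b, equal_variance: bool = True, two_sided: bool = True) -> tuple[float, float]:
    """Student t test for independent samples (pooled variance by default)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate variance with unequal means")
    res = ss.ttest_ind(a, b, equal_var=equal_variance,
                       alternative="two-sided" if two_sided else "greater")
    return float(res.statistic), float(res.pvalue)


def t_test_paired_one_sided(a, b) -> tuple[float, float]:
    """Paired t test of the alternative mean(b) > mean(a)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired t test needs equal lengths >= 2")
    d = b - a
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 0.5
        raise ValueError("zero-variance non-zero differences")
    res = ss.ttest_rel(b, a, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table, sided: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 contingency table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    _, p = ss.fisher_exact(table, alternative=sided)
    return float(p)


def exposure_summary(power_history, intensity_history, duty: float = 0.5,
                     cycle_period: float = 1.0) -> tuple[float, float]:
    """Trial-mean SPTP intensity (W/cm^2) and total acoustic energy (J).

    Energy is the duty-cycle Riemann sum of the delivered acoustic power:
    ``sum(power) * duty * cycle_period``.
    """
    p = np.asarray(power_history, dtype=np.float64)
    i = np.asarray(intensity_history, dtype=np.float64)
    if p.size == 0 or i.size == 0:
        raise ValueError("empty exposure history")
    return float(np.mean(i)), float(np.sum(p) * duty * cycle_period)
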