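"""Two-sample distribution tests and replica aggregation.

Frames within one trajectory are autocorrelated; callers comparing frame
distributions may thin with a stride before testing (the default stride of
1 matches common practice but overstates the effective sample size — see
the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney", "ks_test", "two_sample_test",
           "replica_aggregate", "circular_recenter"]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_A: int
    n_B: int
    method: str


def _check_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return a, b


def mann_whitney(sample_A, sample_B, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test with tie correction.

    Exact null enumeration when both sides have ≤ 8 observations and no
    ties cross the samples; tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    a, b = _check_samples(sample_A, sample_B)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size <= 8 and b.size <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                      n_A=int(a.size), n_B=int(b.size),
                      method=f"mann-whitney ({method})")


def ks_test(sample_A, sample_B, alternative: str = "two-sided") -> TestResult:
    """Two-sample Kolmogorov–Smirnov test."""
    a, b = _check_samples(sample_A, sample_B)
    res = sps.ks_2samp(a, b, alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n_A=int(a.size), n_B=int(b.size), method="kolmogorov-smirnov")


def two_sample_test(sample_A, sample_B, method: str = "mann-whitney") -> TestResult:
    if method in ("mann-whitney", "mannwhitney", "mw"):
        return mann_whitney(sample_A, sample_B)
    if method in ("ks", "kolmogorov-smirnov"):
        return ks_test(sample_A, sample_B)
    raise ValueError(f"unknown test '{method}'")


def replica_aggregate(replica_values: list) -> tuple[float, float | None]:
    """Mean of replica means ± SD over replica means (n−1 denominator).

    The SD is ``None`` for a single replica rather than 0 — one replica
    carries no between-replica spread information.
    """
    if not replica_values:
        raise ValueError("no replicas given")
    means = [float(np.mean(np.asarray(v, dtype=float))) for v in replica_values]
    mean = float(np.mean(means))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else None
    return mean, sd


def circular_recenter(angles, reference: float = 0.0) -> np.ndarray:
    """Shift angles (degrees) by multiples of 360° into (reference−180, reference+180].

    Useful before moment statistics on dihedral distributions that straddle
    the ±180° wrap.
    """
    a = np.asarray(angles, dtype=float)
    d = np.mod(a - reference, 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    # exact half-turn maps to +180 (upper boundary inclusive)
    d = np.where(np.isclose(d, -180.0), 180.0, d)
    return reference + d
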