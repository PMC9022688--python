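"""Shared two-sample tests and Benjamini-Hochberg FDR control."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as st

__all__ = ["TestResult", "FDRResult", "two_sample_test", "bh_fdr"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    degenerate: bool = False


def two_sample_test(x, y, method: str = "t") -> TestResult:
    """Two-sided two-sample test.

    ``method="t"`` is the Welch unequal-variance t test with
    Welch-Satterthwaite degrees of freedom; ``method="mwu"`` is the
    Mann-Whitney U with normal approximation and tie correction. Samples
    in which every value is identical across both groups are degenerate:
    statistic 0, p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return TestResult(0.0, 1.0, method, len(x), len(y), degenerate=True)
    if method == "t":
        stat, p = st.ttest_ind(x, y, equal_var=False)
    elif method == "mwu":
        stat, p = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    else:
        raise ValueError(f"unknown method {method!r}; use 't' or 'mwu'")
    return TestResult(float(stat), float(p), method, len(x), len(y))


@dataclass(frozen=True)
class FDRResult:
    sorted_p: np.ndarray
    threshold: float
    rejected_indices: np.ndarray   # indices into the original p-value array
    alpha: float

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_indices)


def bh_fdr(p_values, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up over m ranked p-values.

    The threshold is p_(i*) for the largest i with p_(i) <= i*alpha/m (0 if
    no such i); every p <= threshold is rejected.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return FDRResult(np.array([]), 0.0, np.array([], dtype=int), alpha)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    crit = (np.arange(1, m + 1) * alpha) / m
    passed = np.flatnonzero(ps <= crit)
    if passed.size == 0:
        return FDRResult(ps, 0.0, np.array([], dtype=int), alpha)
    threshold = float(ps[passed[-1]])
    rejected = np.flatnonzero(p <= threshold)
    return FDRResult(ps, threshold, rejected, alpha)
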