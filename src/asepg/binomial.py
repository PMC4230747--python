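"""The binomial test of allelic balance (pooled over replicates).

Replicates are pooled into a single pair of counts before testing: the
binomial model is defined on the total number ``n`` of reads aligning to
the exon, with ``theta`` the unknown paternal proportion and the null
``H0: theta = 1/2``.  Two variants are provided: the normal-approximation
z statistic with the rejection rule ``|z| > 1.965``, and the two-sided
exact binomial test (doubled smaller tail, capped at 1).  Replicate-level
variation is the province of the Bayesian models, not of this test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AlleleCounts, BinomialResult
from .exceptions import UntestableExonError, ValidationError

__all__ = ["z_test", "exact_test", "bh_fdr", "Z_CUTOFF"]

#: literal rejection cutoff for the z statistic
Z_CUTOFF = 1.965


def _pooled(counts: AlleleCounts) -> tuple[int, int]:
    n = counts.total
    if n == 0:
        raise UntestableExonError(
            f"exon {counts.exon_id}: no reads; binomial test undefined"
        )
    return n, int(counts.y.sum())


def z_test(counts: AlleleCounts) -> BinomialResult:
    """Normal-approximation binomial test of ``theta = 1/2``.

    ``z = (p_hat - 1/2) / sqrt(0.25/n)`` on the pooled counts; the exon is
    flagged as in allelic imbalance when ``|z| > 1.965``.
    """
    n, y = _pooled(counts)
    p_hat = y / n
    z = (p_hat - 0.5) / np.sqrt(0.25 / n)
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return BinomialResult(
        exon_id=counts.exon_id,
        n=n,
        p_hat=p_hat,
        z=float(z),
        p_value=p_value,
        ai_flag=bool(abs(z) > Z_CUTOFF),
        variant="z",
    )


def exact_two_sided_pvalue(y: int, n: int) -> float:
    """Two-sided exact binomial p-value at theta = 1/2.

    Doubles the smaller of the two tail probabilities P(Y <= y) and
    P(Y >= y) under Binomial(n, 1/2), capping at 1.  Symmetric in
    y <-> n - y, which is all the null simulations require.
    """
    lower = stats.binom.cdf(y, n, 0.5)
    upper = stats.binom.sf(y - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_test(counts: AlleleCounts, level: float = 0.05) -> BinomialResult:
    """Two-sided exact binomial test of ``theta = 1/2`` on pooled counts."""
    if not (0.0 < level < 1.0):
        raise ValidationError("test level must lie in (0, 1)")
    n, y = _pooled(counts)
    p_hat = y / n
    p_value = exact_two_sided_pvalue(y, n)
    z = (p_hat - 0.5) / np.sqrt(0.25 / n)
    return BinomialResult(
        exon_id=counts.exon_id,
        n=n,
        p_hat=p_hat,
        z=float(z),
        p_value=p_value,
        ai_flag=bool(p_value < level),
        variant="exact",
        level=level,
    )


def exact_pvalues_vectorized(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact two-sided p-values for arrays of pooled counts (driver use)."""
    y = np.asarray(y)
    n = np.asarray(n)
    lower = stats.binom.cdf(y, n, 0.5)
    upper = stats.binom.sf(y - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (convenience utility)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
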