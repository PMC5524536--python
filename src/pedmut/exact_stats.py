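"""Exact small-count statistics: Fisher's exact test, exact binomial test,
and the Garwood confidence interval for a Poisson count.

These are the inferential primitives of the mutation-rate pipeline, where
every interesting count (mutation events, transmission carriers, parental
origins) is far too small for asymptotics.  All tests enumerate the exact
null distribution; two-sided p-values follow the minimum-likelihood
convention (sum the probability of every outcome no more likely than the
observed one), which is the convention used by mainstream statistics
packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "ContingencyTable2x2",
    "ExactTestResult",
    "fisher_exact_two_sided",
    "binomial_test",
    "poisson_rate_ci",
]

# relative slack when comparing point probabilities in the minimum-likelihood
# rule, guarding against ties lost to floating point
_REL_TIE = 1.0 + 1e-9


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with fixed margins under the Fisher null."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("all-zero table has no exact distribution")


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    sidedness: str  # "one" | "two"
    method: str     # "fisher" | "binomial" | "poisson-ci"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _log_hypergeom_pmf(k: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n)."""

    def lc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lc(K, k) + lc(N - K, n - k) - lc(N, n)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> ExactTestResult:
    """Two-sided Fisher's exact test by full hypergeometric enumeration.

    With all margins fixed the table is determined by its top-left cell a;
    the two-sided p-value sums P(a') over every admissible a' whose point
    probability does not exceed that of the observed table.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, total = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, row1, col1, total)
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * _REL_TIE].sum())
    return ExactTestResult(min(p, 1.0), "two", "fisher")


def binomial_test(k: int, n: int, p0: float, sidedness: str = "two") -> ExactTestResult:
    """Exact binomial test of k successes in n trials against proportion p0.

    ``sidedness`` is "two" (minimum-likelihood rule), "less" (lower tail) or
    "greater" (upper tail).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"null proportion {p0} outside [0, 1]")
    support = np.arange(n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = (
            gammaln(n + 1) - gammaln(support + 1) - gammaln(n - support + 1)
            + np.where(support > 0, support * np.log(p0 if p0 > 0 else 1.0), 0.0)
            + np.where(n - support > 0, (n - support) * np.log1p(-p0 if p0 < 1 else 0.0), 0.0)
        )
    # degenerate nulls: all mass on one endpoint
    if p0 == 0.0:
        pmf = np.where(support == 0, 1.0, 0.0)
    elif p0 == 1.0:
        pmf = np.where(support == n, 1.0, 0.0)
    else:
        pmf = np.exp(logpmf)
    if sidedness == "less":
        p = float(pmf[: k + 1].sum())
    elif sidedness == "greater":
        p = float(pmf[k:].sum())
    elif sidedness == "two":
        p = float(pmf[pmf <= pmf[k] * _REL_TIE].sum())
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    side = "two" if sidedness == "two" else "one"
    return ExactTestResult(min(p, 1.0), side, "binomial")


def poisson_rate_ci(events: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean given a count.

    Inverts the Poisson CDF at alpha/2 in each tail, via the chi-square
    quantile identity: lower = chi2(alpha/2; 2k)/2, upper =
    chi2(1 - alpha/2; 2k + 2)/2, with lower = 0 when no events were seen.
    """
    if events < 0 or int(events) != events:
        raise ValueError(f"event count must be a non-negative integer, got {events}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if events == 0 else float(chi2.ppf(alpha / 2.0, 2 * events) / 2.0)
    upper = float(chi2.ppf(1.0 - alpha / 2.0, 2 * events + 2) / 2.0)
    return lower, upper
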