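"""Observed-vs-expected enrichment and the one-sided Fisher exact test.

Every headline comparison in this pipeline asks whether a "special"
outcome (non-conserved recoding; a nonsynonymous SNP in the codon) is
overrepresented among observed editing sites relative to a genome-wide
unedited-adenosine control, so the one-sided alternative defaults to
"greater". The p-value is the hypergeometric upper tail computed in log
space (log-gamma based pmf + logsumexp), which stays exact at the
million-scale control denominators where naive factorials overflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 observed/control counts: (k special of n) vs (k special of n)."""

    k_obs: int
    n_obs: int
    k_exp: int
    n_exp: int

    def __post_init__(self) -> None:
        for name in ("k_obs", "n_obs", "k_exp", "n_exp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.k_obs > self.n_obs or self.k_exp > self.n_exp:
            raise ValueError("k cannot exceed n")

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.k_obs, self.n_obs - self.k_obs],
            [self.k_exp, self.n_exp - self.k_exp],
        ]


def fraction(k: int, n: int) -> float:
    """Exact proportion k/n; n must be positive."""
    if n <= 0:
        raise ValueError("fraction undefined for n <= 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return k / n


def format_percent(x: float, sig: int = 3) -> str:
    """Percentage with ``sig`` significant digits ('0.826%', '1.22%')."""
    pct = 100.0 * x
    if pct == 0:
        return "0%"
    digits = sig - 1 - math.floor(math.log10(abs(pct)))
    return f"{round(pct, digits):.{max(digits, 0)}f}%"


def fisher_one_sided(table: ContingencyTable, alternative: str = "greater") -> float:
    """One-sided Fisher exact p for enrichment of the observed group.

    Under fixed margins the observed-special count is hypergeometric with
    population n_obs+n_exp, k_obs+k_exp successes, and n_obs draws;
    'greater' returns Pr[X >= k_obs]. The tail is accumulated in log space.
    """
    M = table.n_obs + table.n_exp
    K = table.k_obs + table.k_exp
    N = table.n_obs
    if M == 0 or K == 0 or N == 0 or K == M:
        warnings.warn("degenerate contingency margins; p = 1", stacklevel=2)
        return 1.0
    lo = max(0, K - (M - N))
    hi = min(N, K)
    if alternative == "greater":
        support = np.arange(table.k_obs, hi + 1)
        if support.size == 0:
            return 1.0
        logp = logsumexp(hypergeom.logpmf(support, M, K, N))
        return float(min(1.0, math.exp(logp)))
    if alternative == "two-sided":
        support = np.arange(lo, hi + 1)
        logpmf = hypergeom.logpmf(support, M, K, N)
        cutoff = hypergeom.logpmf(table.k_obs, M, K, N) + 1e-7
        logp = logsumexp(logpmf[logpmf <= cutoff])
        return float(min(1.0, math.exp(logp)))
    raise ValueError(f"unknown alternative {alternative!r}")


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio of the 2x2 table; +inf when the denominator is 0."""
    num = table.k_obs * (table.n_exp - table.k_exp)
    den = (table.n_obs - table.k_obs) * table.k_exp
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


@dataclass(frozen=True)
class EnrichmentResult:
    """One observed-vs-expected comparison: fractions, odds ratio, Fisher p."""

    label: str
    table: ContingencyTable
    observed_fraction: float
    expected_fraction: float
    odds_ratio: float
    p_one_sided: float
    alternative: str = "greater"

    def summary(self) -> str:
        t = self.table
        return (
            f"{self.label or 'enrichment'}: observed {t.k_obs}/{t.n_obs} = "
            f"{format_percent(self.observed_fraction)}, expected {t.k_exp}/{t.n_exp} = "
            f"{format_percent(self.expected_fraction)}, OR = {self.odds_ratio:.3g}, "
            f"one-sided Fisher p = {self.p_one_sided:.3g}"
        )

    def to_dict(self) -> dict:
        t = self.table
        return {
            "label": self.label,
            "k_obs": t.k_obs, "n_obs": t.n_obs,
            "k_exp": t.k_exp, "n_exp": t.n_exp,
            "observed_fraction": self.observed_fraction,
            "expected_fraction": self.expected_fraction,
            "observed_percent": format_percent(self.observed_fraction),
            "expected_percent": format_percent(self.expected_fraction),
            "odds_ratio": self.odds_ratio,
            "p_one_sided": self.p_one_sided,
            "alternative": self.alternative,
        }


def enrichment_report(
    k_obs: int, n_obs: int, k_exp: int, n_exp: int,
    label: str = "", alternative: str = "greater",
    table: Optional[ContingencyTable] = None,
) -> EnrichmentResult:
    """Bundle fractions, odds ratio and the one-sided Fisher p for a comparison."""
    t = table if table is not None else ContingencyTable(k_obs, n_obs, k_exp, n_exp)
    return EnrichmentResult(
        label=label,
        table=t,
        observed_fraction=fraction(t.k_obs, t.n_obs) if t.n_obs else 0.0,
        expected_fraction=fraction(t.k_exp, t.n_exp) if t.n_exp else 0.0,
        odds_ratio=odds_ratio(t),
        p_one_sided=fisher_one_sided(t, alternative=alternative),
        alternative=alternative,
    )
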