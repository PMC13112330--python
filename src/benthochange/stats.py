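"""Exact and asymptotic nonparametric tests for the change-detection analyses.

The analysis battery comprises the paired Wilcoxon signed-rank test (one-sided
"greater", Bonferroni-corrected across the abundance and condition families),
the two-sample Wilcoxon rank-sum test for two-level factors such as phylum,
the Kruskal-Wallis test for multi-level factors, and Dunn's post hoc pairwise
comparisons with multiplicity adjustment.

For the Wilcoxon tests the exact null distribution is enumerated whenever the
effective sample size permits, *including under ties*: midranks are doubled to
integers and the distribution of the (doubled) statistic is built by a
generating-function shift recursion — a polynomial convolution over ranks —
rather than the tie-free closed forms. Ecological score data are tie-rich, so
the tie-aware exact path is the default; above the size threshold a
tie-corrected normal approximation with continuity correction is used.

Zero paired differences are dropped before ranking and the reduced sample
size reported, the convention of the classical exact-test implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Largest effective sample size for which the exact permutation null is
#: enumerated; beyond it the tie-corrected normal approximation is used.
EXACT_THRESHOLD = 30

ALTERNATIVES = ("greater", "less", "two_sided")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    n_effective: int
    alternative: str
    p_value: float
    exact: bool
    p_adjusted: float | None = None
    adjustment: str | None = None

    def adjusted(self, m: int, method: str = "bonferroni") -> "TestResult":
        """Return a copy with the p-value adjusted for a family of ``m`` tests."""
        p_adj = adjust_pvalues([self.p_value], method=method, m=m)[0]
        return TestResult(self.method, self.statistic, self.n_effective,
                          self.alternative, self.p_value, self.exact,
                          p_adjusted=p_adj, adjustment=f"{method} (m={m})")


def _check_alternative(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    return alternative


# ---------------------------------------------------------------------------
# Exact null distributions over doubled midranks
# ---------------------------------------------------------------------------

def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks times two — integers even under ties."""
    r2 = np.rint(2 * sps.rankdata(values)).astype(np.int64)
    return r2


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled W+ over all 2^n sign assignments.

    Generating-function shift recursion: the distribution is the coefficient
    vector of prod_i (1 + x^{d_i}) with d_i the doubled midranks.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for d in doubled_ranks:
        counts[d:] += counts[: total + 1 - d]
    return counts


def signed_rank_test(
    differences: Sequence[float],
    alternative: str = "greater",
    exact_threshold: int = EXACT_THRESHOLD,
) -> TestResult:
    """Paired Wilcoxon signed-rank test on a vector of paired differences.

    ``alternative='greater'`` tests whether the differences tend positive
    (first member of each pair stochastically larger). Zeros are dropped
    before ranking; midranks handle ties in |d|. The exact enumeration runs
    for n_effective <= ``exact_threshold``, else the tie-corrected normal
    approximation with continuity correction.
    """
    _check_alternative(alternative)
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("test undefined: all paired differences are zero")
    r2 = _doubled_midranks(np.abs(d))
    w2 = int(r2[d > 0].sum())  # doubled W+
    statistic = w2 / 2.0

    if n <= exact_threshold:
        counts = _signed_rank_distribution(r2)
        denom = 2.0 ** n
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult("wilcoxon_signed_rank", statistic, n, alternative,
                          float(p), exact=True)

    mean = n * (n + 1) / 4.0
    # tie correction over groups of equal |d|
    _, tie_counts = np.unique(r2, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        p = sps.norm.sf((statistic - 0.5 - mean) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((statistic + 0.5 - mean) / sd)
    else:
        z = (abs(statistic - mean) - 0.5) / sd
        p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult("wilcoxon_signed_rank", statistic, n, alternative,
                      float(p), exact=False)


def _rank_sum_distribution(doubled_ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of each achievable doubled rank-sum over all size-n_a subsets."""
    total = int(doubled_ranks.sum())
    table = np.zeros((n_a + 1, total + 1))
    table[0, 0] = 1.0
    for d in doubled_ranks:
        for k in range(n_a, 0, -1):
            table[k, d:] += table[k - 1, : total + 1 - d]
    return table[n_a]


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    exact_threshold: int = EXACT_THRESHOLD,
) -> TestResult:
    """Two-sample Wilcoxon rank-sum test (Mann-Whitney form of the statistic).

    The statistic is the midrank sum of sample ``a`` in the pooled ranking;
    ``alternative='less'`` tests whether ``a`` is stochastically smaller.
    Exact enumeration over all C(n, n_a) group assignments (tie-aware via
    doubled midranks) when the pooled size is within ``exact_threshold``.
    """
    _check_alternative(alternative)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    r2 = _doubled_midranks(pooled)
    w2 = int(r2[:n_a].sum())
    statistic = w2 / 2.0

    if n <= exact_threshold:
        counts = _rank_sum_distribution(r2, n_a)
        denom = counts.sum()  # C(n, n_a)
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult("wilcoxon_rank_sum", statistic, n, alternative,
                          float(p), exact=True)

    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(r2, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    sd = np.sqrt(var)
    if alternative == "greater":
        p = sps.norm.sf((statistic - 0.5 - mean) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((statistic + 0.5 - mean) / sd)
    else:
        z = (abs(statistic - mean) - 0.5) / sd
        p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult("wilcoxon_rank_sum", statistic, n, alternative,
                      float(p), exact=False)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's post hoc
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df.

    The degenerate case of all pooled values identical is reported as
    H = 0, p = 1 (no evidence of any group difference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, n, "two_sided", 1.0, exact=False)
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), n, "two_sided", float(p),
                      exact=False)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjustment: str = "holm",
) -> pd.DataFrame:
    """Dunn's post hoc pairwise z tests after a Kruskal-Wallis result.

    For groups i, j the statistic is the difference of mean pooled midranks
    over the tie-corrected standard error
    ``sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j))`` with
    ``T = sum(t^3 - t)`` over tie groups. Two-sided p-values are adjusted
    over all k(k-1)/2 pairs. Fully tied data yield z = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)) if n > 1 else 0.0

    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        rows.append({"level_a": labels[i], "level_b": labels[j],
                     "z": float(z), "p_value": float(p)})
    table = pd.DataFrame(rows, columns=["level_a", "level_b", "z", "p_value"])
    table["p_adjusted"] = adjust_pvalues(table["p_value"].tolist(), method=adjustment)
    table["adjustment"] = adjustment
    return table


# ---------------------------------------------------------------------------
# Multiplicity adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(
    p: Sequence[float], method: str = "bonferroni", m: int | None = None
) -> list[float]:
    """Adjust a family of p-values; input order is preserved in the output.

    ``bonferroni``: min(1, m * p). ``holm``: step-down with monotonicity
    enforcement. ``m`` defaults to len(p) and may be set larger when the
    family extends beyond the p-values passed in.
    """
    p = list(p)
    if any(not 0 <= x <= 1 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than the number of p-values")
    if method == "bonferroni":
        return [min(1.0, m * x) for x in p]
    if method == "holm":
        order = sorted(range(len(p)), key=lambda i: p[i])
        adjusted = [0.0] * len(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adjusted[idx] = min(1.0, running)
        return adjusted
    raise ValueError(f"unknown adjustment method {method!r}")
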