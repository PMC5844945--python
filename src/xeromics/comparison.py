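"""Rank-based comparison of classifiers, selectors, and samplers.

Given AUC scores of many model contexts (a context is a set of models
sharing every workflow component except the one being compared), the
Friedman test asks whether the compared algorithms influence performance
equally, the Nemenyi critical difference identifies which pairs differ, and
Holm-Bonferroni controls the family-wise error over the six comparison
families (classifier / selector / sampler, time-specific / longitudinal).
A win-proportion matrix summarizes head-to-head outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "friedman_test",
    "nemenyi_cd",
    "holm_bonferroni",
    "win_proportion_matrix",
    "rank_table",
    "FamilyComparison",
    "compare_family",
    "plot_critical_difference",
]


def rank_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Within-context performance ranks (rank 1 = best AUC; midranks on ties).

    ``scores`` is contexts x algorithms.  Each row of the result is a
    permutation of 1..k up to midrank ties, so row sums equal k(k+1)/2.
    """
    scores = pd.DataFrame(scores)
    if scores.isna().any().any():
        raise ValueError("scores table contains missing values")
    return scores.rank(axis=1, ascending=False, method="average")


def friedman_test(scores: pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square test on a contexts x algorithms score table.

    With N contexts, k algorithms and average ranks R̄_j,

        chi2_F = 12 N / (k (k+1)) * [sum_j R̄_j^2 - k (k+1)^2 / 4]

    referred to a chi-square distribution with k-1 degrees of freedom.
    Rank-based, hence invariant under monotone transforms of the scores
    within a context.
    """
    scores = pd.DataFrame(scores)
    n, k = scores.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 algorithms")
    if n < 2:
        raise ValueError("Friedman test needs at least 2 contexts")
    ranks = rank_table(scores)
    mean_ranks = ranks.mean(axis=0).to_numpy()
    statistic = 12.0 * n / (k * (k + 1)) * (np.sum(mean_ranks**2) - k * (k + 1) ** 2 / 4.0)
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference for k algorithms over N contexts.

    CD = q_alpha * sqrt(k (k+1) / (6 N)) where q_alpha is the studentized
    range quantile at infinite degrees of freedom divided by sqrt(2).  Two
    algorithms differ significantly when their average ranks differ by at
    least CD.
    """
    if not 2 <= k <= 20:
        raise ValueError(f"k must lie in [2, 20], got {k}")
    if n < 2:
        raise ValueError("need at least 2 contexts")
    q = stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down FWER control; returns a rejection flag per p-value.

    Sorted ascending, p_(i) is rejected while p_(i) <= alpha / (m - i + 1);
    the procedure stops at the first failure.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for step, idx in enumerate(order):
        if p[idx] <= alpha / (m - step):
            flags[idx] = True
        else:
            break
    return flags


def win_proportion_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Head-to-head win proportions from a contexts x algorithms score table.

    Entry (a, b) is the fraction of contexts where algorithm a's best AUC
    exceeds b's; ties contribute one half, so M[a, b] + M[b, a] = 1 off the
    diagonal.  Contexts with missing entries are dropped with a warning.
    """
    scores = pd.DataFrame(scores)
    complete = scores.dropna()
    if len(complete) < len(scores):
        warnings.warn(
            f"dropped {len(scores) - len(complete)} contexts with missing algorithms"
        )
    if complete.empty:
        raise ValueError("no complete contexts")
    algs = list(complete.columns)
    vals = complete.to_numpy()
    k = len(algs)
    M = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            diff = vals[:, a] - vals[:, b]
            M[a, b] = np.mean(np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5)))
    return pd.DataFrame(M, index=algs, columns=algs)


@dataclass
class FamilyComparison:
    """Friedman + Nemenyi summary for one comparison family."""

    family: str
    mean_ranks: pd.Series
    statistic: float
    p_value: float
    critical_difference: float
    n_contexts: int
    win_matrix: pd.DataFrame
    significant: bool | None = None  # set after the Holm correction

    def significant_pairs(self) -> list[tuple[str, str]]:
        """Algorithm pairs whose average ranks differ by at least the CD."""
        out = []
        r = self.mean_ranks
        for a in r.index:
            for b in r.index:
                if a < b and abs(r[a] - r[b]) >= self.critical_difference:
                    out.append((a, b))
        return out

    def summary(self) -> str:
        lines = [
            f"family: {self.family} "
            f"(k = {len(self.mean_ranks)}, N = {self.n_contexts})",
            f"  Friedman chi2 = {self.statistic:.3f}, p = {self.p_value:.3g}"
            + ("" if self.significant is None
               else f", {'significant' if self.significant else 'not significant'}"
                    " after Holm correction"),
            f"  critical difference = {self.critical_difference:.3f}",
            "  average ranks (1 = best): "
            + ", ".join(f"{a}={v:.2f}" for a, v in self.mean_ranks.sort_values().items()),
        ]
        return "\n".join(lines)


def compare_family(
    scores: pd.DataFrame, family: str = "", alpha: float = 0.05
) -> FamilyComparison:
    """Run the full rank comparison for one family of algorithms."""
    scores = pd.DataFrame(scores)
    statistic, p = friedman_test(scores)
    cd = nemenyi_cd(scores.shape[1], scores.shape[0], alpha)
    return FamilyComparison(
        family=family,
        mean_ranks=rank_table(scores).mean(axis=0),
        statistic=statistic,
        p_value=p,
        critical_difference=cd,
        n_contexts=scores.shape[0],
        win_matrix=win_proportion_matrix(scores),
    )


def apply_family_correction(
    comparisons: list[FamilyComparison], alpha: float = 0.05
) -> list[FamilyComparison]:
    """Holm-Bonferroni over the Friedman p-values of several families."""
    flags = holm_bonferroni([c.p_value for c in comparisons], alpha)
    for c, f in zip(comparisons, flags):
        c.significant = bool(f)
    return comparisons


def plot_critical_difference(comparison: FamilyComparison, ax=None):
    """Critical-difference diagram: average ranks with a CD ruler.

    Algorithms not significantly different (rank gap < CD) are joined by a
    horizontal bar.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2 + 0.3 * len(comparison.mean_ranks)))
    ranks = comparison.mean_ranks.sort_values()
    k = len(ranks)
    ax.hlines(0, 1, k, color="black", lw=1)
    for i, (name, r) in enumerate(ranks.items()):
        y = -0.3 * (i + 1)
        ax.plot([r, r], [0, y], color="gray", lw=0.8)
        ax.text(r, y - 0.05, f" {name} ({r:.2f})", va="top", fontsize=9)
    # bars joining groups within one CD
    names = list(ranks.index)
    level = 0.15
    i = 0
    while i < k:
        j = i
        while j + 1 < k and ranks.iloc[j + 1] - ranks.iloc[i] < comparison.critical_difference:
            j += 1
        if j > i:
            ax.hlines(level, ranks.iloc[i], ranks.iloc[j], color="black", lw=3)
            level += 0.12
        i = j + 1 if j > i else i + 1
    ax.annotate(
        f"CD = {comparison.critical_difference:.2f}",
        xy=(1, level + 0.2), fontsize=9,
    )
    ax.set_xlim(0.5, k + 0.5)
    ax.set_ylim(-0.3 * (k + 2), level + 0.5)
    ax.set_yticks([])
    ax.set_xlabel("average rank (1 = best)")
    ax.set_title(comparison.family)
    return ax
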