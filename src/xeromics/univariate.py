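"""Univariate feature screening for NTCP modeling.

Each candidate feature is scored against the binary end point with the
rank-based AUC derived from the Mann-Whitney U statistic, with a 95%
bias-corrected accelerated (BCa) bootstrap confidence interval stratified by
class.  Multiplicity over features is controlled at FDR <= q with the
adaptive Gavrilov-Benjamini-Sarkar (GBS) step-down procedure.  For every
feature a univariate logistic model additionally yields tolerance values
TVp — the feature value at which the predicted complication probability is
p — and the truth-bound arithmetic converts an FDR level into lower bounds
on the number of true discoveries.

The screen is exposed statsmodels-style: build a :class:`UnivariateScreen`
from a feature table and labels, call :meth:`~UnivariateScreen.fit`, inspect
the returned results object (`results`, `summary()`, `write_csv`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable

__all__ = [
    "mwu_auc",
    "mwu_pvalue",
    "bca_interval",
    "gbs_stepdown",
    "tolerance_values",
    "fdr_truth_bounds",
    "UnivariateScreen",
    "UnivariateScreenResults",
]


def _split_classes(values: np.ndarray, labels: np.ndarray):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    neg = values[labels == 0]
    pos = values[labels == 1]
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both classes must be nonempty")
    return neg, pos


def mwu_auc(values, labels) -> tuple[float, float]:
    """Mann-Whitney U statistic and the derived AUC.

    U is computed with midranks (tied observations share the average rank)
    and AUC = U / (n_neg * n_pos), which equals the fraction of
    (negative, positive) pairs where the positive observation has the larger
    feature value, ties counting one half.
    """
    neg, pos = _split_classes(values, labels)
    n_neg, n_pos = neg.size, pos.size
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    rank_sum_pos = ranks[n_neg:].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u), float(u / (n_neg * n_pos))


def mwu_pvalue(values, labels) -> float:
    """Two-sided Mann-Whitney p-value (normal approximation, tie- and
    continuity-corrected)."""
    neg, pos = _split_classes(values, labels)
    res = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def bca_interval(
    data,
    statistic,
    n_boot: int = 2000,
    level: float = 0.95,
    labels=None,
    rng=None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for a statistic.

    When ``labels`` is given, resampling is stratified: the negative and
    positive observations are resampled independently (class counts are
    preserved in every replicate) and ``statistic(neg, pos)`` is evaluated.
    Otherwise ``statistic(sample)`` is bootstrapped on the single sample.

    A degenerate bootstrap distribution (all replicates equal) yields a
    zero-width interval with a warning instead of an error.
    """
    rng = np.random.default_rng(rng)
    if labels is not None:
        neg, pos = _split_classes(np.asarray(data, dtype=float), np.asarray(labels))
        samples = (neg, pos)
        stat = statistic
        theta = float(statistic(neg, pos))
    else:
        arr = np.asarray(data, dtype=float)
        samples = (arr,)
        stat = statistic
        theta = float(statistic(arr))
    if min(s.size for s in samples) < 2:
        raise ValueError("each resampled class needs at least 2 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.bootstrap(
            samples,
            stat,
            n_resamples=n_boot,
            confidence_level=level,
            method="BCa",
            vectorized=False,
            paired=False,
            rng=rng,
        )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):
        warnings.warn("degenerate bootstrap distribution; returning zero-width interval")
        return theta, theta
    return lo, hi


def gbs_stepdown(pvalues, q: float = 0.05) -> np.ndarray:
    """Adaptive step-down multiple testing bounding the FDR at ``q``.

    Sorted p-values are compared against the critical constants

        c_i = i * q / (m + 1 - i * (1 - q)),   i = 1..m,

    and the largest prefix with p_(i) <= c_i for every i in the prefix is
    rejected.  Returns a boolean rejection flag per input p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    i = np.arange(1, m + 1)
    crit = i * q / (m + 1 - i * (1 - q))
    ok = p[order] <= crit
    below = np.nonzero(~ok)[0]
    k = m if below.size == 0 else below[0]  # reject the largest passing prefix
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


def tolerance_values(
    values, labels, probabilities=(0.20, 0.10, 0.05)
) -> dict[float, float]:
    """Feature values at which a univariate logistic model predicts risk p.

    Fits P(event | x) = expit(b0 + b1 x) and inverts it:
    TVp = (logit(p) - b0) / b1, reported in the feature's own units.  A
    non-informative feature (|b1| ~ 0) has no defined tolerance value and
    raises ``ValueError``.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    _split_classes(values, labels)  # validates
    labels = np.asarray(labels).astype(int)
    X = sm.add_constant(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(labels, X).fit(disp=0, maxiter=200)
    b0, b1 = fit.params
    scale = max(np.std(values), 1.0)
    if abs(b1) * scale < 1e-8:
        raise ValueError("slope ~ 0: tolerance values undefined for a non-informative feature")
    out = {}
    for p in probabilities:
        if not 0 < p < 1:
            raise ValueError(f"probability must be in (0, 1), got {p}")
        out[p] = float((np.log(p / (1 - p)) - b0) / b1)
    return out


def fdr_truth_bounds(n_rejections: int, q: float) -> tuple[float, float]:
    """Lower bounds on discovery truth implied by an FDR level.

    Treating each of R discoveries as independently false with probability q,
    the probability that all R are true is (1-q)^R and the probability that
    at most one is false adds the one-failure binomial term
    R q (1-q)^(R-1).
    """
    if n_rejections < 1:
        raise ValueError("need at least one rejection")
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    r = int(n_rejections)
    p_all = (1 - q) ** r
    p_one = p_all + r * q * (1 - q) ** (r - 1)
    return float(p_all), float(p_one)


# ---------------------------------------------------------------------------
# the screen


@dataclass
class UnivariateScreenResults:
    """Per-feature screen results.

    ``results`` has one row per screened feature: AUC with its BCa interval,
    the U statistic and class sizes, the two-sided MWU p-value, the GBS
    significance flag, and tolerance values TV20/TV10/TV5 in the feature's
    units (NaN where the logistic slope is ~0).

    The reported AUC is the *discrimination*: protective features (raw AUC
    below 0.5) are orientation-flipped so every AUC is >= 0.5, with
    ``direction`` recording -1 for protective and +1 for risk features.
    """

    results: pd.DataFrame
    q: float
    n_boot: int
    skipped: list[str]

    @property
    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]]

    def truth_bounds(self) -> tuple[float, float] | None:
        """FDR truth bounds for the observed number of discoveries."""
        r = int(self.results["significant"].sum())
        if r == 0:
            return None
        return fdr_truth_bounds(r, self.q)

    def summary(self, top: int | None = None) -> str:
        df = self.results.sort_values("auc", ascending=False)
        if top is not None:
            df = df.head(top)
        lines = [
            f"Univariate screen: {len(self.results)} features, "
            f"n- = {self.results['n_neg'].iat[0]}, n+ = {self.results['n_pos'].iat[0]}, "
            f"FDR <= {self.q} (GBS), {self.n_boot} bootstrap replicates",
            f"{'feature':<22}{'group':<24}{'AUC':>6}  {'95% CI':>14}  sig",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['feature']:<22}{r['group']:<24}{r['auc']:>6.3f}  "
                f"({r['ci_lo']:.3f}-{r['ci_hi']:.3f})  {'*' if r['significant'] else ''}"
            )
        bounds = self.truth_bounds()
        if bounds:
            lines.append(
                f"{int(self.results['significant'].sum())} discoveries; "
                f"P(all true) >= {100 * bounds[0]:.1f}%, "
                f"P(<=1 false) >= {100 * bounds[1]:.1f}%"
            )
        return "\n".join(lines)

    def write_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


class UnivariateScreen:
    """Univariate association screen of a feature table against an end point.

    Parameters
    ----------
    table
        :class:`~xeromics.features.FeatureTable` or a wide DataFrame
        (patients x features).
    labels
        Binary end-point labels aligned with the table rows.
    """

    def __init__(self, table: FeatureTable | pd.DataFrame, labels):
        self.table = table if isinstance(table, FeatureTable) else FeatureTable(table)
        self.labels = np.asarray(labels).astype(int)
        if len(self.labels) != len(self.table):
            raise ValueError("labels length does not match the feature table")
        if self.table.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    def fit(
        self, n_boot: int = 2000, q: float = 0.05, rng=None
    ) -> UnivariateScreenResults:
        """Run the screen.

        Features are z-score normalized (population SD) before ranking — a
        no-op for the rank-based AUC but it keeps the screen's preprocessing
        aligned with the multivariate pipeline; tolerance values are fitted
        on the raw feature so they come out in interpretable units.
        """
        rng = np.random.default_rng(rng)
        meta = self.table.metadata.set_index("feature")
        n_neg = int((self.labels == 0).sum())
        n_pos = int((self.labels == 1).sum())
        rows = []
        pvals = []
        skipped: list[str] = []
        auc_stat = lambda neg, pos: mwu_auc(
            np.concatenate([neg, pos]),
            np.concatenate([np.zeros(len(neg), int), np.ones(len(pos), int)]),
        )[1]
        for col in self.table.data.columns:
            raw = self.table.data[col].to_numpy(dtype=float)
            if np.ptp(raw) == 0:
                warnings.warn(f"feature {col!r} is constant; skipped")
                skipped.append(col)
                continue
            z = (raw - raw.mean()) / raw.std(ddof=0)
            u, auc = mwu_auc(z, self.labels)
            ci = bca_interval(
                z, auc_stat, n_boot=n_boot, labels=self.labels, rng=rng
            )
            # report discrimination: orient protective features (AUC < 0.5)
            # so the screen's AUC is always >= 0.5, flagging the direction
            direction = 1 if auc >= 0.5 else -1
            if direction < 0:
                u = n_neg * n_pos - u
                auc = 1.0 - auc
                ci = (1.0 - ci[1], 1.0 - ci[0])
            try:
                tvs = tolerance_values(raw, self.labels)
            except (ValueError, np.linalg.LinAlgError):
                tvs = {0.20: np.nan, 0.10: np.nan, 0.05: np.nan}
            pvals.append(mwu_pvalue(z, self.labels))
            rows.append(
                {
                    "feature": col,
                    "group": meta.loc[col, "group"],
                    "side": meta.loc[col, "side"],
                    "auc": auc,
                    "direction": direction,
                    "ci_lo": ci[0],
                    "ci_hi": ci[1],
                    "u_statistic": u,
                    "n_neg": n_neg,
                    "n_pos": n_pos,
                    "p_value": pvals[-1],
                    "tv20": tvs[0.20],
                    "tv10": tvs[0.10],
                    "tv5": tvs[0.05],
                }
            )
        if not rows:
            raise ValueError("no non-constant features to screen")
        df = pd.DataFrame(rows)
        df["significant"] = gbs_stepdown(np.asarray(pvals), q=q)
        return UnivariateScreenResults(results=df, q=q, n_boot=n_boot, skipped=skipped)
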