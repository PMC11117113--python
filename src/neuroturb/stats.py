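"""Between-condition statistics for paired pharmacological designs.

The workhorse is a permutation paired t-test: the observed paired t
statistic is referred to a null built by randomly sign-flipping the
per-subject condition differences (exhaustive enumeration when feasible).
Multiple comparisons across the lambda scan are handled by
Benjamini-Hochberg FDR.  Susceptibility and information capability are
compared with the Wilcoxon rank-sum test; node-level turbulence
distributions with the Kolmogorov-Smirnov distance; effect sizes with
Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSample",
    "TestResult",
    "permutation_paired_ttest",
    "fdr_correct",
    "wilcoxon_ranksum",
    "cohens_d",
    "ksd",
    "network_attribution",
]


@dataclass
class PairedSample:
    """Per-subject values under two conditions, paired by position."""

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired samples must be equal-length 1-D vectors")
        if self.values_a.size < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int = 0
    effect_size_d: float = float("nan")
    degenerate: bool = False
    exhaustive: bool = False


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
    return float(d.mean() / (sd / np.sqrt(d.size)))


def permutation_paired_ttest(
    sample: PairedSample,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> TestResult:
    """Sign-flip permutation test of the paired t statistic.

    When ``2**n_pairs <= n_perm`` all sign patterns are enumerated and the
    p-value is the exact proportion of the null at least as extreme as the
    observed statistic; otherwise ``n_perm`` random flips are drawn and the
    add-one convention ``p = (1 + hits) / (1 + n_perm)`` keeps p off zero.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = sample.differences
    n = d.size
    if np.all(d == 0):
        return TestResult(0.0, 1.0, 0, 0.0, degenerate=True)
    t_obs = _paired_t(d)

    def extremity(t_null: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(t_null) >= abs(t_obs)
        if alternative == "greater":
            return t_null >= t_obs
        return t_null <= t_obs

    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(
            [[1 if (m >> k) & 1 else -1 for k in range(n)] for m in range(2**n)]
        )
        flipped = signs * d
        with np.errstate(divide="ignore", invalid="ignore"):
            means = flipped.mean(axis=1)
            sds = flipped.std(axis=1, ddof=1)
            t_null = np.where(
                sds > 0,
                means / (sds / np.sqrt(n)),
                np.where(means != 0, np.inf * np.sign(means), 0.0),
            )
        p = float(extremity(t_null).mean())
        n_used = 2**n
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        flipped = signs * d
        means = flipped.mean(axis=1)
        sds = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(
                sds > 0,
                means / (sds / np.sqrt(n)),
                np.where(means != 0, np.inf * np.sign(means), 0.0),
            )
        p = float((1 + extremity(t_null).sum()) / (1 + n_perm))
        n_used = n_perm
    d_eff = cohens_d(sample) if sample.values_a.std() + sample.values_b.std() > 0 else 0.0
    return TestResult(t_obs, p, n_used, d_eff, exhaustive=exhaustive)


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (reject mask, adjusted p)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value vector")
    if ((p_values < 0) | (p_values > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, p_adj


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null when the combined sample is small (n <= 20) and tie-free;
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(x.size * y.size / 2.0, 1.0, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue))


def cohens_d(sample: PairedSample, convention: str = "pooled") -> float:
    """Effect size of a paired difference.

    ``pooled`` (default): mean difference over the pooled standard
    deviation of the two condition samples.  ``paired``: mean difference
    over the standard deviation of the within-pair differences.
    """
    a, b = sample.values_a, sample.values_b
    if convention == "paired":
        sd = sample.differences.std(ddof=1)
    elif convention == "pooled":
        n = a.size
        sd = np.sqrt(((n - 1) * a.var(ddof=1) + (n - 1) * b.var(ddof=1)) / (2 * n - 2))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if sd == 0:
        if sample.differences.mean() == 0:
            return 0.0
        raise ValueError("zero standard deviation with nonzero mean difference")
    return float(sample.differences.mean() / sd)


def ksd(x: np.ndarray, y: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance between two empirical CDFs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(sp_stats.ks_2samp(x, y).statistic)


def network_attribution(
    node_diff: np.ndarray,
    labels: list[str] | np.ndarray,
    quantile: float = 0.15,
) -> pd.Series:
    """Count top-quantile nodes per resting-state network.

    Selects the nodes whose value is at or above the (1 - quantile)
    empirical quantile (ties at the threshold are all included) and tallies
    them by network label.  Every label present in ``labels`` appears in
    the result, with zero where no node was selected.
    """
    node_diff = np.asarray(node_diff, dtype=float)
    labels = np.asarray(labels)
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if node_diff.size != labels.size:
        raise ValueError("labels must cover all nodes")
    threshold = np.quantile(node_diff, 1.0 - quantile)
    selected = node_diff >= threshold
    counts = (
        pd.Series(labels[selected])
        .value_counts()
        .reindex(pd.unique(labels), fill_value=0)
        .astype(int)
    )
    counts.name = "n_nodes"
    return counts
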