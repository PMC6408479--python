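"""Nonparametric statistics used by the analyses.

* Mann-Whitney U for two independent groups (exact null when small and
  tie-free, tie-corrected normal approximation otherwise; scipy backs
  the computation).
* Steel's many-to-one test: each treatment group is compared with a
  shared control by a pairwise rank-sum statistic, and the family-wise
  error is controlled through the permutation null of the maximum
  standardized statistic across comparisons.
* Pearson correlation with r² and the t-based two-sided p-value.

Significance is read at alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "mann_whitney_u",
    "steel_test",
    "pearson_correlation",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of real-valued measurements."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("a group needs at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def mann_whitney_u(
    a: GroupSample, b: GroupSample, alternative: str = "two_sided"
) -> TestResult:
    """Mann-Whitney U test between two groups.

    Exact enumeration null when n_a + n_b <= 20 and the pooled sample
    is tie-free; tie-corrected normal approximation otherwise. The U
    statistic reported is the count for the first group.
    """
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    xa, xb = a.array, b.array
    pooled = np.concatenate([xa, xb])
    if np.ptp(pooled) == 0:
        return TestResult(
            statistic=float(len(xa) * len(xb) / 2),
            p_value=1.0,
            method="mann_whitney_u",
            n_per_group=(a.n, b.n),
            degenerate=True,
        )
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.n + b.n <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative=alt, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann_whitney_u[{method}]",
        n_per_group=(a.n, b.n),
    )


def _pair_rank_stats(
    control: np.ndarray, treatment: np.ndarray
) -> tuple[float, float, float]:
    """Treatment rank-sum W in the pooled pair, with its exact
    finite-population mean and variance given the observed rank multiset
    (equals the classical tie-corrected moments)."""
    pooled = np.concatenate([control, treatment])
    ranks = sps.rankdata(pooled)
    n = len(treatment)
    big_n = len(pooled)
    w = float(ranks[len(control) :].sum())
    mean = n * ranks.mean()
    var = n * (big_n - n) / (big_n - 1) * ranks.var()
    return w, float(mean), float(var)


def _standardized(
    w: np.ndarray, ranks: np.ndarray, n_treat: int
) -> np.ndarray:
    """Vectorized z for rank-sums drawn without replacement from rank rows."""
    big_n = ranks.shape[-1]
    mean = n_treat * ranks.mean(axis=-1)
    var = n_treat * (big_n - n_treat) / (big_n - 1) * ranks.var(axis=-1)
    var = np.maximum(var, 1e-30)
    return (w - mean) / np.sqrt(var)


def steel_test(
    control: GroupSample,
    treatments: list[GroupSample],
    alternative: str = "two_sided",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> list[TestResult]:
    """Steel's nonparametric many-to-one comparisons against a control.

    For each treatment the pairwise rank-sum of the treatment values in
    (control, treatment) is standardized; the family-wise adjusted
    p-value is the permutation tail probability of the maximum
    standardized statistic across all comparisons, estimated from
    ``n_permutations`` seeded relabelings of the pooled observations.
    """
    if len(treatments) < 1:
        raise ValueError("need at least one treatment group")
    if control.n < 2:
        raise ValueError("control group needs n >= 2")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError("unknown alternative")

    m = control.n
    sizes = [t.n for t in treatments]
    pooled = np.concatenate([control.array] + [t.array for t in treatments])
    n_tot = len(pooled)

    # observed standardized statistics
    z_obs = np.empty(len(treatments))
    w_obs = np.empty(len(treatments))
    for i, t in enumerate(treatments):
        w, mean, var = _pair_rank_stats(control.array, t.array)
        w_obs[i] = w
        z_obs[i] = (w - mean) / np.sqrt(max(var, 1e-30))

    def directed(z: np.ndarray) -> np.ndarray:
        if alternative == "two_sided":
            return np.abs(z)
        if alternative == "greater":
            return z
        return -z

    # permutation null of max directed z across comparisons
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_permutations, n_tot)), axis=1)
    data_perm = pooled[perm]
    ctrl_perm = data_perm[:, :m]
    max_stat = np.full(n_permutations, -np.inf)
    start = m
    for n_i in sizes:
        treat_perm = data_perm[:, start : start + n_i]
        start += n_i
        pair = np.concatenate([ctrl_perm, treat_perm], axis=1)
        ranks = sps.rankdata(pair, axis=1)
        w = ranks[:, m:].sum(axis=1)
        z = _standardized(w, ranks, n_i)
        max_stat = np.maximum(max_stat, directed(z))

    results = []
    d_obs = directed(z_obs)
    for i, t in enumerate(treatments):
        p = float((1 + np.sum(max_stat >= d_obs[i])) / (n_permutations + 1))
        results.append(
            TestResult(
                statistic=float(z_obs[i]),
                p_value=p,
                method="steel[permutation]",
                n_per_group=(m, t.n),
            )
        )
    return results


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Sample Pearson r, r², and the two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r**2), float(p)
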