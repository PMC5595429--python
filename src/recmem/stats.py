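"""Small-sample nonparametric group statistics.

Everything here is two-sided with alpha conventionally at 0.05:
Mann-Whitney U (exact by enumeration for small untied samples),
label-permutation tests (exhaustive when the number of splits is modest),
the rank-based stochastic-superiority effect size A, Spearman correlation,
Pearson chi-square, Bonferroni-Holm step-down adjustment, and the
cross-task z-score summaries that average each subject's per-task indices
against the control distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "SpearmanResult",
    "mann_whitney",
    "effect_size_A",
    "permutation_test",
    "spearman_rho",
    "holm_correct",
    "chi_square",
    "z_summary",
]

# below this product of group sizes an untied Mann-Whitney p is exact
EXACT_MW_LIMIT = 400
# at or below this many label splits the permutation test enumerates them all
EXHAUSTIVE_PERM_LIMIT = 50_000


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    effect_A: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect_A": self.effect_A,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    undefined: bool = False


def _validate_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def effect_size_A(a, b) -> float:
    """Stochastic superiority A = P(a > b) + 0.5 P(a = b), by pair counting.

    0.5 means no effect; conventional bands read roughly 0.56-0.64 as
    small, 0.65-0.71 medium, above 0.71 large.
    """
    a = _validate_sample(a, "a")
    b = _validate_sample(b, "b")
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (a.size * b.size))


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U test for the first sample.

    Exact p by enumeration when n1*n2 <= 400 and the pooled sample has no
    ties, otherwise the normal approximation with the midrank tie
    correction. The reported U counts pairs where a exceeds b (ties half).
    """
    a = _validate_sample(a, "a")
    b = _validate_sample(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            "U", a.size * b.size / 2, 1.0, a.size, b.size, "mann_whitney",
            effect_A=0.5,
        )
    method = "exact" if (not has_ties and a.size * b.size <= EXACT_MW_LIMIT) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return GroupComparison(
        "U", float(res.statistic), float(min(res.pvalue, 1.0)),
        a.size, b.size, "mann_whitney", effect_A=effect_size_A(a, b),
    )


_PERM_STATS = {
    "mean_diff": lambda a, b: np.mean(a) - np.mean(b),
    "median_diff": lambda a, b: np.median(a) - np.median(b),
    "rank_sum": None,  # handled on pooled ranks below
}


def permutation_test(
    a, b, statistic: str = "mean_diff", n_perm: int = 10_000, seed: int = 0
) -> GroupComparison:
    """Two-sided label-permutation test.

    All C(n1+n2, n1) splits are enumerated when there are at most 50,000 of
    them; otherwise ``n_perm`` seeded random shuffles are used with the
    add-one p-value (1 + #extreme) / (1 + n_perm). ``statistic`` is the
    difference in group means (default), in medians, or the first group's
    rank sum.
    """
    if statistic not in _PERM_STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = _validate_sample(a, "a")
    b = _validate_sample(b, "b")
    n1, n = a.size, a.size + b.size
    pooled = np.concatenate([a, b])
    if statistic == "rank_sum":
        pooled = rankdata(pooled)
        stat = lambda x, y: np.sum(x)  # noqa: E731
    else:
        stat = _PERM_STATS[statistic]

    center = np.sum(pooled) * n1 / n if statistic == "rank_sum" else 0.0
    t_obs = stat(pooled[:n1], pooled[n1:]) - center
    n_splits = comb(n, n1)
    if n_splits <= EXHAUSTIVE_PERM_LIMIT:
        count = 0
        idx_all = np.arange(n)
        for idx in combinations(range(n), n1):
            sel = np.asarray(idx)
            rest = np.setdiff1d(idx_all, sel, assume_unique=True)
            t = stat(pooled[sel], pooled[rest]) - center
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        p = count / n_splits
        method = "permutation_exact"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        block = 2_000  # vectorized shuffles in chunks to bound memory
        done = 0
        while done < n_perm:
            m = min(block, n_perm - done)
            perms = rng.permuted(np.broadcast_to(pooled, (m, n)).copy(), axis=1)
            if statistic == "mean_diff":
                t = perms[:, :n1].mean(axis=1) - perms[:, n1:].mean(axis=1)
            elif statistic == "median_diff":
                t = np.median(perms[:, :n1], axis=1) - np.median(perms[:, n1:], axis=1)
            else:
                t = perms[:, :n1].sum(axis=1) - center
            count += int(np.sum(np.abs(t) >= abs(t_obs) - 1e-12))
            done += m
        p = (1 + count) / (1 + n_perm)
        method = "permutation_mc"
    return GroupComparison(
        statistic, float(t_obs if statistic != "rank_sum" else t_obs + center),
        float(min(p, 1.0)), n1, b.size, method, effect_A=effect_size_A(a, b),
    )


def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation with an exact permutation p for n <= 8.

    Larger samples use the t approximation. A constant ranking in either
    variable leaves rho undefined; the result is flagged rather than raised.
    """
    x = _validate_sample(x, "x")
    y = _validate_sample(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return SpearmanResult(float("nan"), float("nan"), x.size, undefined=True)
    rho, p = spearmanr(x, y)
    if x.size <= 8:
        rx, ry = rankdata(x), rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        count = total = 0
        for perm in permutations(ry):
            ry_p = np.asarray(perm)
            r = float(np.mean(rx * (ry_p - ry_p.mean()) / ry_p.std()))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    return SpearmanResult(float(rho), float(p), x.size)


def holm_correct(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be a 2-d array of non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square is undefined with a zero marginal")
    stat, p, _, _ = chi2_contingency(t, correction=False)
    return float(stat), float(p)


def z_summary(
    indices: pd.DataFrame,
    control_ids,
    index_cols: tuple[str, ...] = ("d_prime", "R_index", "F_index"),
) -> pd.DataFrame:
    """Cross-task z-score summaries against the control distribution.

    ``indices`` is the long per-subject table (columns subject_id, task and
    the index columns); each index is z-transformed per task using the
    control mean and SD (ddof=1) and averaged over tasks. Subjects missing
    any task are excluded. Returns one row per subject with columns
    z_<index>.
    """
    control_ids = set(control_ids)
    tasks = sorted(indices["task"].unique())
    complete = indices.groupby("subject_id")["task"].nunique()
    keep = complete[complete == len(tasks)].index
    df = indices[indices["subject_id"].isin(keep)]

    ref = df[df["subject_id"].isin(control_ids)]
    if ref["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 complete control subjects")
    out = {}
    for col in index_cols:
        zs = []
        for task in tasks:
            sub = df[df["task"] == task].set_index("subject_id")[col]
            ctrl = sub[sub.index.isin(control_ids)]
            mu, sd = ctrl.mean(), ctrl.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero control SD for {col} in task {task}")
            zs.append((sub - mu) / sd)
        out[f"z_{col}"] = pd.concat(zs, axis=1).mean(axis=1)
    res = pd.DataFrame(out)
    res.index.name = "subject_id"
    return res.reset_index()
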