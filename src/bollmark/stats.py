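"""Nonparametric group comparisons for mark features.

Mark areas and intensity ratios are skewed, so group differences are tested
rank-based: Kruskal-Wallis across the three mark classes (infested,
control, needle), Dunn's multiple-comparison post test for pairwise
contrasts, and the Wilcoxon signed-rank test for deviation of a sample
median from a hypothetical value (e.g. I1/I2 = 1).  Significance level
defaults to α = 0.05.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_signed_rank",
]


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} has non-finite values")
        out[name] = arr
    return out


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], exact: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with its p-value.

    By default p comes from the chi-square approximation with k−1 degrees
    of freedom; ``exact=True`` replaces it with the exhaustive permutation
    p-value P(H ≥ H_obs) over all assignments of the pooled values to the
    group sizes (small samples only, total n ≤ 13).  All values identical
    → (0, 1).
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(a.size for a in g.values())
    if n_total < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(list(g.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*g.values())
    if exact:
        if n_total > 13:
            raise ValueError("exact mode supported for total n <= 13 only")
        p = _kw_permutation_p(list(g.values()), float(h))
    return float(h), float(p)


def _h_statistic(rank_sums: np.ndarray, sizes: np.ndarray, n: int, tie_corr: float) -> float:
    h = 12.0 / (n * (n + 1)) * float(np.sum(rank_sums**2 / sizes)) - 3.0 * (n + 1)
    return h / tie_corr


def _kw_permutation_p(arrays: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p: enumerate every split of the pooled ranks into
    the observed group sizes and count H ≥ H_obs."""
    from itertools import combinations

    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    _, t = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float(np.sum(t**3 - t)) / (n**3 - n)
    sizes = np.array([a.size for a in arrays])

    count = 0
    total = 0

    def recurse(avail: tuple[int, ...], gi: int, rank_sums: list[float]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            rs = np.array(rank_sums + [ranks[list(avail)].sum()])
            h = _h_statistic(rs, sizes, n, tie_corr)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for chosen in combinations(avail, int(sizes[gi])):
            rest = tuple(i for i in avail if i not in set(chosen))
            recurse(rest, gi + 1, rank_sums + [ranks[list(chosen)].sum()])

    recurse(tuple(range(n)), 0, [])
    return count / total


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    p_adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's multiple-comparison test on pooled ranks.

    For each pair (i, j): z = (R̄_i − R̄_j) / sqrt(S²·(1/n_i + 1/n_j)) with
    S² = N(N+1)/12 − Σ(t³−t)/(12(N−1)) the tie-corrected rank variance.
    Two-sided p-values are family-wise adjusted (Bonferroni by default,
    Holm optional).  Pairs involving a group of size < 2 are flagged
    untestable (nan statistics).
    """
    if p_adjust not in ("bonferroni", "holm"):
        raise ValueError("p_adjust must be 'bonferroni' or 'holm'")
    g = _as_groups(groups)
    names = list(g)
    pooled = np.concatenate([g[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # per-group mean ranks
    mean_rank = {}
    start = 0
    for n in names:
        k = g[n].size
        mean_rank[n] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        na, nb = g[a].size, g[b].size
        if na < 2 or nb < 2:
            rows.append(
                {"group1": a, "group2": b, "z": np.nan, "p_raw": np.nan,
                 "p_adj": np.nan, "significant": False, "testable": False}
            )
            continue
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        if se == 0:  # all pooled values identical
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group1": a, "group2": b, "z": float(z), "p_raw": float(p),
             "p_adj": np.nan, "significant": False, "testable": True}
        )
    df = pd.DataFrame(rows)
    testable = df["testable"]
    m = int(testable.sum())
    if m:
        praw = df.loc[testable, "p_raw"].to_numpy()
        if p_adjust == "bonferroni":
            padj = np.minimum(praw * m, 1.0)
        else:  # holm
            order = np.argsort(praw)
            padj = np.empty_like(praw)
            running = 0.0
            for rank_i, idx in enumerate(order):
                running = max(running, (m - rank_i) * praw[idx])
                padj[idx] = min(running, 1.0)
        df.loc[testable, "p_adj"] = padj
        df.loc[testable, "significant"] = padj < alpha
    return df


def wilcoxon_signed_rank(
    sample: Sequence[float], mu0: float = 1.0
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of a sample median against ``mu0``.

    Differences exactly equal to ``mu0`` are dropped (Wilcoxon's rule);
    at least 5 non-zero differences are required.  The exact null
    distribution is used for n ≤ 25 when the absolute differences are
    untied, the tie-corrected normal approximation otherwise.  Returns the
    two-sided (V, p) with V = Σ ranks of positive differences.
    """
    d = np.asarray(sample, dtype=np.float64) - mu0
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite sample values")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal mu0: untestable")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    no_ties = np.unique(np.abs(d)).size == n
    method = "exact" if (n <= 25 and no_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return _v_plus(d), float(res.pvalue)


def _v_plus(d: np.ndarray) -> float:
    """Sum of ranks of the positive differences (scipy's two-sided statistic
    is min(V+, V−); the conventional report is V+)."""
    r = sps.rankdata(np.abs(d))
    return float(r[d > 0].sum())
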