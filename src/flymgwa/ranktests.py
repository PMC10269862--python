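"""Rank-based two-sample tests shared by the assay and association stages.

All two-group comparisons in the pipeline reduce to the Wilcoxon rank-sum
statistic W (the sum of pooled midranks in the first group).  Three p-value
routes are used, in order of preference:

* full enumeration of all C(N, n1) group assignments of the pooled midranks
  when the combined sample size N is small (handles ties exactly);
* the classic exact no-tie distribution (via the Mann-Whitney recursion)
  when either group is small and the pooled values are distinct;
* a tie-corrected normal approximation otherwise.

Two-sided enumeration p-values are defined as P(|W - E[W]| >= |w - E[W]|),
which coincides with tail doubling when the null distribution is symmetric
(always the case without ties).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

#: largest combined sample size for which group assignments are enumerated
EXACT_ENUMERATION_LIMIT = 16

#: largest "small group" size for which the no-tie exact distribution is used
EXACT_SMALL_GROUP_LIMIT = 8

_ABS_TOL = 1e-9


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a two-group rank-sum comparison."""

    statistic: float  # W: sum of pooled midranks in the first group
    p: float
    method: str  # "enumeration", "exact", or "normal"
    n1: int
    n2: int


def _validate_groups(x: np.ndarray, y: np.ndarray) -> None:
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")


def tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _enumeration_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    n = len(ranks)
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        w = ranks[list(comb)].sum()
        if abs(w - mu) >= dev - _ABS_TOL:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(
    x,
    y,
    *,
    enumeration_limit: int = EXACT_ENUMERATION_LIMIT,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` versus ``y``.

    Returns the rank-sum statistic of ``x`` (pooled midranks) and a two-sided
    p-value computed by enumeration, the no-tie exact distribution, or a
    tie-corrected normal approximation, depending on sample sizes and ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_groups(x, y)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= enumeration_limit:
        p = _enumeration_p(ranks, n1, w)
        return RankSumResult(w, p, "enumeration", n1, n2)

    if not has_ties and min(n1, n2) <= EXACT_SMALL_GROUP_LIMIT:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(w, float(res.pvalue), "exact", n1, n2)

    mu = n1 * (n + 1) / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term(pooled) / (n * (n - 1)))
    if sigma2 <= 0:  # all pooled values identical
        return RankSumResult(w, 1.0, "normal", n1, n2)
    z = (w - mu) / math.sqrt(sigma2)
    p = 2.0 * _sps.norm.sf(abs(z))
    return RankSumResult(w, min(1.0, p), "normal", n1, n2)


def kruskal_h(groups: list[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H and its degrees of freedom.

    H is zero when every pooled value is identical (scipy raises there).
    """
    pooled = np.concatenate(groups)
    if len(np.unique(pooled)) == 1:
        return 0.0, len(groups) - 1
    h, _ = _sps.kruskal(*groups)
    return float(h), len(groups) - 1


def kruskal_p(groups: list[np.ndarray]) -> tuple[float, int, float, str]:
    """(H, df, p, method) for a Kruskal-Wallis test.

    For two groups with small combined n the p-value comes from the exact
    rank-sum permutation distribution (the two tests are equivalent there);
    otherwise from the chi-square upper tail.
    """
    h, df = kruskal_h(groups)
    n = sum(len(g) for g in groups)
    if len(groups) == 2 and n <= EXACT_ENUMERATION_LIMIT:
        res = rank_sum_test(groups[0], groups[1])
        return h, df, res.p, "enumeration"
    if h == 0.0:
        return h, df, 1.0, "chi2"
    return h, df, float(_sps.chi2.sf(h, df)), "chi2"


def dunn_z_matrix(groups: list[np.ndarray]) -> np.ndarray:
    """Pairwise Dunn z statistics from pooled tie-corrected midranks.

    Entry (i, j) is the standardized difference of mean pooled ranks
    between groups i and j.
    """
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    mean_ranks = np.array(mean_ranks)
    var_unit = n * (n + 1) / 12.0 - tie_term(pooled) / (12.0 * (n - 1))
    k = len(groups)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            z[i, j] = zij
            z[j, i] = -zij
    return z


def compact_letter_display(
    labels: list, different: set[tuple]
) -> dict:
    """Assign significance letters by the insert-and-absorb algorithm.

    ``different`` holds unordered pairs of labels declared significantly
    different.  Two labels share a letter iff their pair is not in
    ``different``: each split preserves every other pair, and absorption
    only removes redundant subsets.
    """
    columns: list[set] = [set(labels)]
    for a, b in sorted((tuple(sorted(p, key=str)) for p in different), key=str):
        new_columns: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, duplicates, and proper subsets
        uniq: list[set] = []
        for col in new_columns:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]
    # deterministic letter order: by the smallest member label
    columns.sort(key=lambda col: sorted(map(str, col)))
    letters = {lab: "" for lab in labels}
    for idx, col in enumerate(columns):
        char = _letter(idx)
        for lab in col:
            letters[lab] += char
    return {lab: "".join(sorted(s)) for lab, s in letters.items()}


def _letter(idx: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    idx += 1
    while idx > 0:
        idx, rem = divmod(idx - 1, 26)
        out = alphabet[rem] + out
    return out
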