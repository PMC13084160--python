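"""Nonparametric and parametric tests used to annotate the readouts.

The battery matches the figure legends of the study this pipeline
emulates: Kruskal-Wallis across conditions followed by Dunn's post hoc
test or pairwise Wilcoxon rank-sum tests, with Bonferroni, Holm
("Holm-Bonferroni" in some legends — the same step-down procedure), or
Benjamini-Hochberg correction; two-sample Wilcoxon rank-sum and Welch t
tests; Pearson's chi-squared for count tables. All tests are two-sided.

Kruskal-Wallis, Dunn, the rank-sum test (exact by enumeration for
combined n <= 20 without ties, normal approximation with tie correction
otherwise), chi-squared, and the p-value adjustments are implemented here
from their rank / expected-count definitions; only the Welch t test is
delegated to scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist, norm, rankdata, ttest_ind

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "adjust_pvalues",
    "rank_sum_and_t",
    "chi_squared",
    "significance_code",
    "GroupComparison",
    "compare_groups",
]


def _group_arrays(values: Sequence[float], groups: Sequence) -> Dict[object, np.ndarray]:
    values = np.asarray(list(values), dtype=float)
    groups = np.asarray(list(groups))
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    return {g: values[groups == g] for g in pd.unique(groups)}


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared (k-1 df).

    With every observation identical the tie correction degenerates; by
    convention H = 0 and p = 1 (no evidence of any difference).
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(v) < 1 for v in by_group.values()):
        raise ValueError("every group needs at least one value")
    all_vals = np.concatenate(list(by_group.values()))
    n = len(all_vals)
    ranks = rankdata(all_vals)
    h = 0.0
    start = 0
    for v in by_group.values():
        r = ranks[start:start + len(v)]
        h += len(v) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(v)
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(all_vals) / (n ** 3 - n)
    if correction <= 0:  # all values tied
        return 0.0, 1.0
    h /= correction
    p = float(chi2_dist.sf(h, len(by_group) - 1))
    return float(h), p


def dunn_posthoc(values: Sequence[float], groups: Sequence,
                 correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on joint ranks after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term sum(t^3 - t). Two-sided p-values are corrected
    over all k(k-1)/2 pairs. Returns a frame with columns
    ``group_a, group_b, z, p_raw, p_adj``.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("Dunn's test needs at least two groups")
    names = list(by_group)
    all_vals = np.concatenate([by_group[g] for g in names])
    n = len(all_vals)
    ranks = rankdata(all_vals)
    mean_rank = {}
    start = 0
    for g in names:
        k = len(by_group[g])
        mean_rank[g] = ranks[start:start + k].mean()
        start += k
    var_base = n * (n + 1) / 12.0 - _tie_term(all_vals) / (12.0 * (n - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / len(by_group[a]) + 1.0 / len(by_group[b])))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = float(2.0 * norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = adjust_pvalues(df["p_raw"].tolist(), correction)
    return df


def adjust_pvalues(p: Sequence[float], method: str = "bonferroni") -> List[float]:
    """Multiple-testing adjustment: bonferroni, holm, bh, or none.

    Holm is the step-down procedure (running maximum enforced), BH the
    step-up procedure (running minimum from the largest p); all outputs
    are clipped to [0, 1].
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    method = method.lower().replace("-", "_")
    if method in ("none",):
        return p.tolist()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0).tolist()
    order = np.argsort(p)
    out = np.empty(m)
    if method in ("holm", "holm_bonferroni"):
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            out[idx] = min(running, 1.0)
        return out.tolist()
    if method in ("bh", "benjamini_hochberg", "fdr_bh"):
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, m * p[idx] / (rank + 1))
            out[idx] = running
        return out.tolist()
    raise ValueError(f"unknown correction {method!r}")


def _exact_rank_sum_p(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for the rank-sum statistic by enumeration.

    Counts subsets of size n1 of the ranks 1..N by their rank sum
    (dynamic programming over the full null distribution); the two-sided
    p doubles the smaller tail, capped at 1.
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    # counts[k][s] = number of k-subsets of 1..i with sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for i in range(1, n + 1):
        for k in range(min(i, n1), 0, -1):
            counts[k, i:] += counts[k - 1, :-i] if i > 0 else counts[k - 1]
    dist = counts[n1]
    total = dist.sum()
    w_int = int(round(w))
    lower = dist[: w_int + 1].sum() / total
    upper = dist[w_int:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def rank_sum_and_t(values_a: Sequence[float], values_b: Sequence[float],
                   kind: str = "wilcoxon") -> Tuple[float, float]:
    """Two-sample comparison: Wilcoxon rank-sum or Welch t.

    Rank-sum returns (W, p) where W is the rank sum of sample a. The null
    distribution is exact (full enumeration) when the combined sample has
    at most 20 untied observations, else a normal approximation with tie
    correction. The t test is Welch's (unequal variances) and errors on
    degenerate (zero pooled) variance.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if kind == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t test needs n >= 2 per group")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("degenerate (zero) variance in both samples")
        stat, p = ttest_ind(a, b, equal_var=False)
        return float(stat), float(p)
    if kind not in ("wilcoxon", "rank-sum", "ranksum"):
        raise ValueError(f"unknown test kind {kind!r}")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    w = float(ranks[: a.size].sum())
    n1, n2 = a.size, b.size
    has_ties = len(np.unique(combined)) < len(combined)
    if n1 + n2 <= 20 and not has_ties:
        return w, _exact_rank_sum_p(w, n1, n2)
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - _tie_term(combined) / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return w, float(2.0 * norm.sf(abs(z)))


def chi_squared(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson's chi-squared test of independence on an r x c count table.

    Expected counts are row total x column total / grand total;
    X^2 = sum (observed - expected)^2 / expected with (r-1)(c-1) df.
    Any zero row or column marginal is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal row or column")
    expected = np.outer(row, col) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return x2, float(chi2_dist.sf(x2, df))


def significance_code(p: float) -> str:
    """Star convention used in the figures: * <0.05 ... **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class GroupComparison:
    """A full multi-group comparison: omnibus test plus post hoc battery."""

    test: str
    groups: List[object]
    n: Dict[object, int]
    statistic: float
    p_value: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    correction: str = "none"

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "groups": [str(g) for g in self.groups],
            "n": {str(k): v for k, v in self.n.items()},
            "statistic": self.statistic,
            "p_raw": self.p_value,
            "significance": significance_code(self.p_value),
            "correction": self.correction,
        }
        if len(self.posthoc):
            ph = self.posthoc.copy()
            ph["significance"] = ph["p_adj"].map(significance_code)
            d["posthoc"] = ph.to_dict(orient="records")
        return d


def compare_groups(values: Sequence[float], groups: Sequence,
                   posthoc: str = "dunn",
                   correction: str = "bonferroni") -> GroupComparison:
    """Kruskal-Wallis omnibus plus a chosen post hoc battery.

    ``posthoc`` is ``"dunn"``, ``"pairwise-wilcoxon"`` or ``"none"``;
    pairwise Wilcoxon runs the rank-sum test on every group pair and
    corrects the p-values with the requested method.
    """
    by_group = _group_arrays(values, groups)
    h, p = kruskal_wallis(values, groups)
    if posthoc == "dunn":
        ph = dunn_posthoc(values, groups, correction)
    elif posthoc in ("pairwise-wilcoxon", "wilcoxon"):
        rows = []
        for a, b in itertools.combinations(by_group, 2):
            w, pr = rank_sum_and_t(by_group[a], by_group[b], kind="wilcoxon")
            rows.append({"group_a": a, "group_b": b, "z": w, "p_raw": pr})
        ph = pd.DataFrame(rows)
        ph["p_adj"] = adjust_pvalues(ph["p_raw"].tolist(), correction)
    elif posthoc == "none":
        ph = pd.DataFrame()
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return GroupComparison(test="kruskal-wallis", groups=list(by_group),
                           n={g: len(v) for g, v in by_group.items()},
                           statistic=h, p_value=p, posthoc=ph,
                           correction=correction)
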