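"""Rank-based statistics with SPSS-style output conventions.

Mann-Whitney U, Kruskal-Wallis H, Wilcoxon signed-rank and Spearman's
rank-order correlation, reported the way clinical papers print them:
asymptotic Z (normal approximation, midranks, standard tie-correction
terms, no continuity correction), chi-square H with df, per-group mean
ranks, and two-sided p-values.  Exact-distribution p-values for large n
are out of scope; tests verify the asymptotics against full-enumeration
permutation oracles at small n.

All procedures depend on the data only through ranks, so any strictly
monotone transform of the inputs leaves them unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm, rankdata, t as t_dist

from .exceptions import ParameterError

__all__ = [
    "StatResult",
    "mann_whitney",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "spearman",
    "summarize",
]


@dataclass
class StatResult:
    """One test's output: statistic, Z / df, p, per-group mean ranks."""

    test_name: str
    statistic: float
    p_value: float
    z_value: float | None = None
    df: int | None = None
    mean_ranks: dict[str, float] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags

    def to_row(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "z": self.z_value,
            "df": self.df,
            "p": self.p_value,
            "n": ";".join(f"{k}={v}" for k, v in self.n_per_group.items()),
            "mean_ranks": ";".join(f"{k}={v:.4g}" for k, v in self.mean_ranks.items()),
            "flags": ";".join(self.flags),
        }

    def summary(self) -> str:
        parts = [f"{self.test_name}:"]
        parts.append(f"statistic={self.statistic:.6g}")
        if self.z_value is not None:
            parts.append(f"Z={self.z_value:.4g}")
        if self.df is not None:
            parts.append(f"df={self.df}")
        parts.append(f"p={self.p_value:.4g}")
        if self.mean_ranks:
            mr = ", ".join(f"{k}: {v:.4g}" for k, v in self.mean_ranks.items())
            parts.append(f"mean ranks [{mr}]")
        if self.flags:
            parts.append(f"flags={','.join(self.flags)}")
        return " ".join(parts)


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(group_a, group_b) -> StatResult:
    """Mann-Whitney U with midranks, tie-corrected Z and two-sided p.

    The reported U is the smaller of the two group Us; Z is signed from
    group A's U, so A stochastically smaller than B gives negative Z.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    big_n = n1 + n2
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    res = StatResult(
        test_name="mann_whitney",
        statistic=u,
        p_value=1.0,
        mean_ranks={"a": r1 / n1, "b": float(ranks[n1:].sum()) / n2},
        n_per_group={"a": n1, "b": n2},
    )
    if var <= 0:
        res.z_value = None
        res.flags.append("degenerate")
        return res
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var)
    res.z_value = z
    res.p_value = float(2 * norm.sf(abs(z)))
    return res


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    gs = [np.asarray(g, dtype=np.float64) for g in groups if len(g)]
    if len(gs) < 2:
        raise ParameterError("need at least 2 nonempty groups")
    sizes = [g.size for g in gs]
    pooled = np.concatenate(gs)
    big_n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    mean_ranks = {}
    start = 0
    for i, n_i in enumerate(sizes):
        r_i = float(ranks[start : start + n_i].sum())
        mean_ranks[f"group{i + 1}"] = r_i / n_i
        h += r_i**2 / n_i
        start += n_i
    h = 12.0 / (big_n * (big_n + 1)) * h - 3 * (big_n + 1)
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (big_n**3 - big_n)
    res = StatResult(
        test_name="kruskal_wallis",
        statistic=0.0,
        p_value=1.0,
        df=len(gs) - 1,
        mean_ranks=mean_ranks,
        n_per_group={f"group{i + 1}": n for i, n in enumerate(sizes)},
    )
    if correction <= 0:  # all values identical
        res.flags.append("degenerate")
        return res
    h /= correction
    res.statistic = h
    res.p_value = float(chi2.sf(h, res.df))
    return res


def wilcoxon_signed_rank(before, after) -> StatResult:
    """Paired Wilcoxon signed-rank with midranks and tie-corrected Z.

    Differences are ``after - before`` (zero differences dropped), so a
    uniform decrease gives negative Z.  The statistic is the positive-rank
    sum W+.
    """
    x = np.asarray(before, dtype=np.float64)
    y = np.asarray(after, dtype=np.float64)
    if x.size != y.size or x.size == 0:
        raise ParameterError("before/after must be equal-length, nonempty")
    d = y - x
    d = d[d != 0]
    n = d.size
    res = StatResult(
        test_name="wilcoxon_signed_rank",
        statistic=0.0,
        p_value=1.0,
        n_per_group={"pairs": x.size, "nonzero": n},
    )
    if n == 0:
        res.flags.append("degenerate")
        return res
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    res.statistic = w_pos
    npos, nneg = int(np.sum(d > 0)), int(np.sum(d < 0))
    res.mean_ranks = {
        "negative": w_neg / nneg if nneg else float("nan"),
        "positive": w_pos / npos if npos else float("nan"),
    }
    mu = n * (n + 1) / 4.0
    tie = _tie_term(np.abs(d))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    if var <= 0:
        res.flags.append("degenerate")
        return res
    z = (w_pos - mu) / math.sqrt(var)
    res.z_value = z
    res.p_value = float(2 * norm.sf(abs(z)))
    return res


def spearman(x, y) -> StatResult:
    """Spearman's rank-order correlation: product-moment of midranks.

    Two-sided p from the t approximation with n-2 df.
    """
    xv = np.asarray(x, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if xv.size != yv.size or xv.size < 3:
        raise ParameterError("need equal-length inputs with n >= 3")
    rx, ry = rankdata(xv), rankdata(yv)
    res = StatResult(
        test_name="spearman",
        statistic=0.0,
        p_value=1.0,
        n_per_group={"n": xv.size},
    )
    if np.std(rx) == 0 or np.std(ry) == 0:
        res.flags.append("degenerate")
        return res
    rs = float(np.corrcoef(rx, ry)[0, 1])
    res.statistic = rs
    n = xv.size
    if abs(rs) >= 1.0:
        res.p_value = 0.0
    else:
        t_stat = rs * math.sqrt((n - 2) / (1 - rs * rs))
        res.p_value = float(2 * t_dist.sf(abs(t_stat), n - 2))
    return res


def summarize(values) -> dict:
    """Median with range and IQR (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ParameterError("cannot summarize an empty list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "median": float(med),
        "min": float(v.min()),
        "max": float(v.max()),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }
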