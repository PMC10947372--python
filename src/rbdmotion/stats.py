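"""Statistical layer: group comparisons, paired model comparisons, FDR.

Small-sample tests are exact.  The Mann–Whitney U test enumerates the full
permutation distribution (tie-safe) whenever that is tractable and falls
back to the classical no-ties exact distribution or the tie-corrected
normal approximation otherwise; the Wilcoxon signed-rank test computes the
exact sign-flip distribution of the rank sum (midranks handled by
convolution over doubled ranks) up to n = 25.  Multiple comparisons are
controlled with the Benjamini–Hochberg step-up procedure at q = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "spearman_corr",
    "demographic_table",
    "compare_classifiers",
]

_ENUM_CAP = 200_000  # max permutations for full tie-safe enumeration


@dataclass
class ComparisonResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    reject: bool | None = None
    note: str = ""


def mann_whitney_u(sample_a, sample_b) -> ComparisonResult:
    """Two-sided Mann–Whitney U test of two independent samples.

    The reported statistic is U of ``sample_a``.  Exact by full permutation
    enumeration when C(n_a+n_b, n_a) is small (handles ties exactly); exact
    by the classical recursion when there are no ties and n_a*n_b <= 400;
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    if math.comb(na + nb, na) <= _ENUM_CAP:
        obs_dev = abs(u_a - mu)
        count = 0
        total = 0
        for idx in combinations(range(na + nb), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
            total += 1
        return ComparisonResult("mann-whitney-exact", float(u_a), count / total)
    if not has_ties and na * nb <= 400:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return ComparisonResult("mann-whitney-exact", float(res.statistic), float(res.pvalue))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonResult("mann-whitney-normal", float(res.statistic), float(res.pvalue))


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact sign-flip p for doubled (integer) ranks."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    dev = abs(w2 - total / 2.0)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - total / 2.0) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(paired_a, paired_b) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Zero differences are dropped.  Exact sign-flip distribution (ties via
    midranks) when n <= 25 after dropping; tie-corrected normal
    approximation otherwise.  All-zero differences yield a degenerate
    result (p = 1) flagged in ``note``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return ComparisonResult(
            "wilcoxon-degenerate", float("nan"), 1.0, note="all differences zero"
        )
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= 25:
        p = _wilcoxon_exact_p(np.rint(2 * ranks).astype(int), 2 * w_plus)
        return ComparisonResult("wilcoxon-exact", float(w_plus), p)
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return ComparisonResult("wilcoxon-normal", float(w_plus), float(res.pvalue))


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(reject, adjusted_p)`` where ``adjusted_p[i]`` is
    ``min over j with p(j) >= p(i) of m * p(j) / rank(j)``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj


def spearman_corr(x, y) -> ComparisonResult:
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return ComparisonResult("spearman", float(rho), float(p))


def demographic_table(
    records: pd.DataFrame, group_col: str = "group", alpha: float = 0.05
) -> pd.DataFrame:
    """Two-group demographic comparison table.

    Numeric variables are summarised as mean +/- SD and compared by t test
    when both groups pass Shapiro–Wilk normality (at ``alpha``), otherwise
    as median [IQR] with a Mann–Whitney U test.  Categorical variables are
    compared with (continuity-corrected) chi-squared tests.  ``significant``
    flags p < 0.05.
    """
    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValueError("demographic_table expects exactly two groups")
    ga = records[records[group_col] == groups[0]]
    gb = records[records[group_col] == groups[1]]
    rows = []
    for col in records.columns:
        if col == group_col:
            continue
        series = records[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 5:
            a = ga[col].dropna().to_numpy(dtype=float)
            b = gb[col].dropna().to_numpy(dtype=float)
            normal = (
                len(a) >= 3
                and len(b) >= 3
                and sps.shapiro(a).pvalue > alpha
                and sps.shapiro(b).pvalue > alpha
            )
            if normal:
                stat, p = sps.ttest_ind(a, b)
                summ_a = f"{a.mean():.1f} ± {a.std(ddof=1):.1f}"
                summ_b = f"{b.mean():.1f} ± {b.std(ddof=1):.1f}"
                test = "t-test"
            else:
                res = mann_whitney_u(a, b)
                stat, p = res.statistic, res.p_value
                summ_a = f"{np.median(a):.1f} [{np.percentile(a, 25):.1f}-{np.percentile(a, 75):.1f}]"
                summ_b = f"{np.median(b):.1f} [{np.percentile(b, 25):.1f}-{np.percentile(b, 75):.1f}]"
                test = "mann-whitney"
        else:
            table = pd.crosstab(records[group_col], series)
            note = ""
            if (table.to_numpy() == 0).any():
                note = "empty cell: continuity-corrected"
            stat, p, _, _ = sps.chi2_contingency(table, correction=True)
            test = "chi-squared" + (" (corrected)" if note else "")
            summ_a = "/".join(str(v) for v in table.loc[groups[0]])
            summ_b = "/".join(str(v) for v in table.loc[groups[1]])
        rows.append(
            {
                "variable": col,
                str(groups[0]): summ_a,
                str(groups[1]): summ_b,
                "test": test,
                "statistic": float(stat),
                "p": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def compare_classifiers(
    results: dict[str, "CVResult"],
    metrics: tuple[str, ...] = ("accuracy", "f1"),
    q: float = 0.05,
    level: str = "fold",
) -> pd.DataFrame:
    """Pairwise Wilcoxon comparison of classifier configurations.

    All results must share the same CV plan so their per-fold (default) or
    per-run metric values pair up.  P values are Benjamini–Hochberg
    corrected within each metric family.
    """
    from .classify import CVResult  # noqa: F401 - circular import guard

    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least two classifier results to compare")
    plans = {
        (r.plan.n_runs, r.plan.n_folds, tuple(r.plan.run_seeds)) for r in results.values()
    }
    if len(plans) > 1:
        raise ValueError("CV plans differ: paired comparison is invalid")
    rows = []
    for metric in metrics:
        pairs = []
        pvals = []
        for i, j in combinations(range(len(names)), 2):
            ra, rb = results[names[i]], results[names[j]]
            key = ["run", "fold"] if level == "fold" else ["run"]
            table = "per_fold" if level == "fold" else "per_run"
            va = getattr(ra, table).sort_values(key)[metric].to_numpy(dtype=float)
            vb = getattr(rb, table).sort_values(key)[metric].to_numpy(dtype=float)
            ok = ~(np.isnan(va) | np.isnan(vb))
            res = wilcoxon_signed_rank(va[ok], vb[ok])
            pairs.append((f"{names[i]} vs {names[j]}", res))
            pvals.append(res.p_value)
        reject, adj = benjamini_hochberg(pvals, q=q)
        for (pair, res), rej, ap in zip(pairs, reject, adj):
            rows.append(
                {
                    "pair": pair,
                    "metric": metric,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "adj_p": ap,
                    "reject": bool(rej) and "degenerate" not in res.test,
                    "note": res.note,
                }
            )
    return pd.DataFrame(rows)
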