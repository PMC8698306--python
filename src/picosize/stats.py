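"""Alpha diversity, group comparisons and environmental correlations.

All statistics are computed from their defining formulas; SciPy supplies
only the reference distributions (F, chi-square, Student t) for p-values.

Diversity indices per sample
    richness  S_obs, the number of OTUs with a positive count
    Chao1     S_obs + F1²/(2·F2)  with singleton count F1 and doubleton
              count F2; when F2 = 0 the bias-corrected F1(F1−1)/2 term
              is used, so Chao1 ≥ S_obs always
    Shannon   H' = −Σ p_i ln p_i  (natural log, nats)
    Simpson   1 − Σ p_i²  (Gini–Simpson, probability two random reads
              differ)

Group comparisons are one-way ANOVA (F against the F distribution) or
Kruskal–Wallis (H with mid-rank ties and tie correction, against
chi-square).  Environmental association uses the Pearson product-moment
correlation with a two-sided t test and the conventional star encoding
(*, **, *** at p < 0.05, 0.01, 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _dists


@dataclass(frozen=True)
class DiversityResult:
    richness: int
    chao1: float
    shannon: float
    simpson: float


def alpha_diversity(sample_counts) -> DiversityResult:
    """Diversity indices for one sample's OTU count vector."""
    counts = np.asarray(sample_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    counts = counts[counts > 0]
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sample: diversity undefined")

    s_obs = int(len(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0

    p = counts / total
    shannon = float(-np.sum(p * np.log(p)))
    simpson = float(1.0 - np.sum(p * p))
    return DiversityResult(s_obs, float(chao1), shannon, simpson)


def alpha_diversity_table(otu_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diversity indices for an OTU × sample count table.

    Empty samples are flagged with NaN indices rather than dropped.
    """
    rows = []
    for key in otu_table.columns:
        col = otu_table[key]
        if col.sum() == 0:
            rows.append(
                dict(richness=np.nan, chao1=np.nan, shannon=np.nan, simpson=np.nan)
            )
        else:
            r = alpha_diversity(col.to_numpy())
            rows.append(r.__dict__)
    return pd.DataFrame(rows, index=otu_table.columns)


def compare_groups(values, grouping, method: str = "anova") -> tuple[float, float]:
    """One-way comparison of an index across groups (e.g. size fractions).

    Returns ``(statistic, p_value)``: the ANOVA F with an F-distribution
    p, or the Kruskal–Wallis H (mid-ranks, tie-corrected) with a
    chi-square p on k−1 degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    if values.shape != grouping.shape:
        raise ValueError("values and grouping must align")
    labels = pd.unique(grouping)
    groups = [values[grouping == g] for g in labels]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n = len(values)

    if method == "anova":
        if any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA needs ≥2 observations per group")
        grand = values.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = k - 1, n - k
        if ss_within == 0:
            return (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
        f = (ss_between / df_b) / (ss_within / df_w)
        return float(f), float(_dists.f.sf(f, df_b, df_w))

    if method == "kruskal":
        ranks = _dists.rankdata(values)  # mid-ranks on ties
        h = 12.0 / (n * (n + 1)) * sum(
            len(g) * ranks[grouping == lab].mean() ** 2
            for lab, g in zip(labels, groups)
        ) - 3 * (n + 1)
        _, tie_counts = np.unique(values, return_counts=True)
        correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
        if correction == 0:
            raise ValueError("all observations tied: H undefined")
        h /= correction
        return float(h), float(_dists.chi2.sf(h, k - 1))

    raise ValueError(f"unknown method: {method!r}")


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided t-test p-value; returns (r, p, n).

    r = Σ(x−x̄)(y−ȳ) / √(Σ(x−x̄)² Σ(y−ȳ)²); the test statistic is
    t = r√(n−2)/√(1−r²) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = (dx**2).sum(), (dy**2).sum()
    if sxx == 0 or syy == 0:
        return np.nan, np.nan, n
    r = float((dx * dy).sum() / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * _dists.t.sf(abs(t), n - 2))
    return r, p, n


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_env_correlation(
    abundances: pd.DataFrame,
    env: pd.DataFrame,
    bh_correct: bool = False,
) -> dict[str, pd.DataFrame]:
    """Correlate per-depth group abundances with environmental factors.

    ``abundances``: groups × depths; ``env``: depths × factors.  Returns
    ``{"r": ..., "p": ..., "n": ..., "stars": ...}`` DataFrames over
    (group, factor).  Pairs with zero variance are NaN-flagged.  With
    ``bh_correct`` the stars are drawn from Benjamini–Hochberg adjusted
    p-values (off by default).
    """
    depths = [d for d in abundances.columns if d in env.index]
    if len(depths) < 3:
        raise ValueError("need at least 3 shared depths")
    r = pd.DataFrame(index=abundances.index, columns=env.columns, dtype=float)
    p = r.copy()
    n = r.copy()
    for g in abundances.index:
        for f in env.columns:
            r.loc[g, f], p.loc[g, f], n.loc[g, f] = pearson_r(
                abundances.loc[g, depths], env.loc[depths, f]
            )
    p_for_stars = p
    if bh_correct:
        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = _benjamini_hochberg(flat[ok])
        p_for_stars = pd.DataFrame(
            adj.reshape(p.shape), index=p.index, columns=p.columns
        )
    stars = p_for_stars.map(significance_stars)
    return {"r": r, "p": p, "n": n, "stars": stars}


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
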