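"""Skewness-ratio screening of differential expression between two datasets.

For gene i observed in datasets D1 and D2, the skewness of each expression
vector is the population-standardized third moment

    Skew(X) = (1/n) * sum_j ((x_j - mu) / sigma)^3,

with mu and sigma the 1/n mean and standard deviation (no bias
correction).  The skewness ratio

    SR = (Skew(X1) - Skew(X2)) / (|Skew(X1)| + |Skew(X2)|)

is bounded in [-1, 1]; SR > 0 means stronger skewness in D1.  Genes with
|SR| above a threshold (default 0.5) whose Wilcoxon rank-sum p-value is
below a threshold (default 0.05) are called differentially expressed.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import ExpressionMatrix

__all__ = [
    "DegenerateSkewnessError",
    "skewness",
    "skewness_ratio",
    "wilcoxon_rank_sum",
    "call_degs",
]

#: Largest combined sample size for which the Wilcoxon p-value is computed
#: by exhaustive enumeration of rank assignments.
EXACT_WILCOXON_MAX_N = 20


class DegenerateSkewnessError(ValueError):
    """Skewness is undefined (constant vector or too few values)."""


def skewness(values) -> float:
    """Population (1/n) skewness: mean of cubed standardized residuals."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise DegenerateSkewnessError("need at least 3 values")
    mu = float(np.mean(v))
    sigma = float(np.std(v))
    if sigma == 0:
        raise DegenerateSkewnessError("zero standard deviation")
    return float(np.mean(((v - mu) / sigma) ** 3))


def skewness_ratio(x1, x2) -> float:
    """Normalized skewness difference between two samples, in [-1, 1].

    Defined as 0 when both skewnesses are exactly zero (no skew
    difference exists).
    """
    s1 = skewness(x1)
    s2 = skewness(x2)
    denom = abs(s1) + abs(s2)
    if denom == 0:
        return 0.0
    return (s1 - s2) / denom


def _exact_rank_sum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided permutation p for the rank sum, by full enumeration."""
    total_indices = range(len(ranks))
    w_obs = float(np.sum(ranks[:n1]))
    mu = n1 * float(np.sum(ranks)) / len(ranks)
    t_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in combinations(total_indices, n1):
        w = float(ranks[list(idx)].sum())
        if abs(w - mu) >= t_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_rank_sum(x1, x2) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midrank tie handling.

    Exhaustive permutation enumeration when the combined size is <= 20;
    otherwise the tie-corrected normal approximation (with continuity
    correction).
    """
    a = np.asarray(x1, dtype=float).ravel()
    b = np.asarray(x2, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    n = a.size + b.size
    if n <= EXACT_WILCOXON_MAX_N:
        ranks = stats.rankdata(np.concatenate([a, b]))
        return _exact_rank_sum_p(ranks, a.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def call_degs(
    m1: ExpressionMatrix,
    m2: ExpressionMatrix,
    sr_threshold: float = 0.5,
    p_threshold: float = 0.05,
    adjust_p: bool = False,
) -> pd.DataFrame:
    """Skewness-ratio DEG table over the genes shared by two matrices.

    One row per shared gene, sorted by descending |SR| then ascending
    p-value.  A gene is flagged DEG iff |SR| > sr_threshold AND
    p < p_threshold (both strict).  ``adjust_p`` applies a
    Benjamini-Hochberg correction to the Wilcoxon p-values before
    thresholding (off by default; the plain rule uses raw p-values).
    Genes with degenerate skewness in either dataset are retained with
    NaN SR, flagged not-DEG, and a status note.
    """
    if not 0 < sr_threshold:
        raise ValueError("sr_threshold must be > 0")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    g1, g2 = set(m1.gene_ids), set(m2.gene_ids)
    shared = [g for g in m1.gene_ids if g in g2]
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    if g1 != g2:
        warnings.warn(
            f"gene universes differ; intersecting to {len(shared)} shared genes"
        )
    rows = []
    for gene in shared:
        v1 = m1.gene(gene)
        v2 = m2.gene(gene)
        row = {
            "gene_id": gene,
            "n_d1": v1.size,
            "n_d2": v2.size,
            "mean_d1": float(np.mean(v1)),
            "mean_d2": float(np.mean(v2)),
            "sd_d1": float(np.std(v1)),
            "sd_d2": float(np.std(v2)),
        }
        try:
            s1, s2 = skewness(v1), skewness(v2)
            sr = skewness_ratio(v1, v2)
            p = wilcoxon_rank_sum(v1, v2)
            row.update(
                skew_d1=s1,
                skew_d2=s2,
                sr=sr,
                wilcoxon_p=p,
                is_deg=(abs(sr) > sr_threshold and p < p_threshold),
                status="ok",
            )
        except DegenerateSkewnessError as e:
            row.update(
                skew_d1=np.nan,
                skew_d2=np.nan,
                sr=np.nan,
                wilcoxon_p=np.nan,
                is_deg=False,
                status=f"degenerate: {e}",
            )
        rows.append(row)
    if adjust_p:
        ok = [r["status"] == "ok" for r in rows]
        raw = np.array([r["wilcoxon_p"] for r, o in zip(rows, ok) if o])
        if raw.size:
            adj = stats.false_discovery_control(raw, method="bh")
            it = iter(adj)
            for r, o in zip(rows, ok):
                if o:
                    p = float(next(it))
                    r["wilcoxon_p"] = p
                    r["is_deg"] = abs(r["sr"]) > sr_threshold and p < p_threshold
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "skew_d1",
            "skew_d2",
            "sr",
            "wilcoxon_p",
            "is_deg",
            "n_d1",
            "n_d2",
            "mean_d1",
            "mean_d2",
            "sd_d1",
            "sd_d2",
            "status",
        ],
    )
    df["_abs_sr"] = df["sr"].abs()
    df = df.sort_values(
        by=["_abs_sr", "wilcoxon_p", "gene_id"],
        ascending=[False, True, True],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_abs_sr")
    return df.reset_index(drop=True)
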