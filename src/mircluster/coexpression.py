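"""Pairwise Pearson co-expression, extreme-tail thresholding, and per-cluster
co-expression enrichment.

All miRNA pairs get a Pearson correlation and a two-sided p-value from the
t transform ``t = r * sqrt((n-2)/(1-r^2))``.  Because the correlation
distribution is roughly symmetric around zero, significance is defined on
its empirical extremes: a pair is flagged iff its r lies beyond the 2.5%
upper or lower quantile of all off-diagonal correlations AND its p is below
alpha.  Each genomic cluster is then tested for an excess of flagged pairs
among its within-cluster pairs versus all remaining pairs (one-sided Fisher),
both positively and negatively correlated pairs counting as significant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MirnaCluster

__all__ = [
    "CorrelationAnalysis",
    "ClusterCoexpressionResult",
    "pairwise_pearson",
    "tail_thresholds",
    "significant_pairs",
    "cluster_coexpression_enrichment",
    "cross_cluster_correlation",
]


@dataclass
class CorrelationAnalysis:
    """All-pairs Pearson correlations with tail thresholds and significance mask."""

    corr: pd.DataFrame
    pvals: pd.DataFrame
    n_samples: int
    lower_threshold: float | None = None
    upper_threshold: float | None = None
    significant_mask: pd.DataFrame | None = None


@dataclass
class ClusterCoexpressionResult:
    cluster_id: int
    within_pairs_total: int
    within_pairs_significant: int
    background_pairs_total: int
    background_pairs_significant: int
    fisher_p: float
    co_expressed: bool
    note: str = ""


def pairwise_pearson(expr: pd.DataFrame) -> CorrelationAnalysis:
    """Pearson r and two-sided p for every pair of rows (miRNAs).

    Rows with zero variance are dropped with a warning; fewer than 3 samples
    is an error.  The diagonal is r = 1 with p undefined (NaN).
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"correlation needs at least 3 samples, got {n}")
    var = expr.var(axis=1, ddof=1)
    flat = var[var == 0].index
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance miRNA(s) before correlation")
        expr = expr.drop(index=flat)
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 variable miRNAs for correlation")
    R = np.corrcoef(expr.to_numpy(dtype=float))
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)  # exact symmetry
    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, np.nan)
    idx = expr.index
    return CorrelationAnalysis(
        corr=pd.DataFrame(R, index=idx, columns=idx),
        pvals=pd.DataFrame(P, index=idx, columns=idx),
        n_samples=n,
    )


def _offdiag_values(corr: pd.DataFrame) -> np.ndarray:
    A = corr.to_numpy(dtype=float)
    iu = np.triu_indices_from(A, k=1)
    return A[iu]


def tail_thresholds(
    corr: pd.DataFrame, tail_fraction: float = 0.025
) -> tuple[float, float]:
    """Empirical (tail, 1-tail) quantiles of the off-diagonal upper-triangle
    correlations, with numpy's linear order-statistic interpolation."""
    if not 0 < tail_fraction < 0.5:
        raise ValueError(f"tail_fraction must be in (0, 0.5), got {tail_fraction}")
    vals = _offdiag_values(corr)
    if vals.size < 2:
        raise ValueError("need at least 2 off-diagonal pairs for tail thresholds")
    lo, hi = np.quantile(vals, [tail_fraction, 1.0 - tail_fraction])
    return float(lo), float(hi)


def significant_pairs(
    analysis: CorrelationAnalysis, alpha: float = 0.05
) -> pd.DataFrame:
    """Boolean mask: |r| beyond its tail threshold AND p < alpha.

    Computes and stores tail thresholds on the analysis if absent; the mask
    (symmetric, False diagonal) is also stored on the analysis.
    """
    if analysis.lower_threshold is None or analysis.upper_threshold is None:
        analysis.lower_threshold, analysis.upper_threshold = tail_thresholds(
            analysis.corr
        )
    R = analysis.corr.to_numpy()
    P = analysis.pvals.to_numpy()
    with np.errstate(invalid="ignore"):
        mask = (
            ((R > analysis.upper_threshold) | (R < analysis.lower_threshold))
            & (P < alpha)
        )
    np.fill_diagonal(mask, False)
    out = pd.DataFrame(mask, index=analysis.corr.index, columns=analysis.corr.columns)
    analysis.significant_mask = out
    return out


def _pair_strata(index: pd.Index, members: set[str]) -> np.ndarray:
    flags = np.array([name in members for name in index])
    return np.outer(flags, flags)


def cluster_coexpression_enrichment(
    mask: pd.DataFrame,
    clusters: list[MirnaCluster],
    alpha: float = 0.05,
) -> list[ClusterCoexpressionResult]:
    """Per-cluster 2x2 Fisher test: within-cluster pairs versus all other
    pairs, significant versus not (one-sided, greater).  Clusters with fewer
    than 2 members retained in the mask are skipped with a note."""
    M = mask.to_numpy(dtype=bool)
    iu = np.triu_indices_from(M, k=1)
    sig = M[iu]
    total_pairs = sig.size
    total_sig = int(sig.sum())
    results = []
    for c in clusters:
        members = set(c.members) & set(mask.index)
        if len(members) < 2:
            results.append(
                ClusterCoexpressionResult(
                    cluster_id=c.cluster_id,
                    within_pairs_total=0, within_pairs_significant=0,
                    background_pairs_total=total_pairs,
                    background_pairs_significant=total_sig,
                    fisher_p=1.0, co_expressed=False,
                    note=f"skipped: only {len(members)} member(s) retained",
                )
            )
            continue
        within = _pair_strata(mask.index, members)[iu]
        ws, wt = int(sig[within].sum()), int(within.sum())
        bs, bt = total_sig - ws, total_pairs - wt
        _, p = stats.fisher_exact(
            [[ws, wt - ws], [bs, bt - bs]], alternative="greater"
        )
        results.append(
            ClusterCoexpressionResult(
                cluster_id=c.cluster_id,
                within_pairs_total=wt,
                within_pairs_significant=ws,
                background_pairs_total=bt,
                background_pairs_significant=bs,
                fisher_p=float(p),
                co_expressed=bool(p < alpha),
            )
        )
    return results


def cross_cluster_correlation(
    corr: pd.DataFrame,
    cluster_a: MirnaCluster,
    cluster_b: MirnaCluster,
    mask: pd.DataFrame | None = None,
) -> dict:
    """Summary of all between-cluster pairs: mean r, fraction flagged
    significant (when a mask is given), and the dominant correlation sign."""
    a = [m for m in cluster_a.members if m in corr.index]
    b = [m for m in cluster_b.members if m in corr.index]
    if not a or not b:
        raise ValueError("both clusters need at least one retained member")
    pairs = [(x, y) for x, y in itertools.product(a, b) if x != y]
    rs = np.array([corr.loc[x, y] for x, y in pairs])
    out = {
        "n_pairs": len(pairs),
        "mean_r": float(rs.mean()),
        "dominant_sign": "positive" if rs.mean() >= 0 else "negative",
    }
    if mask is not None:
        out["fraction_significant"] = float(
            np.mean([bool(mask.loc[x, y]) for x, y in pairs])
        )
    return out
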