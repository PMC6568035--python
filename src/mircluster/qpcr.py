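"""Relative qPCR quantification by the ddCt method, group comparison, and
cluster-annotated pairwise correlation of qPCR targets.

dCt = mean Ct(target) - mean Ct(reference) per sample (replicates averaged);
ddCt = dCt - mean dCt of the control group; relative expression = 2^(-ddCt),
so the control group has geometric mean 1 for every target.  Group
comparisons are two-sided Welch t-tests on log2 relative expression
(equivalently -ddCt).  References default to 18S for mRNA assays and SNORD68
for miRNA assays but are simply whatever the Ct table records.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import pairwise_pearson

__all__ = [
    "read_ct_table",
    "validate_ct_table",
    "ddct",
    "group_compare",
    "qpcr_pairwise_correlation",
]

CT_COLUMNS = ["sample_id", "group", "target", "reference", "ct_target", "ct_reference"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if table.empty:
        raise ValueError("empty Ct table")
    for col in ("ct_target", "ct_reference"):
        vals = table[col].astype(float)
        if ((vals <= 0) | (vals >= 45)).any():
            bad = table.loc[(vals <= 0) | (vals >= 45)].iloc[0]
            raise ValueError(
                f"Ct value out of range (0, 45) for sample {bad['sample_id']!r}, "
                f"target {bad['target']!r}"
            )
    return table


def read_ct_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return validate_ct_table(pd.read_csv(path, sep=sep))


def ddct(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative expression per (sample, target) by the ddCt method.

    Returns columns sample_id, group, target, dct, ddct, rel_expr.  Raises if
    a target has no measurement in the control group.
    """
    validate_ct_table(table)
    per = (
        table.groupby(["sample_id", "group", "target"], sort=False)
        .agg(ct_target=("ct_target", "mean"), ct_reference=("ct_reference", "mean"))
        .reset_index()
    )
    per["dct"] = per["ct_target"] - per["ct_reference"]
    out = []
    for target, sub in per.groupby("target", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "dct"]
        if ctrl.empty:
            raise ValueError(
                f"target {target!r} has no samples in control group {control_group!r}"
            )
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - ctrl.mean()
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["rel_expr"] = 2.0 ** (-res["ddct"])
    return res[["sample_id", "group", "target", "dct", "ddct", "rel_expr"]]


def group_compare(
    rel: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Welch t-test on log2 relative expression, per target.

    ``groups`` selects and orders the two group labels (defaults to the two
    labels present); the reported difference is group2 minus group1 in log2
    folds.  A group with fewer than 2 samples is an error.
    """
    if groups is None:
        labels = list(pd.unique(rel["group"]))
        if len(labels) != 2:
            raise ValueError(
                f"need exactly 2 groups, found {labels}; pass `groups` explicitly"
            )
        groups = (labels[0], labels[1])
    g1, g2 = groups
    rows = []
    for target, sub in rel.groupby("target", sort=False):
        x1 = np.log2(sub.loc[sub["group"] == g1, "rel_expr"].to_numpy(dtype=float))
        x2 = np.log2(sub.loc[sub["group"] == g2, "rel_expr"].to_numpy(dtype=float))
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError(
                f"target {target!r}: each group needs >= 2 samples "
                f"({g1}: {len(x1)}, {g2}: {len(x2)})"
            )
        if np.allclose(x1, x1[0]) and np.allclose(x2, x2[0]) and np.isclose(x1[0], x2[0]):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(x2, x1, equal_var=False)
        rows.append(
            {
                "target": target,
                f"mean_log2_{g1}": float(x1.mean()),
                f"mean_log2_{g2}": float(x2.mean()),
                "log2_fold_diff": float(x2.mean() - x1.mean()),
                "t_stat": float(t_stat),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def qpcr_pairwise_correlation(
    rel: pd.DataFrame,
    clusters: dict[str, int] | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2 relative expression across samples.

    Samples missing either target of a pair are dropped pairwise.  Returns an
    edge list (target_a, target_b, n, r, p, same_cluster); ``clusters`` maps
    target names to cluster IDs, and ``group`` restricts the computation to
    one sample group (matching the healthy/AH overlay analyses).
    """
    sub = rel if group is None else rel[rel["group"] == group]
    wide = sub.pivot_table(index="target", columns="sample_id", values="rel_expr")
    log2w = np.log2(wide)
    targets = list(log2w.index)
    rows = []
    for i, ta in enumerate(targets):
        for tb in targets[i + 1 :]:
            pair = log2w.loc[[ta, tb]].dropna(axis=1)
            n = pair.shape[1]
            if n < 3:
                warnings.warn(f"pair ({ta}, {tb}): only {n} complete samples; skipped")
                continue
            if pair.loc[ta].var() == 0 or pair.loc[tb].var() == 0:
                warnings.warn(f"pair ({ta}, {tb}): zero variance; skipped")
                continue
            analysis = pairwise_pearson(pair)
            r = float(analysis.corr.loc[ta, tb])
            p = float(analysis.pvals.loc[ta, tb])
            same = (
                clusters is not None
                and clusters.get(ta) is not None
                and clusters.get(ta) == clusters.get(tb)
            )
            rows.append(
                {
                    "target_a": ta, "target_b": tb, "n": n,
                    "r": r, "p_value": p, "same_cluster": bool(same),
                }
            )
    return pd.DataFrame(
        rows, columns=["target_a", "target_b", "n", "r", "p_value", "same_cluster"]
    )
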