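"""Count matrices: loading, read counting, filtering, TPM normalization, PCA.

Counts are plain :class:`pandas.DataFrame` objects with miRNA names as the
row index and sample IDs as columns; sample metadata is a DataFrame indexed
by sample ID with ``diet`` (pair/ethanol) and ``treatment`` (baseline/LPS)
columns.  All coordinates are 1-based inclusive; BED alignments are shifted
at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

__all__ = [
    "validate_counts",
    "validate_metadata",
    "read_counts",
    "read_metadata",
    "read_alignments_bed",
    "count_from_alignments",
    "tpm_transform",
    "filter_expressed",
    "filter_for_correlation",
    "pca_summary",
    "PcaSummary",
]

DIETS = {"pair", "ethanol"}
TREATMENTS = {"baseline", "LPS"}


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a count matrix: unique labels, nonnegative integral entries."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate miRNA name in count matrix: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample name in count matrix: {dup!r}")
    values = counts.to_numpy()
    if values.size and (values < 0).any():
        raise ValueError("count matrix has negative entries")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValueError("count matrix has non-integral entries")
    return counts


def validate_metadata(meta: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    for col in ("diet", "treatment"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata missing column {col!r}")
    bad_diet = set(meta["diet"]) - DIETS
    if bad_diet:
        raise ValueError(f"unknown diet levels {sorted(bad_diet)}; expected {sorted(DIETS)}")
    bad_trt = set(meta["treatment"]) - TREATMENTS
    if bad_trt:
        raise ValueError(f"unknown treatment levels {sorted(bad_trt)}; expected {sorted(TREATMENTS)}")
    if counts is not None and set(meta.index) != set(counts.columns):
        raise ValueError("metadata sample IDs do not match count-matrix columns")
    return meta


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(counts)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return validate_metadata(meta)


def read_alignments_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of alignments, converting to 1-based inclusive coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    df["start"] = df["start"].astype(int) + 1  # BED is 0-based half-open
    df["end"] = df["end"].astype(int)
    return df


def count_from_alignments(
    alignments: pd.DataFrame,
    ann: GenomeAnnotation,
    min_overlap_frac: float = 0.5,
) -> pd.Series:
    """Count reads per miRNA for one sample.

    Each alignment (1-based inclusive ``chrom``/``start``/``end``) is assigned
    to the miRNA whose interval it overlaps by at least ``min_overlap_frac``
    of the read length; ties go to the larger overlap, then the leftmost
    miRNA.  Reads overlapping no miRNA are dropped.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in ann.records:
        # half-open tree interval [start, end+1) over 1-based inclusive coords
        trees.setdefault(r.chrom, IntervalTree())[r.start : r.end + 1] = r
    counts = pd.Series(0, index=pd.Index(ann.names, name="mirna"), dtype=int)
    if alignments.empty:
        return counts
    ann_chroms = set(trees)
    if ann_chroms and not (set(alignments["chrom"]) & ann_chroms):
        warnings.warn(
            "alignments and annotation share no chromosome names; all counts zero"
        )
    for row in alignments.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        read_len = row.end - row.start + 1
        best = None
        for iv in tree.overlap(row.start, row.end + 1):
            rec = iv.data
            ov = min(row.end, rec.end) - max(row.start, rec.start) + 1
            if ov < min_overlap_frac * read_len:
                continue
            key = (-ov, rec.start, rec.name)
            if best is None or key < best[0]:
                best = (key, rec)
        if best is not None:
            counts[best[1].name] += 1
    return counts


def tpm_transform(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for miRNA {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("miRNA lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(f"all-zero sample(s) left at zero in TPM: {list(zero_cols)}")
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expressed(counts: pd.DataFrame, min_fraction: float = 0.25) -> pd.DataFrame:
    """Keep miRNAs with >0 reads in at least ``ceil(min_fraction * n)`` samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    threshold = math.ceil(min_fraction * counts.shape[1])
    keep = (counts > 0).sum(axis=1) >= threshold
    return counts.loc[keep]


def filter_for_correlation(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_present: int = 5,
) -> pd.DataFrame:
    """Restrict to baseline (untreated) samples and keep miRNAs detected in at
    least ``min_present`` of them — the inclusion rule for co-expression
    analysis (default: expression in at least 5 of the 6 baseline samples)."""
    validate_metadata(meta)
    baseline = meta.index[meta["treatment"] == "baseline"]
    baseline = [s for s in counts.columns if s in set(baseline)]
    if len(baseline) < min_present:
        raise ValueError(
            f"only {len(baseline)} baseline samples; need at least {min_present}"
        )
    sub = counts[baseline]
    keep = (sub > 0).sum(axis=1) >= min_present
    return sub.loc[keep]


@dataclass
class PcaSummary:
    """Variance fractions and sample scores from a PCA across samples."""

    variance_fractions: np.ndarray
    scores: pd.DataFrame  # samples x components

    @property
    def n_components(self) -> int:
        return len(self.variance_fractions)


def pca_summary(tpm: pd.DataFrame) -> PcaSummary:
    """PCA of row-centered expression, decomposed across samples.

    Deterministic sign convention: for each component the largest-magnitude
    miRNA loading is made positive.  Variance fractions sum to 1 (or are all
    zero, with a warning, for a constant matrix).
    """
    if tpm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = tpm.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    k = min(tpm.shape[0], tpm.shape[1])
    if total <= 0 or not np.isfinite(total):
        warnings.warn("constant expression matrix: all variance fractions are 0")
        fractions = np.zeros(k)
        scores = np.zeros((tpm.shape[1], k))
    else:
        fractions = s**2 / total
        flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
        flip[flip == 0] = 1.0
        scores = (Vt * flip[:, None]).T * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaSummary(
        variance_fractions=fractions,
        scores=pd.DataFrame(scores, index=tpm.columns, columns=cols),
    )
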