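"""Macrophage M1/M2 polarization set handling and Fisher-exact enrichment.

The polarization set maps miRNA names to an M1 (pro-inflammatory) or M2
(anti-inflammatory) label, curated from polarized mouse bone-marrow-derived
macrophage profiling studies.  Enrichment of the set among differentially
expressed miRNAs is a one-sided (greater) Fisher exact / hypergeometric tail
test against the universe of tested miRNAs.  Name matching strips species
prefixes (rno-/mmu-/hsa-) and is case-insensitive, since labels derived from
mouse data are applied to rat identifiers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MirnaCluster

__all__ = [
    "PolarizationSet",
    "EnrichmentResult",
    "normalize_mirna_name",
    "load_polarization_set",
    "intersect_de",
    "fisher_exact_enrichment",
    "annotate_clusters_with_polarization",
]

_PREFIX_RE = re.compile(r"^(rno|mmu|hsa)-", re.IGNORECASE)

VALID_LABELS = {"M1", "M2"}


def normalize_mirna_name(name: str) -> str:
    """Strip species prefix and lowercase, e.g. ``rno-miR-199a-3p`` -> ``mir-199a-3p``."""
    return _PREFIX_RE.sub("", name.strip()).lower()


@dataclass
class PolarizationSet:
    """miRNA -> M1/M2 label map with source citations."""

    labels: dict[str, str]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - VALID_LABELS
        if bad:
            raise ValueError(f"polarization labels must be M1 or M2, got {sorted(bad)}")

    def label_of(self, name: str) -> str | None:
        return self.labels.get(normalize_mirna_name(name))

    def __len__(self) -> int:
        return len(self.labels)


def load_polarization_set(path: str | Path) -> PolarizationSet:
    """Load a polarization set TSV with columns (mirna, label, sources)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("mirna", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        warnings.warn(f"{path}: empty polarization set")
        return PolarizationSet(labels={})
    labels: dict[str, str] = {}
    sources: dict[str, str] = {}
    for row in df.itertuples(index=False):
        key = normalize_mirna_name(row.mirna)
        label = str(row.label).strip()
        if label not in VALID_LABELS:
            raise ValueError(f"{path}: bad label {label!r} for {row.mirna}")
        if key in labels and labels[key] != label:
            raise ValueError(
                f"{path}: conflicting labels for {row.mirna}: {labels[key]} vs {label}"
            )
        labels[key] = label
        if "sources" in df.columns and isinstance(row.sources, str):
            sources[key] = row.sources
    return PolarizationSet(labels=labels, sources=sources)


@dataclass
class EnrichmentResult:
    overlap_k: int
    set_size_K: int
    de_size_n: int
    universe_N: int
    odds_ratio: float
    p_value: float
    overlap: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        k, K, n, N = self.overlap_k, self.set_size_K, self.de_size_n, self.universe_N
        if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= max(0, K + n - N)):
            raise ValueError(f"impossible 2x2 table: k={k}, K={K}, n={n}, N={N}")


def intersect_de(
    polar: PolarizationSet,
    de: pd.DataFrame | list[str],
    universe: list[str],
) -> dict:
    """Intersect the polarization set with a DE list over a tested universe.

    Returns the hypergeometric inputs ``k`` (overlap), ``K`` (set members in
    the universe), ``n`` (DE miRNAs), ``N`` (universe size) and the per-miRNA
    overlap table with labels (and logFC sign when ``de`` carries a logFC
    column).
    """
    if isinstance(de, pd.DataFrame):
        de_names = list(de.index)
        logfc = de["logFC"] if "logFC" in de.columns else None
    else:
        de_names, logfc = list(de), None
    uni_norm = {normalize_mirna_name(u) for u in universe}
    de_norm = {}
    for name in de_names:
        key = normalize_mirna_name(name)
        if key not in uni_norm:
            raise ValueError(f"DE miRNA {name!r} absent from the universe")
        de_norm[key] = name
    K = len(set(polar.labels) & uni_norm)
    hits = sorted(set(polar.labels) & set(de_norm))
    rows = []
    for key in hits:
        name = de_norm[key]
        rows.append(
            {
                "mirna": name,
                "label": polar.labels[key],
                "direction": (
                    "up" if logfc is not None and logfc.loc[name] > 0
                    else "down" if logfc is not None else ""
                ),
            }
        )
    return {
        "k": len(hits),
        "K": K,
        "n": len(de_norm),
        "N": len(uni_norm),
        "overlap": pd.DataFrame(rows, columns=["mirna", "label", "direction"]),
    }


def fisher_exact_enrichment(k: int, K: int, n: int, N: int) -> EnrichmentResult:
    """One-sided (greater) Fisher exact enrichment test.

    ``p = P[X >= k]`` for ``X ~ Hypergeom(N, K, n)``, evaluated by the
    log-space hypergeometric survival function; the odds ratio comes from the
    2x2 table with a 0.5 continuity correction when any cell is zero.
    """
    result = EnrichmentResult(
        overlap_k=k, set_size_K=K, de_size_n=n, universe_N=N,
        odds_ratio=np.nan, p_value=np.nan,
    )  # validates bounds
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    result.odds_ratio = (a * d) / (b * c)
    result.p_value = min(max(p, np.nextafter(0, 1)), 1.0)
    return result


def annotate_clusters_with_polarization(
    clusters: list[MirnaCluster], polar: PolarizationSet
) -> pd.DataFrame:
    """Per cluster: member polarization labels and a summary call
    (M1 / M2 / mixed / none) with the contributing miRNAs."""
    rows = []
    for c in clusters:
        labeled = [(m, polar.label_of(m)) for m in c.members]
        labeled = [(m, lab) for m, lab in labeled if lab is not None]
        kinds = {lab for _, lab in labeled}
        call = (
            "none" if not kinds
            else "mixed" if kinds == {"M1", "M2"}
            else kinds.pop()
        )
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "polarization": call,
                "labeled_members": ",".join(f"{m}({lab})" for m, lab in labeled),
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "polarization", "labeled_members"])
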