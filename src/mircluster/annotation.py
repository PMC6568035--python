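"""Genome annotation parsing, miRNA cluster detection, and host-gene classification.

A miRNA cluster is defined as a group of at least ``min_cluster_size``
(default 4) annotated mature miRNAs whose total genomic span fits inside a
``window_bp`` (default 1 Mb) window on one chromosome.  The -5p and -3p arms
of a hairpin count as separate members.  Clustering ignores strand; the
dominant strand is summarized afterwards, and each cluster is classified by
its relation to overlapping genes (sense-intronic host, antisense transcript,
or intergenic).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MirnaRecord",
    "GeneRecord",
    "GenomeAnnotation",
    "MirnaCluster",
    "read_annotation",
    "detect_clusters",
    "classify_host_relation",
    "clusters_to_frame",
    "clusters_to_json",
    "chrom_sort_key",
]

_ARM_RE = re.compile(r"-(5p|3p)$", re.IGNORECASE)

VALID_STRANDS = {"+", "-", "unknown"}


@dataclass(frozen=True)
class MirnaRecord:
    """One mature miRNA: name and 1-based inclusive genomic interval."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("miRNA name must be nonempty")
        if self.start > self.end:
            raise ValueError(
                f"{self.name}: start {self.start} > end {self.end}"
            )
        if self.start < 0 or self.end < 0:
            raise ValueError(f"{self.name}: negative coordinates")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")

    @property
    def arm(self) -> str:
        """Arm (``5p``/``3p``) derived from the name suffix, else ``unspecified``."""
        m = _ARM_RE.search(self.name)
        return m.group(1).lower() if m else "unspecified"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval used for host-relation classification."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    biotype: str = ""


@dataclass
class GenomeAnnotation:
    """A collection of mature-miRNA records plus optional gene intervals."""

    records: list[MirnaRecord] = field(default_factory=list)
    genes: list[GeneRecord] | None = None

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for r in self.records:
            if r.name in seen:
                raise ValueError(f"duplicate miRNA name: {r.name!r}")
            seen[r.name] = 1

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MirnaCluster:
    """A called genomic miRNA cluster."""

    cluster_id: int
    chrom: str
    span_start: int
    span_end: int
    members: list[str]
    dominant_strand: str = "unknown"
    host_relation: str = "unknown"
    host_gene: str | None = None

    @property
    def span(self) -> int:
        return self.span_end - self.span_start

    @property
    def n_members(self) -> int:
        return len(self.members)


def chrom_sort_key(chrom: str):
    """Natural chromosome order: numeric labels first, then X, Y, others."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["name", "chrom", "start", "end", "strand"]


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return "gff3"
    return "tsv"


def read_annotation(path: str | Path, format: str | None = None) -> GenomeAnnotation:
    """Read a miRNA annotation from GFF3 (``miRNA`` features, ``Name=`` attribute)
    or a 5-column TSV (name, chrom, start, end, strand).

    GFF3 ``gene`` features, when present, are retained as gene intervals for
    host-relation classification.  Coordinates are 1-based inclusive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_tsv(path: Path) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MirnaRecord(
                    name=str(row.name),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand) if str(row.strand) in VALID_STRANDS else "unknown",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed line {i}: {exc}") from exc
    return GenomeAnnotation(records=records)


def _read_gff3(path: Path) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        id_spec=["ID", "Name"],
        merge_strategy="create_unique",
    )
    records = []
    for f in db.features_of_type("miRNA"):
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [f.id])[0]
        records.append(
            MirnaRecord(
                name=name,
                chrom=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in VALID_STRANDS else "unknown",
            )
        )
    genes = [
        GeneRecord(
            name=(g.attributes.get("Name") or [g.id])[0],
            chrom=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand if g.strand in VALID_STRANDS else "unknown",
            biotype=(g.attributes.get("biotype") or [""])[0],
        )
        for g in db.features_of_type("gene")
    ]
    return GenomeAnnotation(records=records, genes=genes or None)


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(
    ann: GenomeAnnotation,
    window_bp: int = 1_000_000,
    min_cluster_size: int = 4,
) -> list[MirnaCluster]:
    """Call miRNA clusters by greedy left-to-right chaining.

    Per chromosome, records sorted by (start, end, name) are chained: a record
    joins the open chain iff adding it keeps (max end - min start) <=
    ``window_bp``; otherwise the chain is closed and a new one opened.  Chains
    with >= ``min_cluster_size`` members become clusters, numbered by
    (chromosome order, span start).  Each miRNA belongs to at most one cluster.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if min_cluster_size < 2:
        raise ValueError(f"min_cluster_size must be >= 2, got {min_cluster_size}")
    by_chrom: dict[str, list[MirnaRecord]] = {}
    for r in ann.records:
        by_chrom.setdefault(r.chrom, []).append(r)

    clusters: list[MirnaCluster] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.name))
        chain: list[MirnaRecord] = []
        chain_max_end = 0

        def close() -> None:
            if len(chain) >= min_cluster_size:
                strands = [r.strand for r in chain if r.strand in {"+", "-"}]
                dominant = (
                    max(("+", "-"), key=strands.count) if strands else "unknown"
                )
                clusters.append(
                    MirnaCluster(
                        cluster_id=0,  # renumbered below
                        chrom=chrom,
                        span_start=chain[0].start,
                        span_end=chain_max_end,
                        members=[r.name for r in chain],
                        dominant_strand=dominant,
                    )
                )

        for r in recs:
            if chain and max(chain_max_end, r.end) - chain[0].start <= window_bp:
                chain.append(r)
                chain_max_end = max(chain_max_end, r.end)
            else:
                close()
                chain = [r]
                chain_max_end = r.end
        close()

    clusters.sort(key=lambda c: (chrom_sort_key(c.chrom), c.span_start))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


# ---------------------------------------------------------------------------
# Host-relation classification
# ---------------------------------------------------------------------------

def classify_host_relation(
    cluster: MirnaCluster, genes: Sequence[GeneRecord] | None
) -> MirnaCluster:
    """Classify a cluster's relation to overlapping genes.

    ``sense-intronic`` if a gene on the cluster's dominant strand fully
    contains its span (smallest such gene chosen); ``antisense`` if the only
    overlapping genes lie on the opposite strand (largest overlap chosen);
    ``intergenic`` if no gene overlaps; ``unknown`` if no gene annotation is
    available or only a partial same-strand overlap exists.
    """
    if genes is None:
        return replace_cluster(cluster, "unknown", None)
    overlapping = [
        g
        for g in genes
        if g.chrom == cluster.chrom
        and g.start <= cluster.span_end
        and g.end >= cluster.span_start
    ]
    if not overlapping:
        return replace_cluster(cluster, "intergenic", None)
    same = [g for g in overlapping if g.strand == cluster.dominant_strand]
    containing = [
        g for g in same if g.start <= cluster.span_start and g.end >= cluster.span_end
    ]
    if containing:
        best = min(containing, key=lambda g: (g.end - g.start, g.name))
        return replace_cluster(cluster, "sense-intronic", best.name)
    opposite = [g for g in overlapping if g.strand not in {cluster.dominant_strand, "unknown"}]
    if opposite and not same:
        best = max(
            opposite,
            key=lambda g: (
                min(g.end, cluster.span_end) - max(g.start, cluster.span_start),
                g.name,
            ),
        )
        return replace_cluster(cluster, "antisense", best.name)
    # partial same-strand overlap: no clean call
    return replace_cluster(cluster, "unknown", None)


def replace_cluster(
    cluster: MirnaCluster, relation: str, host_gene: str | None
) -> MirnaCluster:
    out = MirnaCluster(
        cluster_id=cluster.cluster_id,
        chrom=cluster.chrom,
        span_start=cluster.span_start,
        span_end=cluster.span_end,
        members=list(cluster.members),
        dominant_strand=cluster.dominant_strand,
        host_relation=relation,
        host_gene=host_gene,
    )
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def clusters_to_frame(clusters: Iterable[MirnaCluster]) -> pd.DataFrame:
    """Tabulate clusters with the familiar Cluster/Chr/First/Last/Dir columns."""
    rows = [
        {
            "Cluster": c.cluster_id,
            "Chr": c.chrom,
            "First": c.span_start,
            "Last": c.span_end,
            "Dir": c.dominant_strand,
            "HostRelation": c.host_relation,
            "HostGene": c.host_gene or "",
            "Members": ",".join(c.members),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "Cluster", "Chr", "First", "Last", "Dir",
            "HostRelation", "HostGene", "Members",
        ],
    )


def clusters_to_json(clusters: Iterable[MirnaCluster]) -> str:
    return json.dumps(
        [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "span_start": c.span_start,
                "span_end": c.span_end,
                "dominant_strand": c.dominant_strand,
                "host_relation": c.host_relation,
                "host_gene": c.host_gene,
                "members": c.members,
            }
            for c in clusters
        ],
        indent=2,
    )
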