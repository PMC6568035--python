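"""Packaged reference tables and fixture builders.

Ships the published 13-cluster table, the 9-entry polarization table, the
static cross-species host-gene reference, and two synthetic stand-ins for
supplementary material that is not redistributable here (the full 44-miRNA
polarization set and the complete DE statistics table; their filenames and
headers mark them as synthetic).

``build_reference_annotation`` turns the cluster table into a concrete
annotation: member coordinates are interpolated inside each cluster's printed
span (the span endpoints are exact; individual member positions within it are
synthetic), and solitary decoy miRNAs are placed at least 2 Mb from every
cluster so that cluster calls are unambiguous.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GenomeAnnotation, MirnaRecord, chrom_sort_key
from .enrichment import PolarizationSet, load_polarization_set

__all__ = [
    "load_cluster_table",
    "load_polarization_table",
    "load_full_polarization_set",
    "load_de_results",
    "load_host_gene_reference",
    "build_reference_annotation",
    "reference_gene_records",
    "MATURE_LEN",
]

MATURE_LEN = 22


def _data_path(name: str):
    return resources.files("mircluster.data").joinpath(name)


def load_cluster_table() -> pd.DataFrame:
    """The published 13-cluster table (span coordinates, strand, members)."""
    with resources.as_file(_data_path("cluster_table.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"chrom": str})


def load_polarization_table() -> pd.DataFrame:
    """The 9 DE polarization miRNAs with published labels, logFC and FDR."""
    with resources.as_file(_data_path("polarization_table1.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_full_polarization_set() -> PolarizationSet:
    """44-entry polarization set (synthetic stand-in; see module docstring)."""
    with resources.as_file(_data_path("polarization_set_44_synthetic.tsv")) as p:
        return load_polarization_set(p)


def load_de_results() -> pd.DataFrame:
    """Full DE statistics table (synthetic stand-in; see module docstring),
    indexed by miRNA with logFC / PValue / FDR columns renamed to the
    package's conventions."""
    with resources.as_file(_data_path("de_results_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df = df.rename(
        columns={"GeneID": "mirna", "LR": "lrt_stat", "PValue": "p_value", "FDR": "fdr"}
    ).set_index("mirna")
    return df


def load_host_gene_reference() -> pd.DataFrame:
    """Static cross-species (rat/mouse/human) host-gene table; reference only."""
    with resources.as_file(_data_path("host_gene_reference.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def _interpolated_members(row) -> list[MirnaRecord]:
    members = row.members.split(",")
    first, last = int(row.first), int(row.last)
    m = len(members)
    records = []
    for i, name in enumerate(members):
        if m == 1:
            start = first
        elif i == m - 1:
            start = last - MATURE_LEN + 1
        else:
            start = first + round(i * (last - first - MATURE_LEN + 1) / (m - 1))
        records.append(
            MirnaRecord(
                name=name,
                chrom=str(row.chrom),
                start=int(start),
                end=int(start) + MATURE_LEN - 1,
                strand=str(row.strand),
            )
        )
    return records


def build_reference_annotation(
    n_decoys: int = 24,
    seed: int = 0,
    decoy_gap: int = 2_500_000,
) -> GenomeAnnotation:
    """Annotation fixture: every published cluster member at its printed span,
    plus ``n_decoys`` solitary decoy miRNAs placed >= 2 Mb from any cluster.

    Two mature miRNAs appear in two clusters each (miR-181a-5p and
    miR-181b-5p arise from two loci); the second occurrence gets a ``.2``
    locus suffix to keep names unique.
    """
    table = load_cluster_table()
    records: list[MirnaRecord] = []
    seen: set[str] = set()
    chrom_max: dict[str, int] = {}
    for row in table.itertuples(index=False):
        for rec in _interpolated_members(row):
            name = rec.name
            while name in seen:
                name += ".2"
            seen.add(name)
            if name != rec.name:
                rec = MirnaRecord(name, rec.chrom, rec.start, rec.end, rec.strand)
            records.append(rec)
            chrom_max[rec.chrom] = max(chrom_max.get(rec.chrom, 0), rec.end)

    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_max, key=chrom_sort_key)
    for i in range(n_decoys):
        chrom = chroms[i % len(chroms)]
        pos = chrom_max[chrom] + decoy_gap + int(rng.integers(0, decoy_gap // 5))
        chrom_max[chrom] = pos + MATURE_LEN - 1
        records.append(
            MirnaRecord(
                name=f"decoy-miR-{i + 1:03d}",
                chrom=chrom,
                start=pos,
                end=pos + MATURE_LEN - 1,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return GenomeAnnotation(records=records)


def reference_gene_records() -> list[GeneRecord]:
    """Gene intervals implied by the published host-gene column: sense hosts
    contain their cluster's span on the cluster strand, antisense hosts on
    the opposite strand.  Interval extents beyond the cluster span are
    nominal (5 kb pad)."""
    table = load_cluster_table()
    genes = []
    for row in table.itertuples(index=False):
        host = row.host_gene if isinstance(row.host_gene, str) else ""
        if not host:
            continue
        relation = row.host_relation
        strand = str(row.strand)
        if relation == "antisense":
            strand = "-" if strand == "+" else "+"
        genes.append(
            GeneRecord(
                name=host,
                chrom=str(row.chrom),
                start=int(row.first) - 5_000,
                end=int(row.last) + 5_000,
                strand=strand,
            )
        )
    return genes
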