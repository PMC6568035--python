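"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure the analysis assumes: a genome
annotation with clusters of >= 4 mature miRNAs (arm pairs named -5p/-3p)
spaced >= 2 Mb apart so cluster truth is unambiguous, solitary miRNAs far
from any cluster, negative-binomial counts under a 2x2 diet x treatment
design with planted log2 fold changes, an expression-filter structure (a
fraction of all-zero rows), latent-factor within-cluster correlation for a
designated subset of clusters, and qPCR Ct tables with planted group folds.

Latent-factor construction: for a co-regulated cluster c, each sample j
draws z_cj ~ N(0, 1) and member i adds lambda_i * z_cj to its log mean.
With v_i = 1/mu_i + phi approximating the NB variance of log counts (delta
method), lambda_i = sqrt(rho * v_i / (1 - rho)) gives within-cluster
log-scale Pearson correlation ~= rho.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, GeneRecord, MirnaRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_ct_table",
]

MATURE_LEN = 22  # bp, typical mature miRNA


@dataclass
class SimulationConfig:
    """Generator parameters.

    Defaults mirror the study design: 13 genomic clusters of which 3 are
    co-regulated, a 2x2 pair/ethanol x baseline/LPS layout with 3 animals per
    cell (6 baseline samples), NB dispersion 0.1, 10% of miRNAs differentially
    expressed by diet with |log2FC| = 2 and 95% of effects downregulated.
    """

    seed: int
    n_chromosomes: int = 4
    chromosome_length: int = 300_000_000
    n_clusters: int = 13
    cluster_size_range: tuple[int, int] = (4, 10)
    max_cluster_span: int = 60_000
    cluster_spacing: int = 2_000_000
    n_solitary_mirnas: int = 60
    n_samples_per_cell: int = 3
    nb_dispersion: float = 0.1
    mean_log_count: float = float(np.log(200.0))
    sd_log_count: float = 1.2
    zero_fraction: float = 0.05
    library_size_sd: float = 0.1
    de_fraction: float = 0.10
    de_logfc: float = 2.0
    de_down_fraction: float = 0.95
    lps_logfc: float = 0.0
    n_coregulated: int = 3
    rho: float = 0.9
    n_polarization: int = 20
    polar_de_fraction: float = 0.5
    # qPCR arm
    n_healthy: int = 9
    n_ah: int = 10
    qpcr_targets: int = 8
    qpcr_fold_ah: float = 4.0
    qpcr_de_targets: int = 3
    qpcr_noise_sd: float = 0.5
    qpcr_rho: float = 0.9
    qpcr_clustered_pairs: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        for name in (
            "n_chromosomes", "chromosome_length", "n_solitary_mirnas",
            "n_samples_per_cell", "max_cluster_span", "cluster_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic data."""

    cluster_members: dict[int, list[str]] = field(default_factory=dict)
    coregulated_clusters: list[int] = field(default_factory=list)
    host_relations: dict[int, str] = field(default_factory=dict)
    de_logfc: dict[str, float] = field(default_factory=dict)  # log2, diet effect
    polarization: dict[str, str] = field(default_factory=dict)
    all_zero: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["cluster_members"] = {str(k): v for k, v in d["cluster_members"].items()}
        d["host_relations"] = {str(k): v for k, v in d["host_relations"].items()}
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Place clusters (>= 2 Mb apart) and solitary miRNAs on synthetic
    chromosomes, with -5p/-3p arms named in pairs."""
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    records: list[MirnaRecord] = []
    genes: list[GeneRecord] = []

    n_chrom = cfg.n_chromosomes
    placements = cfg.n_clusters + cfg.n_solitary_mirnas
    per_chrom = -(-placements // n_chrom)  # ceil
    jitter_max = cfg.cluster_spacing // 4
    # guarantees >= cluster_spacing bp between consecutive placements
    step = cfg.cluster_spacing + cfg.max_cluster_span + jitter_max
    if per_chrom * step + cfg.cluster_spacing > cfg.chromosome_length:
        raise ValueError(
            f"chromosome_length {cfg.chromosome_length} too short for "
            f"{placements} placements spaced {cfg.cluster_spacing} bp apart"
        )

    # interleave cluster and solitary slots deterministically
    slots = [("cluster", i + 1) for i in range(cfg.n_clusters)]
    slots += [("solitary", i) for i in range(cfg.n_solitary_mirnas)]
    order = rng.permutation(len(slots))

    relations = ["antisense", "sense-intronic", "intergenic"]
    for slot_idx, si in enumerate(order):
        kind, ident = slots[si]
        chrom = f"chr{slot_idx % n_chrom + 1}"
        slot_on_chrom = slot_idx // n_chrom
        base = cfg.cluster_spacing + slot_on_chrom * step
        base += int(rng.integers(0, jitter_max))
        if kind == "solitary":
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                MirnaRecord(
                    name=f"sim-miR-s{ident:03d}",
                    chrom=chrom, start=base, end=base + MATURE_LEN - 1,
                    strand=strand,
                )
            )
            continue
        cid = ident
        lo, hi = cfg.cluster_size_range
        n_pri = int(rng.integers(max(2, lo // 2), hi // 2 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(n_pri * 120, cfg.max_cluster_span))
        members = []
        for p in range(n_pri):
            pri_start = base + int(round(p * (span - 120) / max(n_pri - 1, 1)))
            for arm, off in (("5p", 0), ("3p", 50)):
                name = f"sim-miR-c{cid:02d}-{p + 1}-{arm}"
                records.append(
                    MirnaRecord(
                        name=name, chrom=chrom,
                        start=pri_start + off, end=pri_start + off + MATURE_LEN - 1,
                        strand=strand,
                    )
                )
                members.append(name)
        truth.cluster_members[cid] = members
        relation = relations[(cid - 1) % len(relations)]
        truth.host_relations[cid] = relation
        span_start, span_end = base, base + span + 50 + MATURE_LEN
        if relation == "sense-intronic":
            genes.append(
                GeneRecord(
                    name=f"SimHost{cid}", chrom=chrom,
                    start=span_start - 5_000, end=span_end + 5_000, strand=strand,
                )
            )
        elif relation == "antisense":
            genes.append(
                GeneRecord(
                    name=f"SimAnti{cid}", chrom=chrom,
                    start=span_start - 5_000, end=span_end + 5_000,
                    strand="-" if strand == "+" else "+",
                )
            )

    truth.coregulated_clusters = list(range(1, min(cfg.n_coregulated, cfg.n_clusters) + 1))
    ann = GenomeAnnotation(records=records, genes=genes or None)
    return ann, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _sample_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for diet in ("pair", "ethanol"):
        for trt in ("baseline", "LPS"):
            for i in range(cfg.n_samples_per_cell):
                rows.append(
                    {
                        "sample_id": f"{diet}_{trt}_{i + 1}",
                        "diet": diet,
                        "treatment": trt,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    cfg: SimulationConfig, ann: GenomeAnnotation, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts under the diet x treatment design with planted effects.

    Per miRNA i and sample j: count ~ NB(mu_ij, phi) with
    log mu_ij = b_i + ln2 * logFC_i * [ethanol_j] + ln2 * lpsFC * [LPS_j]
    + library offset + lambda_i * z_cj (co-regulated clusters only).
    Fixed seed + config gives a bit-reproducible matrix.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    meta = _sample_metadata(cfg)
    names = ann.names
    G, S = len(names), len(meta)

    base = rng.normal(cfg.mean_log_count, cfg.sd_log_count, size=G)
    zero = rng.random(G) < cfg.zero_fraction
    truth.all_zero = [names[i] for i in np.flatnonzero(zero)]

    # planted diet effects
    n_de = int(round(cfg.de_fraction * G))
    de_idx = rng.choice(np.flatnonzero(~zero), size=min(n_de, int((~zero).sum())), replace=False)
    logfc = np.zeros(G)
    signs = np.where(rng.random(de_idx.size) < cfg.de_down_fraction, -1.0, 1.0)
    logfc[de_idx] = signs * cfg.de_logfc
    truth.de_logfc = {names[i]: float(logfc[i]) for i in de_idx}

    # polarization labels: a configurable blend of DE and non-DE miRNAs
    n_from_de = int(round(cfg.polar_de_fraction * cfg.n_polarization))
    pool_de = [names[i] for i in de_idx]
    pool_other = [n for n in names if n not in set(pool_de)]
    chosen = list(rng.choice(pool_de, size=min(n_from_de, len(pool_de)), replace=False))
    chosen += list(
        rng.choice(pool_other, size=min(cfg.n_polarization - len(chosen), len(pool_other)), replace=False)
    )
    truth.polarization = {
        n: ("M1" if rng.random() < 0.5 else "M2") for n in chosen
    }

    ethanol = (meta["diet"] == "ethanol").to_numpy(dtype=float)
    lps = (meta["treatment"] == "LPS").to_numpy(dtype=float)
    lib_offset = rng.normal(0.0, cfg.library_size_sd, size=S)

    log_mu = (
        base[:, None]
        + np.log(2.0) * (logfc[:, None] * ethanol[None, :] + cfg.lps_logfc * lps[None, :])
        + lib_offset[None, :]
    )

    # latent-factor correlation for co-regulated clusters
    name_pos = {n: i for i, n in enumerate(names)}
    for cid in truth.coregulated_clusters:
        members = truth.cluster_members.get(cid, [])
        idx = np.array([name_pos[m] for m in members if not zero[name_pos[m]]])
        if idx.size < 2:
            continue
        mu_base = np.exp(base[idx])
        v = 1.0 / mu_base + cfg.nb_dispersion  # delta-method var of log count
        lam = np.sqrt(cfg.rho * v / (1.0 - cfg.rho))
        z = rng.standard_normal(S)
        log_mu[idx] += lam[:, None] * z[None, :]

    mu = np.exp(log_mu)
    mu[zero] = 0.0
    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu * cfg.nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts, index=pd.Index(names, name="mirna"), columns=meta.index)
    return df, meta.copy()


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table for healthy vs AH groups with planted folds and
    latent-factor correlated target pairs.

    Ct(target) = baseline_t - log2(relative expression) + N(0, noise_sd);
    the reference gene is constant across groups.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    truth = GroundTruth()
    samples = [("healthy", f"H{i + 1}") for i in range(cfg.n_healthy)]
    samples += [("AH", f"A{i + 1}") for i in range(cfg.n_ah)]
    targets = [f"sim-target-{t + 1}" for t in range(cfg.qpcr_targets)]

    # first qpcr_de_targets targets carry the AH fold change
    fold = {
        t: (cfg.qpcr_fold_ah if i < cfg.qpcr_de_targets else 1.0)
        for i, t in enumerate(targets)
    }
    truth.de_logfc = {t: float(np.log2(f)) for t, f in fold.items()}
    # pair up the first 2*qpcr_clustered_pairs targets into latent-factor clusters
    cluster_of: dict[str, int] = {}
    for p in range(cfg.qpcr_clustered_pairs):
        for t in targets[2 * p : 2 * p + 2]:
            cluster_of[t] = p + 1
    truth.cluster_members = {
        c: [t for t, cc in cluster_of.items() if cc == c]
        for c in sorted(set(cluster_of.values()))
    }
    truth.coregulated_clusters = sorted(truth.cluster_members)

    lam = np.sqrt(cfg.qpcr_rho / (1.0 - cfg.qpcr_rho)) * cfg.qpcr_noise_sd
    base_ct = {t: float(rng.uniform(20.0, 30.0)) for t in targets}
    ref_ct = 15.0

    rows = []
    for group, sid in samples:
        z = {c: rng.standard_normal() for c in truth.cluster_members}
        for t in targets:
            expr_log2 = (np.log2(fold[t]) if group == "AH" else 0.0)
            if t in cluster_of:
                expr_log2 += lam * z[cluster_of[t]]
            noise = rng.normal(0.0, cfg.qpcr_noise_sd)
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "target": t,
                    "reference": "SNORD68",
                    "ct_target": base_ct[t] - expr_log2 + noise,
                    "ct_reference": ref_ct,
                    "replicate": 1,
                }
            )
    return pd.DataFrame(rows), truth
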