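"""End-to-end orchestration of the sequencing (rat) and qPCR (human) arms.

The rat arm runs: expression filter -> TMM -> common dispersion -> NB-GLM
LRT for the diet effect (LPS as covariate) and for the LPS effect (diet as
covariate) -> BH FDR -> DE table -> genomic cluster detection and host
classification -> polarization enrichment -> baseline correlation filter ->
all-pairs Pearson -> 2.5% tail thresholds -> significant pairs -> per-cluster
co-expression enrichment.  The qPCR arm runs: ddCt -> group comparison ->
cluster-annotated pairwise correlation.  Both write TSV outputs, a run log,
and a machine-readable summary JSON validated against the shipped schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import coexpression as coex
from . import diffexpr as de_mod
from . import enrichment as enr
from . import expression as expr_mod
from . import qpcr as qpcr_mod
from . import simulate as sim_mod

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_rat_pipeline",
    "run_qpcr_pipeline",
    "simulate_to_dir",
    "validate_summary",
]

log = logging.getLogger("mircluster")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (input digest {digest}): {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths and parameters for a pipeline run."""

    output_dir: str
    annotation: str | None = None
    genes: str | None = None
    counts: str | None = None
    metadata: str | None = None
    polarization: str | None = None
    ct_table: str | None = None
    control_group: str = "healthy"
    window_bp: int = 1_000_000
    min_cluster_size: int = 4
    min_fraction: float = 0.25
    min_present: int = 5
    fdr_cutoff: float = 0.2
    tail_fraction: float = 0.025
    alpha: float = 0.05
    trim_m: float = 0.30
    trim_a: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require: tuple[str, ...]) -> None:
        for key in require:
            path = getattr(self, key)
            if path is None:
                raise ValueError(f"config is missing required input {key!r}")
            if not Path(path).exists():
                raise ValueError(f"{key} file does not exist: {path}")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.window_bp <= 0 or self.min_cluster_size < 2:
            raise ValueError("invalid clustering parameters")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _setup_run(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("parameters: %s", json.dumps(asdict(cfg), sort_keys=True))
    log.info("seed: %d", cfg.seed)
    return outdir


def validate_summary(summary: dict, kind: str) -> None:
    """Check a summary dict against the shipped schema (required keys and types)."""
    with resources.as_file(
        resources.files("mircluster.data").joinpath("summary_schema.json")
    ) as p:
        schema = json.loads(Path(p).read_text())[kind]
    types = {"int": int, "float": float, "list": list, "dict": dict}
    for key, tname in schema["required"].items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        if not isinstance(summary[key], types[tname]):
            raise ValueError(
                f"summary key {key!r} has type {type(summary[key]).__name__}, "
                f"expected {tname}"
            )
    for key, tname in schema.get("enrichment_required", {}).items():
        if key not in summary.get("enrichment", {}):
            raise ValueError(f"summary enrichment missing key {key!r}")


def run_rat_pipeline(cfg: PipelineConfig) -> dict:
    """Run the sequencing arm; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    cfg.validate(require=("annotation", "counts", "metadata", "polarization"))
    outdir = _setup_run(cfg)
    digest = cfg.digest()
    stage = "load_inputs"
    try:
        ann = ann_mod.read_annotation(cfg.annotation)
        genes = None
        if cfg.genes:
            genes = ann_mod.read_annotation(cfg.genes).genes
        counts = expr_mod.read_counts(cfg.counts)
        meta = expr_mod.read_metadata(cfg.metadata)
        expr_mod.validate_metadata(meta, counts)
        if counts.shape[1] == 0:
            raise ValueError("count matrix has zero samples")
        polar = enr.load_polarization_set(cfg.polarization)

        stage = "filter_expressed"
        expressed = expr_mod.filter_expressed(counts, cfg.min_fraction)
        log.info("expressed: %d of %d miRNAs", expressed.shape[0], counts.shape[0])

        stage = "tmm_factors"
        factors = de_mod.tmm_factors(expressed, cfg.trim_m, cfg.trim_a)

        stage = "estimate_common_dispersion"
        design = de_mod.build_design(meta.loc[expressed.columns])
        disp = de_mod.estimate_common_dispersion(expressed, design)
        log.info("common dispersion: %.4g", disp.common_dispersion)

        stage = "nb_glm_lrt"
        de_diet = de_mod.nb_glm_lrt(expressed, meta, factors, disp, contrast="diet")
        de_trt = de_mod.nb_glm_lrt(expressed, meta, factors, disp, contrast="treatment")

        stage = "de_table"
        sig_diet = de_mod.de_table(de_diet, cfg.fdr_cutoff)
        sig_trt = de_mod.de_table(de_trt, cfg.fdr_cutoff)
        de_diet.to_csv(outdir / "de_diet.tsv", sep="\t")
        de_trt.to_csv(outdir / "de_treatment.tsv", sep="\t")
        sig_diet.to_csv(outdir / "de_diet_significant.tsv", sep="\t")

        stage = "detect_clusters"
        clusters = ann_mod.detect_clusters(ann, cfg.window_bp, cfg.min_cluster_size)
        stage = "classify_host_relation"
        clusters = [ann_mod.classify_host_relation(c, genes) for c in clusters]
        ann_mod.clusters_to_frame(clusters).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        (outdir / "clusters.json").write_text(ann_mod.clusters_to_json(clusters))

        stage = "polarization_enrichment"
        inputs = enr.intersect_de(polar, sig_diet, universe=list(expressed.index))
        enrich = enr.fisher_exact_enrichment(
            inputs["k"], inputs["K"], inputs["n"], inputs["N"]
        )
        enr.annotate_clusters_with_polarization(clusters, polar).to_csv(
            outdir / "cluster_polarization.tsv", sep="\t", index=False
        )

        stage = "filter_for_correlation"
        baseline = expr_mod.filter_for_correlation(counts, meta, cfg.min_present)
        lengths = pd.Series(
            {r.name: r.length for r in ann.records}
        ).reindex(baseline.index).fillna(22)
        tpm = expr_mod.tpm_transform(baseline, lengths)

        stage = "pairwise_pearson"
        analysis = coex.pairwise_pearson(tpm)
        stage = "tail_thresholds"
        analysis.lower_threshold, analysis.upper_threshold = coex.tail_thresholds(
            analysis.corr, cfg.tail_fraction
        )
        stage = "significant_pairs"
        mask = coex.significant_pairs(analysis, cfg.alpha)
        analysis.corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t")
        _write_edges(outdir / "significant_pairs.tsv", analysis, clusters)

        stage = "cluster_coexpression_enrichment"
        results = coex.cluster_coexpression_enrichment(mask, clusters, cfg.alpha)
        pd.DataFrame([vars(r) for r in results]).to_csv(
            outdir / "cluster_coexpression.tsv", sep="\t", index=False
        )

        member_set = {m for c in clusters for m in c.members}
        coexpressed = [r.cluster_id for r in results if r.co_expressed]
        summary = {
            "n_mirnas_input": int(counts.shape[0]),
            "n_mirnas_expressed": int(expressed.shape[0]),
            "n_de_diet": int(sig_diet.shape[0]),
            "n_de_diet_up": sig_diet.attrs["n_up"],
            "n_de_diet_down": sig_diet.attrs["n_down"],
            "n_de_treatment": int(sig_trt.shape[0]),
            "n_clusters": len(clusters),
            "n_de_in_clusters": int(sum(m in member_set for m in sig_diet.index)),
            "n_coexpressed_clusters": len(coexpressed),
            "coexpressed_cluster_ids": coexpressed,
            "enrichment": {
                "k": enrich.overlap_k, "K": enrich.set_size_K,
                "n": enrich.de_size_n, "N": enrich.universe_N,
                "odds_ratio": float(enrich.odds_ratio),
                "p_value": float(enrich.p_value),
            },
            "correlation_thresholds": {
                "lower": float(analysis.lower_threshold),
                "upper": float(analysis.upper_threshold),
            },
            "parameters": {
                k: v for k, v in asdict(cfg).items()
                if isinstance(v, (int, float)) and not isinstance(v, bool)
            },
            "seed": cfg.seed,
        }
        validate_summary(summary, "rat")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("rat pipeline complete: %s", json.dumps(summary)[:500])
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        log.exception("stage %s failed", stage)
        raise PipelineError(stage, digest, exc) from exc
    finally:
        for h in list(log.handlers):
            if isinstance(h, logging.FileHandler):
                log.removeHandler(h)
                h.close()


def _write_edges(path: Path, analysis, clusters) -> None:
    mask = analysis.significant_mask.to_numpy()
    idx = analysis.corr.index
    member_of: dict[str, int] = {}
    for c in clusters:
        for m in c.members:
            member_of[m] = c.cluster_id
    rows = []
    ii, jj = np.triu_indices(len(idx), k=1)
    for i, j in zip(ii, jj):
        if not mask[i, j]:
            continue
        a, b = idx[i], idx[j]
        r = analysis.corr.iat[i, j]
        rows.append(
            {
                "mirna_a": a, "mirna_b": b,
                "r": r, "p_value": analysis.pvals.iat[i, j],
                "sign": "positive" if r > 0 else "negative",
                "same_cluster": member_of.get(a) is not None
                and member_of.get(a) == member_of.get(b),
            }
        )
    pd.DataFrame(
        rows, columns=["mirna_a", "mirna_b", "r", "p_value", "sign", "same_cluster"]
    ).to_csv(path, sep="\t", index=False)


def run_qpcr_pipeline(cfg: PipelineConfig, clusters: dict[str, int] | None = None) -> dict:
    """Run the qPCR arm; returns the summary dict."""
    cfg.validate(require=("ct_table",))
    outdir = _setup_run(cfg)
    digest = cfg.digest()
    stage = "load_inputs"
    try:
        table = qpcr_mod.read_ct_table(cfg.ct_table)

        stage = "ddct"
        rel = qpcr_mod.ddct(table, control_group=cfg.control_group)
        rel.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
        summary_stats = (
            rel.groupby(["target", "group"])["rel_expr"]
            .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
            .reset_index()
        )
        summary_stats.to_csv(outdir / "group_means.tsv", sep="\t", index=False)

        stage = "group_compare"
        groups = list(pd.unique(rel["group"]))
        if len(groups) >= 2:
            comparison = qpcr_mod.group_compare(rel, alpha=cfg.alpha)
            comparison.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
            n_sig = int(comparison["significant"].sum())
        else:
            import warnings

            warnings.warn("only one group present; group comparison skipped")
            comparison = None
            n_sig = 0

        stage = "qpcr_pairwise_correlation"
        edges = qpcr_mod.qpcr_pairwise_correlation(rel, clusters=clusters)
        edges.to_csv(outdir / "correlation_edges.tsv", sep="\t", index=False)

        summary = {
            "n_targets": int(rel["target"].nunique()),
            "n_samples": int(rel["sample_id"].nunique()),
            "groups": groups,
            "n_significant_targets": n_sig,
            "n_pairs": int(edges.shape[0]),
            "n_significant_pairs": int((edges["p_value"] < cfg.alpha).sum()),
            "parameters": {"alpha": cfg.alpha, "control_group": cfg.control_group},
            "seed": cfg.seed,
        }
        validate_summary(summary, "qpcr")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        log.exception("stage %s failed", stage)
        raise PipelineError(stage, digest, exc) from exc
    finally:
        for h in list(log.handlers):
            if isinstance(h, logging.FileHandler):
                log.removeHandler(h)
                h.close()


def simulate_to_dir(cfg: sim_mod.SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic scenario and write it in the formats the
    pipeline consumes, plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth = sim_mod.simulate_annotation(cfg)
    counts, meta = sim_mod.simulate_counts(cfg, ann, truth)
    ct, ct_truth = sim_mod.simulate_ct_table(cfg)

    paths = {
        "annotation": outdir / "annotation.tsv",
        "genes": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "polarization": outdir / "polarization.tsv",
        "ct_table": outdir / "ct_table.csv",
        "truth": outdir / "truth.json",
        "ct_truth": outdir / "ct_truth.json",
    }
    pd.DataFrame(
        [
            {"name": r.name, "chrom": r.chrom, "start": r.start, "end": r.end,
             "strand": r.strand}
            for r in ann.records
        ]
    ).to_csv(paths["annotation"], sep="\t", index=False)
    with open(paths["genes"], "w") as f:
        f.write("##gff-version 3\n")
        for g in ann.genes or []:
            f.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.name};Name={g.name}\n"
            )
    counts.to_csv(paths["counts"], sep="\t")
    meta.to_csv(paths["metadata"], sep="\t")
    pd.DataFrame(
        [
            {"mirna": m, "label": lab, "sources": "simulated"}
            for m, lab in truth.polarization.items()
        ]
    ).to_csv(paths["polarization"], sep="\t", index=False)
    ct.to_csv(paths["ct_table"], index=False)
    paths["truth"].write_text(truth.to_json())
    paths["ct_truth"].write_text(ct_truth.to_json())
    return paths
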