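"""Synthetic-data generator: determinism, truth consistency, calibration."""

import numpy as np
import pandas as pd
import pytest

from mircluster.annotation import detect_clusters
from mircluster.diffexpr import (
    DispersionEstimate, de_table, estimate_common_dispersion, build_design,
    nb_glm_lrt, tmm_factors,
)
from mircluster.expression import tpm_transform
from mircluster.qpcr import ddct
from mircluster.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_ct_table,
)


def _small_cfg(seed, **kw):
    defaults = dict(n_clusters=4, n_solitary_mirnas=12, n_coregulated=1)
    defaults.update(kw)
    return SimulationConfig(seed=seed, **defaults)


class TestDeterminism:
    def test_identical_seed_gives_identical_outputs(self):
        a1, t1 = simulate_annotation(_small_cfg(5))
        a2, t2 = simulate_annotation(_small_cfg(5))
        assert [r.__dict__ for r in a1.records] == [r.__dict__ for r in a2.records]
        c1, m1 = simulate_counts(_small_cfg(5), a1, t1)
        c2, m2 = simulate_counts(_small_cfg(5), a2, t2)
        assert c1.equals(c2) and m1.equals(m2)
        ct1, _ = simulate_ct_table(_small_cfg(5))
        ct2, _ = simulate_ct_table(_small_cfg(5))
        assert ct1.equals(ct2)

    def test_different_seeds_differ(self):
        c1, _ = simulate_counts(_small_cfg(5), *simulate_annotation(_small_cfg(5)))
        c2, _ = simulate_counts(_small_cfg(6), *simulate_annotation(_small_cfg(6)))
        assert not np.array_equal(c1.to_numpy(), c2.to_numpy())


class TestAnnotationGeneration:
    def test_default_13_clusters_recovered_exactly(self):
        cfg = SimulationConfig(seed=0)
        ann, truth = simulate_annotation(cfg)
        clusters = detect_clusters(ann)
        assert len(clusters) == 13
        det = sorted(tuple(c.members) for c in clusters)
        tru = sorted(tuple(v) for v in truth.cluster_members.values())
        assert det == tru

    def test_zero_clusters(self):
        cfg = SimulationConfig(seed=1, n_clusters=0, n_solitary_mirnas=10)
        ann, truth = simulate_annotation(cfg)
        assert detect_clusters(ann) == []

    @pytest.mark.parametrize("seed", range(100))
    def test_recovery_sweep(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(
            seed=seed,
            n_clusters=int(rng.integers(0, 8)),
            n_solitary_mirnas=int(rng.integers(1, 30)),
            n_chromosomes=int(rng.integers(1, 5)),
        )
        ann, truth = simulate_annotation(cfg)
        det = sorted(tuple(c.members) for c in detect_clusters(ann))
        tru = sorted(tuple(v) for v in truth.cluster_members.values())
        assert det == tru

    def test_chromosome_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_annotation(
                SimulationConfig(seed=0, chromosome_length=10_000_000, n_chromosomes=1)
            )

    def test_arm_names_paired(self):
        ann, truth = simulate_annotation(_small_cfg(2))
        members = [m for v in truth.cluster_members.values() for m in v]
        assert all(m.endswith(("-5p", "-3p")) for m in members)


class TestCountGeneration:
    def test_poisson_limit_column_sums(self):
        cfg = _small_cfg(3, nb_dispersion=0.0, de_fraction=0.0, zero_fraction=0.0,
                         library_size_sd=0.0, n_coregulated=0)
        ann, truth = simulate_annotation(cfg)
        counts, meta = simulate_counts(cfg, ann, truth)
        expected = np.exp(np.random.default_rng(cfg.seed + 1).normal(
            cfg.mean_log_count, cfg.sd_log_count, size=len(ann))).sum()
        sums = counts.sum(axis=0).to_numpy(dtype=float)
        # Poisson column totals concentrate around the summed means
        assert np.all(np.abs(sums - expected) < 5 * np.sqrt(expected))

    def test_truth_matches_outputs(self):
        cfg = _small_cfg(4)
        ann, truth = simulate_annotation(cfg)
        counts, meta = simulate_counts(cfg, ann, truth)
        assert list(counts.index) == ann.names
        assert set(meta["diet"]) == {"pair", "ethanol"}
        for name in truth.all_zero:
            assert counts.loc[name].sum() == 0
        assert (counts.to_numpy() >= 0).all()

    def test_de_recovery_sensitivity_and_fdr(self):
        """Planted |log2FC| = 2 in 10% of 500 miRNAs, 6+6 samples: the NB-GLM
        at FDR < 0.2 recovers >= 80% with realized FDR <= 0.25."""
        cfg = SimulationConfig(
            seed=10, n_clusters=0, n_solitary_mirnas=500, n_coregulated=0,
            zero_fraction=0.0, de_down_fraction=0.5, n_chromosomes=8,
        )
        ann, truth = simulate_annotation(cfg)
        counts, meta = simulate_counts(cfg, ann, truth)
        counts = counts[counts.sum(axis=1) > 0]
        factors = tmm_factors(counts)
        disp = estimate_common_dispersion(counts, build_design(meta.loc[counts.columns]))
        res = nb_glm_lrt(counts, meta, factors, disp, contrast="diet")
        called = set(de_table(res, 0.2).index)
        truth_set = set(truth.de_logfc)
        sens = len(called & truth_set) / len(truth_set)
        fdr = len(called - truth_set) / max(len(called), 1)
        assert sens >= 0.8
        assert fdr <= 0.25

    def test_latent_factor_correlation_calibrated(self):
        """rho = 0.9 latent factor: mean within-cluster log-TPM correlation
        lands in [0.8, 0.95] at 50 baseline samples.  The annotation carries
        200 solitary miRNAs so the cluster members are a small fraction of the
        library, as in real miRNomes; otherwise the TPM denominator itself
        carries the latent factor and attenuates the correlations."""
        cfg = SimulationConfig(
            seed=11, n_samples_per_cell=25, n_clusters=4, n_coregulated=2,
            n_solitary_mirnas=200,
        )
        ann, truth = simulate_annotation(cfg)
        counts, meta = simulate_counts(cfg, ann, truth)
        base = counts[meta.index[meta["treatment"] == "baseline"]]
        log_tpm = np.log2(tpm_transform(base, pd.Series(22.0, index=base.index)) + 1)
        for cid in truth.coregulated_clusters:
            mem = [m for m in truth.cluster_members[cid] if m not in truth.all_zero]
            C = np.corrcoef(log_tpm.loc[mem].to_numpy())
            iu = np.triu_indices_from(C, 1)
            assert 0.8 <= C[iu].mean() <= 0.95


class TestCtGeneration:
    def test_zero_noise_unit_fold_gives_exact_1(self):
        cfg = SimulationConfig(seed=6, qpcr_fold_ah=1.0, qpcr_de_targets=0,
                               qpcr_noise_sd=0.0, qpcr_clustered_pairs=0)
        ct, _ = simulate_ct_table(cfg)
        rel = ddct(ct, "healthy")
        assert np.allclose(rel["rel_expr"], 1.0)

    def test_planted_fold_propagates(self):
        """4-fold AH increase, noise SD 0.5 cycles: group mean relative
        expression lands in [3, 5.3]."""
        means = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, qpcr_fold_ah=4.0, qpcr_de_targets=1,
                                   qpcr_noise_sd=0.5, qpcr_clustered_pairs=0,
                                   n_ah=10, n_healthy=9)
            ct, truth = simulate_ct_table(cfg)
            rel = ddct(ct, "healthy")
            target = [t for t, f in truth.de_logfc.items() if f > 0][0]
            means.append(
                rel[(rel["group"] == "AH") & (rel["target"] == target)]["rel_expr"].mean()
            )
        assert 3.0 <= np.mean(means) <= 5.3

    def test_null_calibration(self):
        """Unit folds everywhere: ~5% of targets flagged across replicates."""
        from mircluster.qpcr import group_compare

        flags = []
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, qpcr_fold_ah=1.0, qpcr_de_targets=0,
                                   qpcr_noise_sd=0.5, qpcr_clustered_pairs=0,
                                   qpcr_targets=10)
            ct, _ = simulate_ct_table(cfg)
            out = group_compare(ddct(ct, "healthy"))
            flags.extend(out["significant"].tolist())
        rate = np.mean(flags)
        assert 0.02 <= rate <= 0.08

    def test_reference_constant_across_groups(self):
        ct, _ = simulate_ct_table(_small_cfg(7))
        assert ct["ct_reference"].nunique() == 1
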