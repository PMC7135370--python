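"""Synthetic-data generator: planted structure, truth bookkeeping, round-trips."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import io
from pleioscan.simulate import (SynthConfig, TruthSet, plant_sweep_sfs,
                                simulate_expression, simulate_genotypes,
                                write_fixture)


class TestGenotypes:
    def test_seed_determinism(self):
        cfg = SynthConfig(n_genes=40, sites_per_gene_mean=6, clinal_shift=0.1,
                          seed=5)
        a, _ = simulate_genotypes(cfg)
        b, _ = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.sites.equals(b.sites)

    def test_cluster_separation_on_pc1(self, default_cohort):
        from sklearn.metrics import silhouette_score
        from pleioscan.scan import genotype_pca
        _, gm, _, _ = default_cohort
        scores = genotype_pca(gm, K=2)["scores"]
        cluster = (gm.admixture[:, 0] > 0.5).astype(int)
        assert silhouette_score(scores[:, :1], cluster) > 0.5

    def test_no_cline_no_outlier_differentiation(self):
        """With clinal_shift=0, planted 'outliers' match background FST."""
        from scipy.stats import ranksums
        from pleioscan.diversity import pairwise_differentiation
        fsts_out, fsts_bg = [], []
        for seed in (0, 1, 2):
            cfg = SynthConfig(n_genes=200, sites_per_gene_mean=8,
                              clinal_shift=0.0, sweep_alpha=0.0,
                              frac_outlier_genes=0.1, seed=seed)
            gm, truth = simulate_genotypes(cfg)
            tab = pairwise_differentiation(gm, "P01", "P15").dropna()
            is_out = tab.index.isin(truth.outlier_genes)
            fsts_out.extend(tab["fst"][is_out])
            fsts_bg.extend(tab["fst"][~is_out])
        assert ranksums(fsts_out, fsts_bg).pvalue > 0.01

    def test_cline_raises_outlier_differentiation(self, default_cohort):
        from scipy.stats import ranksums
        from pleioscan.diversity import pairwise_differentiation
        _, gm, _, truth = default_cohort
        tab = pairwise_differentiation(gm, "P01", "P15").dropna()
        is_out = tab.index.isin(truth.outlier_genes)
        assert ranksums(tab["fst"][is_out], tab["fst"][~is_out]).pvalue < 0.01
        assert np.median(tab["fst"][is_out]) > np.median(tab["fst"][~is_out])

    def test_admixture_simplex(self, default_cohort):
        _, gm, _, _ = default_cohort
        assert np.allclose(gm.admixture.sum(axis=1), 1.0, atol=1e-9)

    def test_truth_consistency(self, default_cohort):
        _, gm, _, truth = default_cohort
        assert truth.sweep_genes <= truth.outlier_genes
        genes = set(gm.sites["gene"])
        assert truth.outlier_genes <= genes


class TestPlantSweep:
    def test_alpha_zero_identity(self, null_cohort):
        _, gm, truth = null_cohort
        out = plant_sweep_sfs(gm, {"g00001"}, 0.0)
        assert out is gm

    def test_negative_alpha_rejected(self, null_cohort):
        _, gm, _ = null_cohort
        with pytest.raises(ValueError):
            plant_sweep_sfs(gm, {"g00001"}, -1.0)

    def test_unknown_gene_rejected(self, null_cohort):
        _, gm, _ = null_cohort
        with pytest.raises(ValueError, match="unknown"):
            plant_sweep_sfs(gm, {"nope"}, 1.0)

    def test_distortion_direction(self, null_cohort):
        """Planted genes get negative H and reduced diversity."""
        from pleioscan.diversity import gene_diversity_table
        _, gm, _ = null_cohort
        genes = set(pd.unique(gm.sites["gene"])[:30])
        planted = plant_sweep_sfs(gm, genes, alpha=5.0,
                                  rng=np.random.default_rng(1))
        tab = gene_diversity_table(planted).dropna(subset=["fay_wu_h"])
        inpl = tab.index.isin(genes)
        assert np.mean(tab["fay_wu_h"][inpl]) < 0
        assert np.median(tab["fay_wu_h"][inpl]) < np.median(tab["fay_wu_h"][~inpl])
        assert np.median(tab["theta_pi"][inpl]) < np.median(tab["theta_pi"][~inpl])


class TestExpression:
    def test_seed_determinism(self):
        cfg = SynthConfig(n_genes=30, sites_per_gene_mean=5, seed=9)
        gm, truth = simulate_genotypes(cfg)
        e1, _ = simulate_expression(cfg, gm, truth)
        gm2, truth2 = simulate_genotypes(cfg)
        e2, _ = simulate_expression(cfg, gm2, truth2)
        assert np.array_equal(e1.to_numpy(), e2.to_numpy())

    def test_noise_free_single_module_all_hubs(self):
        cfg = SynthConfig(n_genes=20, sites_per_gene_mean=5, n_modules=1,
                          hub_fraction=1.0, noise_sd=1e-12, ns_loading=0.0,
                          frac_eqtl_outliers=0.0, frac_eqtl_background=0.0,
                          seed=3)
        gm, truth = simulate_genotypes(cfg)
        em, _ = simulate_expression(cfg, gm, truth)
        c = np.corrcoef(em.to_numpy())
        assert np.abs(c).min() > 0.999

    def test_planted_eqtl_slope_recovered(self):
        cfg = SynthConfig(n_genes=40, sites_per_gene_mean=6, noise_sd=0.1,
                          eqtl_effect=2.0, frac_eqtl_background=0.3,
                          frac_eqtl_outliers=0.3, clinal_shift=0.0,
                          ns_loading=0.0, base_loading=0.2, seed=21)
        gm, truth = simulate_genotypes(cfg)
        em, truth = simulate_expression(cfg, gm, truth)
        assert truth.eqtl_pairs
        src, tgt, eff = truth.eqtl_pairs[0]
        snp_cols = np.flatnonzero(gm.sites["gene"].to_numpy() == src)
        y = em.loc[tgt].to_numpy()
        slopes = []
        for j in snp_cols:
            x = gm.dosages[:, j].astype(float)
            if x.std() > 0:
                slopes.append(np.polyfit(x, y, 1)[0])
        # the causal SNP is one of the gene's SNPs; best slope matches
        assert min(abs(s - eff) for s in slopes) < 0.15


class TestFixtureIo:
    def test_round_trip(self, tmp_path, null_cohort):
        cfg, gm, truth = null_cohort
        em, truth = simulate_expression(cfg, gm, truth)
        paths = write_fixture(tmp_path / "fx", gm, em, truth)
        meta = io.read_sample_meta(paths["samples"])
        back = io.read_vcf(paths["vcf"], sample_meta=meta)
        assert np.array_equal(back.dosages, gm.dosages)
        assert np.allclose(back.admixture, gm.admixture, atol=1e-9)
        em_back = io.read_expression(paths["expression"])
        assert np.allclose(em_back.to_numpy(), em.to_numpy(), atol=1e-9)
        truth_back = TruthSet.from_json(paths["truth"])
        assert truth_back.outlier_genes == truth.outlier_genes
        assert truth_back.hub_genes == truth.hub_genes
        assert truth_back.module_assignment == truth.module_assignment

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            TruthSet(outlier_genes={"a"}, sweep_genes={"a", "b"})
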