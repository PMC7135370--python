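"""Selection scans: PCA, calibration, q-values, gene aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from pleioscan import scan
from pleioscan.simulate import SynthConfig, simulate_genotypes
from conftest import make_gm


class TestPca:
    def test_two_cluster_separation(self, default_cohort):
        _, gm, _, _ = default_cohort
        pca = scan.genotype_pca(gm, K=2)
        south = (gm.admixture[:, 0] > 0.5).astype(float)
        r = np.corrcoef(pca["scores"][:, 0], south)[0, 1]
        assert abs(r) > 0.9

    def test_scores_orthogonal(self, default_cohort):
        _, gm, _, _ = default_cohort
        u = scan.genotype_pca(gm, K=4)["scores"]
        gram = u.T @ u
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_duplicate_snps_pruned(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(30, 40))
        dd = np.repeat(d, 2, axis=1)  # every SNP duplicated adjacently
        gm = make_gm(dd, genes=[f"g{i}" for i in range(80)])
        kept = scan.ld_prune(gm, r2_max=0.99, window=10)
        assert len(kept) == 40

    def test_bad_k(self, default_cohort):
        _, gm, _, _ = default_cohort
        with pytest.raises(ValueError):
            scan.genotype_pca(gm, K=0)


class TestPcadaptScan:
    def test_null_calibration(self):
        ps = []
        lams = []
        for seed in (0, 1, 2):
            # exchangeable null: no clusters, no drift, no planted signal
            cfg = SynthConfig(n_genes=150, sites_per_gene_mean=10,
                              clinal_shift=0.0, sweep_alpha=0.0,
                              fst_between_clusters=0.0, ibd_slope=0.0,
                              n_clusters=1, seed=seed)
            gm, _ = simulate_genotypes(cfg)
            res = scan.pcadapt_scan(gm, K=2)
            ps.append(res.snps["p"].to_numpy())
            lams.append(res.lam)
        pooled = np.concatenate(ps)
        assert kstest(pooled, "uniform").pvalue > 0.01
        assert all(0.8 < l < 1.2 for l in lams)

    def test_planted_perfect_association_top_ranked(self, default_cohort):
        _, gm, _, _ = default_cohort
        pca = scan.genotype_pca(gm, K=2)
        snp = (pca["scores"][:, 0] > np.median(pca["scores"][:, 0])).astype(int) * 2
        import pandas as pd
        d = np.column_stack([gm.dosages, snp])
        sites = pd.concat([gm.sites, gm.sites.iloc[[-1]].assign(gene="gPLANT")],
                          ignore_index=True)
        gm2 = type(gm)(d, sites, gm.samples, admixture=gm.admixture)
        res = scan.pcadapt_scan(gm2, K=2)
        assert res.snps["stat"].idxmax() == len(res.snps) - 1

    def test_allele_flip_invariance(self, default_cohort):
        _, gm, _, _ = default_cohort
        res1 = scan.pcadapt_scan(gm, K=2)
        import dataclasses
        flipped = dataclasses.replace(gm, dosages=(2 - gm.dosages).astype(np.int8),
                                      sites=gm.sites, samples=gm.samples)
        # restore missing sentinel
        flipped.dosages[gm.dosages == -1] = -1
        res2 = scan.pcadapt_scan(flipped, K=2)
        assert np.allclose(res1.snps["stat"], res2.snps["stat"], atol=1e-6)


class TestEnvScan:
    def test_noise_axis_uniform_p(self, null_cohort):
        from pleioscan.io import FilterSpec, apply_filters
        _, gm, _ = null_cohort
        filt, _ = apply_filters(gm, FilterSpec())  # scans use MAF-filtered SNPs
        rng = np.random.default_rng(3)
        env = rng.normal(size=(filt.n_individuals, 1))
        res = scan.env_association_scan(filt, env, K_latent=2)
        assert kstest(res.snps["p"], "uniform").pvalue > 0.01

    def test_constant_axis_rejected(self, null_cohort):
        _, gm, _ = null_cohort
        with pytest.raises(ValueError, match="constant"):
            scan.env_association_scan(gm, np.ones((gm.n_individuals, 1)), 2)

    def test_collinear_axis_loses_power(self, default_cohort):
        """An env axis absorbed by the latent factors loses planted signal."""
        from sklearn.metrics import roc_auc_score
        _, gm, _, truth = default_cohort
        lat = gm.samples["lat"].to_numpy()
        lat_z = (lat - lat.mean()) / lat.std()

        def auc(env, K):
            res = scan.env_association_scan(gm, env[:, None], K_latent=K)
            g = res.snps.groupby("gene")["p"].min()
            y = g.index.isin(truth.outlier_genes)
            return roc_auc_score(y, -np.log10(g.to_numpy() + 1e-300))

        # K=2 latent factors absorb the latitudinal cline itself
        assert auc(lat_z, 2) <= auc(lat_z, 1) + 0.05


class TestQvalues:
    def test_identical_ps_identical_qs(self):
        q = scan.qvalues(np.full(50, 0.02))
        assert np.allclose(q, q[0])

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(0)
        p = rng.random(10_000)
        q = scan.qvalues(p)
        # q ~= pi0 * BH; at the largest p, q ~= pi0
        assert 0.9 < q.max() <= 1.0

    def test_matches_bh_when_pi0_is_one(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.random(20)  # m < 100 -> pi0 fixed at 1 -> q == BH
        q = scan.qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        q = scan.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scan.qvalues(np.array([]))


class TestGeneOutliers:
    def _fake_scan(self, genes, qs, method):
        snps = pd.DataFrame({"gene": genes, "pos": np.arange(len(genes)),
                             "stat": 1.0, "p": qs, "q": qs, "axis": 1})
        return scan.ScanResult(method=method, snps=snps, K=2, lam=1.0)

    def test_threshold_calls(self):
        res = self._fake_scan(["g1", "g2"], [0.04, 0.5], "diff")
        out = scan.gene_outliers([res])
        assert bool(out.loc["g1", "outlier_diff"]) is True
        assert bool(out.loc["g2", "outlier_diff"]) is False

    def test_overlap_fisher(self):
        genes = [f"g{i}" for i in range(100)]
        qs = np.where(np.arange(100) < 20, 0.01, 0.5)
        a = self._fake_scan(genes, qs, "diff")
        b = self._fake_scan(genes, qs, "env")
        out = scan.gene_outliers([a, b])
        assert out.attrs["overlap_odds_ratio"] > 1
        assert out.attrs["overlap_p"] < 0.01


class TestSControlledRegression:
    def test_response_equals_minus_s(self):
        rng = np.random.default_rng(0)
        S = rng.integers(1, 50, 30).astype(float)
        out = scan.s_controlled_regression(-S, S, rng.integers(0, 2, 30))
        assert out.loc["S", "beta"] < 0
        assert out.attrs["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        y = np.array([0.2, 0.5, 0.9, 0.1, 0.7, 0.3])
        S = np.array([3, 8, 12, 2, 9, 5], dtype=float)
        flag = np.array([0, 1, 1, 0, 1, 0], dtype=float)
        ys = (y - y.mean()) / y.std()
        X = np.column_stack([np.ones(6), S, flag])
        beta = np.linalg.solve(X.T @ X, X.T @ ys)
        out = scan.s_controlled_regression(y, S, flag)
        assert np.allclose(out["beta"].to_numpy(), beta, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            scan.s_controlled_regression(np.ones(5), np.arange(5), np.zeros(5))
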