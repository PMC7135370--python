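"""Trans-eQTL mapping between SNP genotypes and gene expression.

All SNP x gene pairs are tested (transcript SNPs have no positional
cis/trans split, so a SNP may be tested against its own host gene;
``drop_self_pairs`` turns that off).  Population structure is handled
twice, as in standard practice for transcriptome panels: the first
expression PCs are regressed out of expression beforehand, and
admixture proportions enter each association model as covariates.

The mapping streams SNP blocks through a precomputed covariate
projection, so the algebra is exact ordinary least squares at
O(SNPs x genes) memory for the p-values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .io import MISSING, GenotypeMatrix
from .scan import qvalues


@dataclass
class EqtlResult:
    """Significant associations and per-gene eQTL/eGene classification."""

    associations: pd.DataFrame  # snp_idx, snp_gene, target_gene, beta, t, p, q
    gene_flags: pd.DataFrame    # is_eqtl, is_egene, is_both, n_targets
    n_tests: int
    n_skipped_snps: int
    q_threshold: float


def correct_expression(em: pd.DataFrame, n_pcs: int = 2) -> pd.DataFrame:
    """Remove the leading expression PCs (structure axes) by regression.

    PCA is taken over individuals (columns); each gene's expression is
    replaced by its residual after OLS on the first ``n_pcs`` scores.
    ``n_pcs=0`` returns the input unchanged.
    """
    if n_pcs == 0:
        return em.copy()
    n_ind = em.shape[1]
    if n_pcs >= n_ind:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    if n_ind < n_pcs + 2:
        raise ValueError("too few individuals for PC correction")
    x = em.to_numpy(float).T            # individuals x genes
    xc = x - x.mean(axis=0)             # per-gene centering
    u, _, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :n_pcs]               # orthonormal individual scores
    resid = xc - scores @ (scores.T @ xc)
    return pd.DataFrame(resid.T, index=em.index, columns=em.columns)


def expression_pc_scores(em: pd.DataFrame, n_pcs: int = 2) -> np.ndarray:
    """Leading individual-level PC scores of the expression matrix."""
    x = em.to_numpy(float).T
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def map_eqtl(gm: GenotypeMatrix, em: pd.DataFrame,
             covariates: np.ndarray | None = None,
             q_threshold: float = 0.05,
             drop_self_pairs: bool = False,
             block_size: int = 512) -> EqtlResult:
    """Associate every SNP with every gene's expression.

    Per pair: expression ~ dosage + covariates (OLS); two-sided t test
    on the dosage term; Storey q over the pooled test set.  Genes
    carrying a significant SNP are eQTLs (sources); genes whose
    expression is hit are eGenes (targets).

    ``covariates`` defaults to ``gm.admixture`` with one simplex column
    dropped.  Monomorphic SNPs are skipped and counted.
    """
    if covariates is None:
        if gm.admixture is not None:
            covariates = gm.admixture[:, :-1]  # drop simplex redundancy
        else:
            covariates = np.empty((gm.n_individuals, 0))
    covariates = np.asarray(covariates, dtype=float)
    n = gm.n_individuals
    if em.shape[1] != n:
        raise ValueError("expression columns must match genotype individuals")

    x = gm.dosages.astype(float)
    x[x == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    ij = np.where(np.isnan(x))
    x[ij] = mu[ij[1]]
    poly = x.std(axis=0) > 0
    snp_idx_all = np.flatnonzero(poly)
    n_skipped = int((~poly).sum())

    covs = np.column_stack([np.ones(n), covariates])
    qc, _ = np.linalg.qr(covs)
    e = em.to_numpy(float).T                     # individuals x genes
    er = e - qc @ (qc.T @ e)
    er_ss = (er ** 2).sum(axis=0)
    dof = n - covs.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough individuals for the covariate model")

    genes = np.asarray(em.index)
    snp_genes = gm.sites["gene"].to_numpy()
    gene_to_row = {g: i for i, g in enumerate(genes)}

    t_chunks, pair_rows = [], []
    for start in range(0, len(snp_idx_all), block_size):
        blk = snp_idx_all[start:start + block_size]
        xb = x[:, blk]
        xb = xb - qc @ (qc.T @ xb)
        xb_ss = (xb ** 2).sum(axis=0)
        num = xb.T @ er                          # (block, genes)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(np.outer(xb_ss, er_ss))
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
            tt = r * np.sqrt(dof / (1 - r ** 2))
            beta = np.where(xb_ss[:, None] > 0, num / np.where(
                xb_ss[:, None] > 0, xb_ss[:, None], 1.0), 0.0)
        if drop_self_pairs:
            for bi, j in enumerate(blk):
                row = gene_to_row.get(snp_genes[j])
                if row is not None:
                    tt[bi, row] = 0.0
        t_chunks.append(tt.astype(np.float32))
        pair_rows.append((blk, beta.astype(np.float32)))

    tmat = np.concatenate(t_chunks, axis=0)
    p = 2.0 * t_dist.sf(np.abs(tmat.astype(float)), dof)
    q = qvalues(p.ravel()).reshape(p.shape)
    n_tests = p.size

    sig = np.argwhere(q < q_threshold)
    assoc_rows = []
    beta_all = np.concatenate([b for _, b in pair_rows], axis=0)
    for si, gi in sig:
        j = snp_idx_all[si]
        assoc_rows.append((j, snp_genes[j], genes[gi],
                           float(beta_all[si, gi]), float(tmat[si, gi]),
                           float(p[si, gi]), float(q[si, gi])))
    associations = pd.DataFrame(
        assoc_rows, columns=["snp_idx", "snp_gene", "target_gene",
                             "beta", "t", "p", "q"])

    universe = pd.Index(np.unique(np.concatenate([genes, snp_genes])))
    flags = pd.DataFrame(index=universe)
    eqtl_targets = associations.groupby("snp_gene")["target_gene"].nunique()
    flags["is_eqtl"] = flags.index.isin(eqtl_targets.index)
    flags["is_egene"] = flags.index.isin(associations["target_gene"])
    flags["is_both"] = flags["is_eqtl"] & flags["is_egene"]
    flags["n_targets"] = eqtl_targets.reindex(universe).fillna(0).astype(int)
    return EqtlResult(associations=associations, gene_flags=flags,
                      n_tests=int(n_tests), n_skipped_snps=n_skipped,
                      q_threshold=q_threshold)


def egene_count_model(result: EqtlResult, S: pd.Series,
                      outlier: pd.Series) -> pd.DataFrame:
    """Logistic model of multi-target eQTLs on outlier status.

    Restricted to eQTL genes; response is 1 when an eQTL hits more than
    one eGene.  S (segregating sites) enters as a covariate.  Complete
    separation falls back to an L2-penalized fit, flagged in
    ``attrs['penalized']``.
    """
    flags = result.gene_flags
    sub = flags[flags["is_eqtl"]]
    if len(sub) < 10:
        raise ValueError("need at least 10 eQTL genes")
    y = (sub["n_targets"] > 1).astype(float)
    X = pd.DataFrame({
        "S": S.reindex(sub.index).fillna(0).astype(float),
        "outlier": outlier.reindex(sub.index).fillna(False).astype(float),
    }, index=sub.index)
    return fit_logistic(y, X)


def fit_logistic(y, X) -> pd.DataFrame:
    """Logistic GLM with Wald 95% CIs and a penalized fallback on
    separation; coefficient table indexed by predictor."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X)
    penalized = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(np.asarray(y, float), Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
            raise ValueError("separation suspected")
    except Exception:
        penalized = True
        fit = sm.Logit(np.asarray(y, float), Xc).fit_regularized(
            disp=0, alpha=1.0, L1_wt=0.0, maxiter=500)
    params = pd.Series(np.asarray(fit.params).ravel(), index=Xc.columns)
    if penalized and (not hasattr(fit, "bse") or
                      not np.all(np.isfinite(np.asarray(fit.bse, float)))):
        se = pd.Series(np.nan, index=Xc.columns)
        pv = pd.Series(np.nan, index=Xc.columns)
    else:
        se = pd.Series(np.asarray(fit.bse).ravel(), index=Xc.columns)
        pv = pd.Series(np.asarray(fit.pvalues).ravel(), index=Xc.columns)
    out = pd.DataFrame({
        "beta": params, "se": se,
        "ci_lo": params - 1.96 * se, "ci_hi": params + 1.96 * se, "p": pv,
    })
    out.attrs["penalized"] = penalized
    return out
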