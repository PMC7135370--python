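"""Per-gene diversity, neutrality, and differentiation statistics.

Genes (transcript contigs) are the unit of analysis; there are no
sliding windows.  All theta estimates are per-site, dividing by the
gene's span = number of genotyped sites assigned to it, so values are
comparable within a run.  Missing genotypes are dropped pairwise: every
per-site quantity uses that site's own haploid sample size
n = 2 x non-missing individuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i^power (Watterson/Tajima constants)."""
    i = np.arange(1, n)
    return float((1.0 / i ** power).sum())


def theta_pi(counts: np.ndarray, n_per_site: np.ndarray, span: float) -> float:
    """Average pairwise diversity per site.

    ``counts`` are per-site minor/derived allele counts with
    corresponding haploid sizes ``n_per_site``; each site contributes
    2 i (n - i) / (n (n - 1)), the heterozygosity of a sample without
    replacement.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    counts = np.asarray(counts, dtype=float)
    n = np.asarray(n_per_site, dtype=float)
    if len(counts) == 0:
        return 0.0
    if np.any((counts <= 0) | (counts >= n)):
        raise ValueError("counts must be polymorphic: 0 < i < n")
    return float((2.0 * counts * (n - counts) / (n * (n - 1.0))).sum() / span)


def theta_w(S: int, n: int, span: float) -> float:
    """Watterson's estimator per site: (S / a1) / span."""
    if span <= 0:
        raise ValueError("span must be positive")
    if S == 0:
        return 0.0
    if n < 2:
        raise ValueError("need haploid sample size >= 2")
    return float(S / harmonic(n) / span)


def tajimas_d(counts: np.ndarray, n: int) -> float:
    """Tajima's D from per-site allele counts at common haploid size n.

    Standard 1989 variance constants; undefined (NaN) when S = 0.
    """
    counts = np.asarray(counts, dtype=float)
    S = len(counts)
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    pi_total = (2.0 * counts * (n - counts) / (n * (n - 1.0))).sum()
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))


def fay_wu_h_normalized(derived_counts: np.ndarray, n: int) -> float:
    """Normalized Fay & Wu's H from unfolded (polarized) counts.

    H contrasts pairwise diversity with theta_L = (1/(n-1)) sum_i i, an
    estimator weighted toward high-frequency derived variants; negative
    values indicate the derived-allele excess left by hitchhiking.  The
    variance uses theta_W and the unbiased theta^2 estimator
    S(S-1)/(a1^2 + b_n), following the standard normalization of the
    statistic.
    """
    i = np.asarray(derived_counts, dtype=float)
    S = len(i)
    if S == 0:
        raise ValueError("need at least one polarized segregating site")
    if np.any((i <= 0) | (i >= n)):
        raise ValueError("derived counts must satisfy 0 < i < n")
    a1 = harmonic(n)
    bn = harmonic(n, 2)
    bn1 = bn + 1.0 / n ** 2  # sum_{i=1}^{n} 1/i^2
    pi_total = (2.0 * i * (n - i) / (n * (n - 1.0))).sum()
    theta_l = i.sum() / (n - 1.0)
    theta_hat = S / a1
    theta_sq_hat = S * (S - 1.0) / (a1 ** 2 + bn)
    var = ((n - 2.0) / (6.0 * (n - 1.0))) * theta_hat + (
        (18.0 * n ** 2 * (3.0 * n + 2.0) * bn1
         - (88.0 * n ** 3 + 9.0 * n ** 2 - 13.0 * n + 6.0))
        / (9.0 * n * (n - 1.0) ** 2)
    ) * theta_sq_hat
    if var <= 0:
        return float("nan")
    return float((pi_total - theta_l) / np.sqrt(var))


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int):
    """Hudson-style FST with ratio-of-averages aggregation.

    Per-site numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    and denominator p1(1-p2) + p2(1-p1); sites fixed for the same
    allele in both populations are excluded.  Returns (fst, num, den)
    so callers can pool across genes as a ratio of sums.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two haploid samples per population")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    keep = ~((p1 == p2) & ((p1 == 0) | (p1 == 1)))
    p1, p2 = p1[keep], p2[keep]
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1.0)
           - p2 * (1 - p2) / (n2 - 1.0)).sum()
    den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
    fst = float(num / den) if den > 0 else float("nan")
    return fst, float(num), float(den)


def dxy(p1: np.ndarray, p2: np.ndarray, span: float) -> float:
    """Absolute divergence per site: sum[p1(1-p2) + p2(1-p1)] / span."""
    if span <= 0:
        raise ValueError("span must be positive")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float((p1 * (1 - p2) + p2 * (1 - p1)).sum() / span)


# ---------------------------------------------------------------------
# Per-gene tables
# ---------------------------------------------------------------------

def _pop_freqs(gm: GenotypeMatrix, pop_mask: np.ndarray, cols: np.ndarray):
    d = gm.dosages[np.ix_(pop_mask, cols)].astype(np.int64)
    called = d != MISSING
    n = 2 * called.sum(axis=0)
    ac = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / np.maximum(n, 1), np.nan)
    return p, n


def gene_diversity_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-gene S, theta_pi, theta_w, Tajima's D, and normalized H.

    Span is the number of genotyped sites assigned to the gene.  D and
    H use complete-case sites at the common n = 2 x individuals; H is
    NaN for genes without polarized sites.
    """
    genes = gm.sites["gene"].to_numpy()
    d = gm.dosages.astype(np.int64)
    called = d != MISSING
    n_site = 2 * called.sum(axis=0)
    ac = np.where(called, d, 0).sum(axis=0)
    poly = (ac > 0) & (ac < n_site)
    complete = called.all(axis=0)
    known = gm.sites["ancestral"].isin(["ref", "alt"]).to_numpy()
    der = gm.derived_dosages().astype(np.int64)
    der_count = np.where(der != MISSING, der, 0).sum(axis=0)
    n_full = 2 * gm.n_individuals

    rows = []
    for gene, cols in pd.Series(np.arange(gm.n_sites)).groupby(genes):
        cols = cols.to_numpy()
        span = float(len(cols))
        pcols = cols[poly[cols]]
        S = len(pcols)
        if S == 0:
            rows.append((gene, 0, 0.0, 0.0, np.nan, np.nan, span))
            continue
        tp = theta_pi(ac[pcols], n_site[pcols], span)
        tw = theta_w(S, int(np.round(n_site[pcols].mean())), span)
        ccols = pcols[complete[pcols]]
        td = tajimas_d(ac[ccols], n_full) if len(ccols) else np.nan
        hcols = ccols[known[ccols]]
        hcols = hcols[(der_count[hcols] > 0) & (der_count[hcols] < n_full)]
        h = fay_wu_h_normalized(der_count[hcols], n_full) if len(hcols) else np.nan
        rows.append((gene, S, tp, tw, td, h, span))
    return pd.DataFrame(
        rows, columns=["gene", "S", "theta_pi", "theta_w", "tajima_d",
                       "fay_wu_h", "span"]).set_index("gene")


def pairwise_differentiation(gm: GenotypeMatrix, pop1: str, pop2: str) -> pd.DataFrame:
    """Per-gene Hudson FST and dXY between two populations, plus the
    genome-wide ratio-of-sums FST in ``DataFrame.attrs['fst_genome']``."""
    pops = gm.samples["population"].to_numpy()
    m1, m2 = pops == pop1, pops == pop2
    if m1.sum() < 1 or m2.sum() < 1:
        raise ValueError(f"populations {pop1!r}/{pop2!r} not found")
    genes = gm.sites["gene"].to_numpy()
    rows, tot_num, tot_den = [], 0.0, 0.0
    for gene, cols in pd.Series(np.arange(gm.n_sites)).groupby(genes):
        cols = cols.to_numpy()
        p1, n1 = _pop_freqs(gm, m1, cols)
        p2, n2 = _pop_freqs(gm, m2, cols)
        ok = ~np.isnan(p1) & ~np.isnan(p2)
        span = float(len(cols))
        if not ok.any():
            rows.append((gene, np.nan, np.nan))
            continue
        fst, num, den = hudson_fst(p1[ok], p2[ok],
                                   int(np.median(n1[ok])), int(np.median(n2[ok])))
        rows.append((gene, fst, dxy(p1[ok], p2[ok], span)))
        tot_num += num
        tot_den += den
    out = pd.DataFrame(rows, columns=["gene", "fst", "dxy"]).set_index("gene")
    out.attrs["fst_genome"] = tot_num / tot_den if tot_den > 0 else float("nan")
    return out
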