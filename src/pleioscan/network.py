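"""Signed weighted co-expression network and module detection.

Adjacency follows the signed WGCNA convention,
a_ij = ((1 + cor(x_i, x_j)) / 2)^beta with soft power beta = 6, so
anticorrelated genes get adjacency near 0 rather than near 1.
Connectivity k_i is the sum of a gene's adjacencies to all other
genes — the package's proxy for pleiotropy.  Modules are detected by
average-linkage clustering of the topological overlap dissimilarity
with a static height cut (a deliberate simplification of dynamic tree
cutting: downstream statistics consume only module membership and
connectivity, and connectivity does not depend on the cut).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from .scan import qvalues


def signed_adjacency(em: pd.DataFrame, power: int = 6) -> np.ndarray:
    """Signed soft-thresholded adjacency from Pearson correlations.

    Zero-variance genes get correlation 0 with everything (adjacency
    (1/2)^power) and a warning.  Diagonal is 0 so row sums are
    connectivities.
    """
    if em.shape[1] < 3:
        raise ValueError("need at least 3 individuals")
    x = em.to_numpy(float)
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance genes: correlations "
                      "set to 0", stacklevel=2)
    xs = (x - x.mean(axis=1, keepdims=True))
    norm = np.where(dead, 1.0, np.sqrt((xs ** 2).sum(axis=1)))
    xs = xs / norm[:, None]
    c = xs @ xs.T
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.clip(c, -1.0, 1.0, out=c)
    a = ((1.0 + c) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Per-gene connectivity: sum of adjacencies to all other genes."""
    a = np.asarray(adjacency, dtype=float)
    return a.sum(axis=1) - np.diag(a)


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbourhood similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: np.ndarray, min_size: int = 30,
                   cut_quantile: float = 0.97) -> np.ndarray:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    The tree is cut at the ``cut_quantile`` quantile of its merge
    heights; clusters smaller than ``min_size`` become label 0
    (unassigned).  Surviving modules are renumbered 1..M by decreasing
    size.
    """
    tom = np.asarray(tom, dtype=float)
    g = tom.shape[0]
    if min_size > g:
        return np.zeros(g, dtype=int)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    heights = link[:, 2]
    cut = np.quantile(heights, cut_quantile)
    raw = fcluster(link, t=cut, criterion="distance")
    labels = np.zeros(g, dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].index
    for new, old in enumerate(sorted(keep, key=lambda c: -sizes[c]), start=1):
        labels[raw == old] = new
    return labels


def module_enrichment(labels: np.ndarray, outlier: np.ndarray) -> pd.DataFrame:
    """Per-module Fisher exact test for outlier over-representation.

    Unassigned genes (label 0) form part of the background but are not
    tested as a module.  q-values are computed across modules.
    """
    labels = np.asarray(labels)
    outlier = np.asarray(outlier, dtype=bool)
    mods = sorted(m for m in np.unique(labels) if m != 0)
    if len(mods) < 2:
        raise ValueError("need at least 2 modules")
    rows = []
    for m in mods:
        inm = labels == m
        table = [[int((inm & outlier).sum()), int((inm & ~outlier).sum())],
                 [int((~inm & outlier).sum()), int((~inm & ~outlier).sum())]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append((m, int(inm.sum()), int((inm & outlier).sum()),
                     float(odds), float(p)))
    out = pd.DataFrame(rows, columns=["module", "n_genes", "n_outliers",
                                      "odds_ratio", "p"]).set_index("module")
    out["q"] = qvalues(out["p"].to_numpy())
    return out
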