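"""Composite likelihood ratio test for recent selective sweeps.

Implements a SweepFinder-style scan at the gene level: the dataset-wide
unfolded SFS is the neutral (background) allele-frequency distribution,
and each gene is tested for a sweep centred at each of its variable
sites.  During a sweep, a sampled lineage at distance d from the swept
site escapes (recombines onto a non-sweeping background) with
probability

    p_escape(d) = 1 - exp(-d / alpha)

where ``alpha`` (bp) is the sweep's intensity/footprint scale: as
alpha -> 0 every lineage escapes and the model collapses to the
background; larger alpha distorts the spectrum over a wider region.
Lineages that fail to escape coalesce into the single hitchhiking
lineage, so the post-sweep spectrum is the background spectrum
subsampled to the escaped lineages plus one, conditioned on the site
remaining polymorphic.  CLR = 2 (max log composite likelihood under the
sweep model - background log likelihood), maximized over the alpha grid
and candidate positions, with the background limit included so the
statistic is never negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, hypergeom

from .io import MISSING, SFS, GenotypeMatrix, unfolded_sfs

_PE_BINS = 201  # escape-probability discretization for the class-prob table


@dataclass
class ClrModel:
    """Background spectrum plus the alpha grid and lookup tables.

    ``pe_floor`` is the minimum escape probability, allowing soft or
    incomplete sweeps: even at the swept site itself a small fraction
    of lineages may carry non-hitchhiking backgrounds (or mutate after
    the sweep), so observed frequencies near — but not at — fixation do
    not categorically reject a sweep centred there.
    """

    background: SFS
    alpha_grid: np.ndarray | None = None
    pe_floor: float = 0.05
    _table: np.ndarray = field(init=False, repr=False, default=None)
    _pe_grid: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.background.normalized:
            self.background = self.background.normalize()
        if self.alpha_grid is not None:
            self.alpha_grid = np.sort(np.asarray(self.alpha_grid, dtype=float))
            if (self.alpha_grid <= 0).any():
                raise ValueError("alpha grid must be positive")
        self._pe_grid = np.linspace(1e-6, 1.0, _PE_BINS)
        q = self.background.counts
        n = self.background.n
        emat = _escape_class_probs(q, n)  # (n+1, n-1)
        w = binom.pmf(np.arange(n + 1)[None, :], n, self._pe_grid[:, None])
        tab = w @ emat  # (bins, n-1)
        tab /= tab.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            self._table = np.log(tab)

    def log_class_probs(self, pe: np.ndarray) -> np.ndarray:
        """Log P(derived count j | escape prob) via the binned table."""
        idx = np.clip(np.searchsorted(self._pe_grid, pe), 0, _PE_BINS - 1)
        return self._table[idx]


def _escape_class_probs(q: np.ndarray, n: int) -> np.ndarray:
    """P(observed derived count j | e lineages escaped), rows e=0..n.

    Given e escapes, e+1 lineages are drawn from the background
    spectrum (the e escapees plus the single hitchhiking ancestor,
    which represents the remaining n-e sample copies).  Rows are
    unnormalized over the polymorphic classes 1..n-1; mass falling on
    the monomorphic classes is dropped (polymorphism conditioning
    happens at table construction).
    """
    classes = np.arange(1, n)
    out = np.zeros((n + 1, n - 1))
    out[n] = q  # everything escaped: background unchanged
    for e in range(n):
        m = e + 1
        k = np.arange(m + 1)
        # subsample the size-n spectrum down to m lineages
        sub = np.zeros(m + 1)
        for j, qj in zip(classes, q):
            if qj > 0:
                sub += qj * hypergeom.pmf(k, n, j, m)
        row = np.zeros(n + 1)
        p_hitch = k / m
        # hitchhiker derived: the n-e swept copies are all derived
        np.add.at(row, np.clip(k - 1 + (n - e), 0, n), sub * p_hitch)
        # hitchhiker ancestral: only the escaped derived copies remain
        np.add.at(row, k, sub * (1.0 - p_hitch))
        out[e] = row[1:n]
    return out


def background_sfs(gm: GenotypeMatrix) -> SFS:
    """Transcriptome-wide unfolded SFS used as the neutral distribution."""
    sfs = unfolded_sfs(gm)
    if sfs.counts.sum() < 100:
        warnings.warn("fewer than 100 polarized sites: background SFS "
                      "may be unstable", stacklevel=2)
    return sfs.normalize()


def default_alpha_grid(half_width: float, n_alpha: int = 20) -> np.ndarray:
    """Log-spaced alpha values so p_escape at the gene half-width spans
    (0.01, 0.99)."""
    if half_width <= 0:
        half_width = 1.0
    lo = -half_width / np.log(1.0 - 0.99)   # weak sweep: escape 0.99
    hi = -half_width / np.log(1.0 - 0.01)   # strong sweep: escape 0.01
    return np.geomspace(lo, hi, n_alpha)


def clr_gene(positions: np.ndarray, derived: np.ndarray, model: ClrModel) -> dict:
    """CLR for one gene over a grid of candidate sweep positions.

    ``positions`` are bp coordinates of the gene's polarized variable
    sites and ``derived`` their derived-allele counts (0 < j < n).  The
    candidate grid is the variable sites themselves; the candidate site
    itself is treated as the sweeping allele's own position (escape
    probability 1, i.e. its term equals the background term), which
    makes the background model exactly nested as alpha -> 0.  Ties in
    the argmax resolve toward smaller alpha (the most conservative
    sweep).
    """
    positions = np.asarray(positions, dtype=float)
    derived = np.asarray(derived, dtype=np.int64)
    n = model.background.n
    if len(positions) == 0:
        raise ValueError("need at least one polarized site")
    if np.any((derived <= 0) | (derived >= n)):
        raise ValueError("derived counts must satisfy 0 < j < n")
    alphas = model.alpha_grid
    if alphas is None:
        half = max((positions.max() - positions.min()) / 2.0, 1.0)
        alphas = default_alpha_grid(half)
    with np.errstate(divide="ignore"):
        log_q = np.log(model.background.counts)
    ll0 = float(log_q[derived - 1].sum())

    dist = np.abs(positions[:, None] - positions[None, :])  # (grid, sites)
    best = (ll0, 0.0, float(positions[0]))
    for a in alphas:  # ascending: first max kept -> smallest alpha wins ties
        pe = np.maximum(1.0 - np.exp(-dist / a), model.pe_floor)
        pe[dist == 0] = 1.0  # the candidate site is the swept site itself
        lp = model.log_class_probs(pe)  # (grid, sites, n-1)
        ll = lp[np.arange(dist.shape[0])[:, None],
                np.arange(dist.shape[1])[None, :], (derived - 1)[None, :]].sum(axis=1)
        g = int(np.argmax(ll))
        if ll[g] > best[0]:
            best = (float(ll[g]), float(a), float(positions[g]))
    return {"clr": 2.0 * (best[0] - ll0), "alpha_hat": best[1],
            "pos_hat": best[2], "loglik_background": ll0}


def clr_table(gm: GenotypeMatrix, model: ClrModel | None = None):
    """Per-gene CLR over all genes with polarized polymorphic sites."""
    import pandas as pd

    if model is None:
        model = ClrModel(background_sfs(gm))
    n = model.background.n
    known = gm.sites["ancestral"].isin(["ref", "alt"]).to_numpy()
    complete = gm.called_mask().all(axis=0)
    der = gm.derived_dosages().astype(np.int64)
    der_count = np.where(der != MISSING, der, 0).sum(axis=0)
    poly = (der_count > 0) & (der_count < n)
    use = known & complete & poly
    genes = gm.sites["gene"].to_numpy()
    pos = gm.sites["pos"].to_numpy(float)
    rows = []
    for gene in pd.unique(genes[use]):
        cols = np.flatnonzero(use & (genes == gene))
        res = clr_gene(pos[cols], der_count[cols], model)
        rows.append((gene, res["clr"], res["alpha_hat"], res["pos_hat"]))
    return pd.DataFrame(rows, columns=["gene", "clr", "alpha_hat",
                                       "pos_hat"]).set_index("gene")
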