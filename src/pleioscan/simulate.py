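"""Synthetic genotype and expression fixtures with planted truth.

The generator emulates the statistical structure the analysis assumes:
two ancestral clusters on a latitudinal admixture/isolation-by-distance
gradient, genes with variable numbers of segregating sites whose
derived-allele frequencies follow a truncated neutral (1/p) density, a
minority of adaptive genes with clinal frequency shifts and
sweep-distorted spectra, trans-eQTL effects concentrated in the
adaptive genes, and modular expression covariance with hub genes plus
a north-south latent factor (the structure removed by PC correction).

Every planted signal is recorded in a machine-readable
:class:`TruthSet` so downstream stages can be scored against ground
truth.  Genotype drift uses a hierarchical Balding-Nichols scheme
(Beta-distributed subpopulation frequencies), chosen over coalescent
simulation to stay analytically controllable; the neutral-SFS shape is
therefore approximate by design.  Read depth is simulated
independently of genotype (log-normal) so the coverage-genotype QC has
a true null.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SITE_COLUMNS, write_vcf, write_expression


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated sampling design: 15 populations of 5
    individuals across a 15-degree latitudinal transect, ~2000 genes
    with geometrically distributed segregating sites, two ancestral
    clusters at FST 0.05, 5% planted adaptive genes with a clinal
    allele-frequency shift, trans-eQTLs concentrated in adaptive genes,
    and 8 expression modules with hub genes.
    """

    n_pops: int = 15
    inds_per_pop: int = 5
    n_genes: int = 2000
    sites_per_gene_mean: float = 30.0
    n_clusters: int = 2
    fst_between_clusters: float = 0.05
    ibd_slope: float = 0.004          # Balding-Nichols F per degree latitude
    frac_outlier_genes: float = 0.05
    clinal_shift: float = 0.3         # frequency delta at the transect edges
    sweep_alpha: float = 3.0          # SFS distortion intensity
    frac_sweep_of_outliers: float = 0.5
    # trans-eQTL rates chosen so ~14% of genes are eQTLs overall and
    # adaptive genes carry them at the elevated (~30%) rate
    frac_eqtl_outliers: float = 0.30
    frac_eqtl_background: float = 0.12
    # default trans-effect explains ~30% of a target gene's variance
    eqtl_effect: float = 1.0
    eqtl_targets_outlier: int = 2
    eqtl_targets_background: int = 1
    n_modules: int = 8
    hub_fraction: float = 0.10
    # adaptive genes are preferentially hubs (their elevated network
    # centrality is the pattern the analysis is built to detect)
    outlier_hub_boost: float = 5.0
    hub_loading: float = 0.9
    base_loading: float = 0.45
    ns_loading: float = 0.6           # north-south latent factor loading
    noise_sd: float = 0.5
    freq_min: float = 0.02            # truncation of the 1/p neutral density
    frac_unpolarized: float = 0.05
    n_env_axes: int = 4
    depth_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_between_clusters", "frac_outlier_genes",
                     "frac_eqtl_outliers", "frac_eqtl_background",
                     "hub_fraction", "frac_unpolarized",
                     "frac_sweep_of_outliers"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_pops", "inds_per_pop", "n_genes", "n_clusters",
                     "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TruthSet:
    """Planted signals emitted by the generator."""

    outlier_genes: set = field(default_factory=set)
    sweep_genes: set = field(default_factory=set)
    eqtl_pairs: list = field(default_factory=list)  # (source, target, effect)
    hub_genes: set = field(default_factory=set)
    module_assignment: dict = field(default_factory=dict)
    env_pc_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.sweep_genes <= self.outlier_genes:
            raise ValueError("sweep genes must be a subset of outlier genes")

    def to_json(self, path) -> None:
        env = (None if self.env_pc_values is None
               else self.env_pc_values.reset_index().to_dict(orient="list"))
        payload = {
            "outlier_genes": sorted(self.outlier_genes),
            "sweep_genes": sorted(self.sweep_genes),
            "eqtl_pairs": [[s, t, float(e)] for s, t, e in self.eqtl_pairs],
            "hub_genes": sorted(self.hub_genes),
            "module_assignment": self.module_assignment,
            "env_pc_values": env,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        env = d.get("env_pc_values")
        env_df = None
        if env is not None:
            env_df = pd.DataFrame(env).set_index("population")
        return cls(outlier_genes=set(d["outlier_genes"]),
                   sweep_genes=set(d["sweep_genes"]),
                   eqtl_pairs=[tuple(x) for x in d["eqtl_pairs"]],
                   hub_genes=set(d["hub_genes"]),
                   module_assignment=d["module_assignment"],
                   env_pc_values=env_df)


# ---------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------

def _neutral_freqs(rng, size, fmin):
    """Derived-allele frequencies from the truncated 1/p density."""
    u = rng.random(size)
    return fmin * ((1.0 - fmin) / fmin) ** u


def simulate_genotypes(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Hierarchical Balding-Nichols genotypes with planted clines.

    Returns (GenotypeMatrix, TruthSet).  Global derived frequencies ->
    cluster frequencies (Beta drift at ``fst_between_clusters``) ->
    population frequencies (IBD Beta drift scaled by latitude distance
    to the population's admixture-weighted cluster centre), plus a
    monotone latitudinal cline of magnitude ``clinal_shift`` at planted
    outlier-gene sites.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_pops * cfg.inds_per_pop
    lats = np.linspace(30.0, 45.0, cfg.n_pops)
    lons = np.linspace(-95.0, -88.0, cfg.n_pops) + rng.normal(0, 0.5, cfg.n_pops)
    # admixture: smooth logistic gradient between the two end clusters
    centres = np.linspace(lats[0], lats[-1], cfg.n_clusters)
    scale = (lats[-1] - lats[0]) / 6.0
    w = np.exp(-((lats[:, None] - centres[None, :]) / scale) ** 2 / 2)
    q_pop = w / w.sum(axis=1, keepdims=True)          # (pops, clusters)

    sites_per_gene = np.maximum(
        rng.geometric(1.0 / cfg.sites_per_gene_mean, size=cfg.n_genes), 1)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    n_out = int(round(cfg.frac_outlier_genes * cfg.n_genes))
    outlier_idx = rng.choice(cfg.n_genes, size=n_out, replace=False)
    outliers = {genes[i] for i in outlier_idx}
    n_swp = int(round(cfg.frac_sweep_of_outliers * n_out))
    sweep = set(rng.choice(sorted(outliers), size=n_swp, replace=False)) \
        if n_out else set()

    total_sites = int(sites_per_gene.sum())
    gene_of_site = np.repeat(np.arange(cfg.n_genes), sites_per_gene)
    is_outlier_site = np.isin(gene_of_site, outlier_idx)

    p_glob = _neutral_freqs(rng, total_sites, cfg.freq_min)
    F = cfg.fst_between_clusters
    if F > 1e-9:
        a = p_glob * (1 - F) / F
        b = (1 - p_glob) * (1 - F) / F
        p_clust = rng.beta(a[:, None], b[:, None],
                           size=(total_sites, cfg.n_clusters))
    else:
        p_clust = np.repeat(p_glob[:, None], cfg.n_clusters, axis=1)

    lat_z = (lats - lats.mean()) / ((lats[-1] - lats[0]) / 2.0)
    n_clipped = 0
    dosage_der = np.empty((n_ind, total_sites), dtype=np.int8)
    for pi in range(cfg.n_pops):
        base = p_clust @ q_pop[pi]
        dist = np.abs(lats[pi] - (centres * q_pop[pi]).sum() / q_pop[pi].sum())
        Fp = min(max(cfg.ibd_slope * max(dist, 0.25), 1e-4), 0.5)
        ap = base * (1 - Fp) / Fp
        bp = (1 - base) * (1 - Fp) / Fp
        p_pop = rng.beta(np.maximum(ap, 1e-3), np.maximum(bp, 1e-3))
        if cfg.clinal_shift != 0.0:
            shifted = p_pop[is_outlier_site] + cfg.clinal_shift * lat_z[pi]
            n_clipped += int(((shifted < 0) | (shifted > 1)).sum())
            p_pop[is_outlier_site] = np.clip(shifted, 0.0, 1.0)
        rows = slice(pi * cfg.inds_per_pop, (pi + 1) * cfg.inds_per_pop)
        dosage_der[rows] = rng.binomial(2, p_pop,
                                        size=(cfg.inds_per_pop, total_sites))
    if n_clipped:
        warnings.warn(f"{n_clipped} population-site frequencies clipped to "
                      "[0, 1] by the planted cline", stacklevel=2)

    # allele labelling: half the sites have alt = derived, half ref = derived
    flip = rng.random(total_sites) < 0.5
    unpol = rng.random(total_sites) < cfg.frac_unpolarized
    dosages = np.where(flip[None, :], 2 - dosage_der, dosage_der).astype(np.int8)
    ancestral = np.where(unpol, "unknown", np.where(flip, "alt", "ref"))

    pos = np.concatenate([
        np.sort(rng.choice(np.arange(1, max(2000, 4 * s)), size=s,
                           replace=False))
        for s in sites_per_gene])
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, total_sites)]
    alt_off = rng.integers(1, 4, total_sites)
    alt = bases[(np.searchsorted(bases, ref) + alt_off) % 4]
    sites = pd.DataFrame({
        "gene": np.asarray(genes)[gene_of_site], "pos": pos,
        "ref": ref, "alt": alt, "ancestral": ancestral,
        "qual": rng.uniform(50, 2000, total_sites).round(1),
    }, columns=SITE_COLUMNS)

    pop_names = [f"P{p + 1:02d}" for p in range(cfg.n_pops)]
    samples = pd.DataFrame({
        "sample": [f"{pop_names[p]}_i{i + 1}" for p in range(cfg.n_pops)
                   for i in range(cfg.inds_per_pop)],
        "population": np.repeat(pop_names, cfg.inds_per_pop),
        "lat": np.repeat(lats, cfg.inds_per_pop),
        "lon": np.repeat(lons, cfg.inds_per_pop),
    })
    admixture = np.repeat(q_pop, cfg.inds_per_pop, axis=0)

    depth = rng.lognormal(np.log(cfg.depth_mean), 0.4,
                          size=(n_ind, total_sites)).round(1)
    gq = np.clip(rng.normal(70, 15, size=(n_ind, total_sites)), 21, 99).round(0)

    gm = GenotypeMatrix(dosages, sites, samples, depth=depth, gq=gq,
                        admixture=admixture)

    env = pd.DataFrame({"population": pop_names, "env1": lat_z})
    for k in range(2, cfg.n_env_axes + 1):
        env[f"env{k}"] = rng.normal(0, 1, cfg.n_pops)
    truth = TruthSet(outlier_genes=outliers, sweep_genes=sweep,
                     env_pc_values=env.set_index("population"))

    if cfg.sweep_alpha > 0 and sweep:
        gm = plant_sweep_sfs(gm, sweep, cfg.sweep_alpha, rng=rng)
    return gm, truth


def plant_sweep_sfs(gm: GenotypeMatrix, genes: set, alpha: float,
                    rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Distort listed genes' SFS toward the sweep footprint.

    Each polarized site's derived count is resampled, with probability
    1 - exp(-alpha), from the boundary classes of the background SFS
    (rare and high-frequency-derived variants in equal parts).  Derived
    copies are reassigned along the latitudinal gradient in the
    direction the site already leaned, so a planted sweep remains
    geographically localized (sweeps in the emulated study drive
    North-South differentiation, they do not erase it).
    alpha = 0 is the identity.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return gm
    if rng is None:
        rng = np.random.default_rng(0)
    missing_genes = set(genes) - set(gm.sites["gene"])
    if missing_genes:
        raise ValueError(f"unknown genes: {sorted(missing_genes)[:3]}...")
    n = 2 * gm.n_individuals
    der = gm.derived_dosages()
    known = gm.sites["ancestral"].isin(["ref", "alt"]).to_numpy()
    in_gene = gm.sites["gene"].isin(genes).to_numpy()
    move = 1.0 - np.exp(-alpha)
    lo_max = max(n // 10, 1)
    hi_min = n - lo_max
    dosages = gm.dosages.copy()
    flip = (gm.sites["ancestral"].to_numpy() == "alt")
    lat = gm.samples["lat"].to_numpy(float)
    lat_z = np.repeat((lat - lat.mean()) / max(lat.std(), 1e-9), 2)  # per hap
    for j in np.flatnonzero(in_gene & known):
        if rng.random() >= move:
            continue
        if rng.random() < 0.5:
            k = int(rng.integers(1, lo_max + 1))
        else:
            k = int(rng.integers(hi_min, n))
        # keep the sweep geographically polarized: place derived copies
        # toward the latitude end the site already favours
        dj = der[:, j].astype(float)
        dj[dj < 0] = np.nan
        lean = np.nansum((dj - np.nanmean(dj)) * lat_z[0::2])
        direction = 1.0 if lean >= 0 else -1.0
        score = 1.5 * direction * lat_z + rng.gumbel(size=n)
        hap = np.zeros(n, dtype=np.int8)
        hap[np.argsort(-score)[:k]] = 1
        d = hap[0::2] + hap[1::2]
        dosages[:, j] = (2 - d) if flip[j] else d
    out = GenotypeMatrix(dosages, gm.sites.copy(), gm.samples,
                         depth=gm.depth, gq=gm.gq, admixture=gm.admixture)
    return out


# ---------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------

def simulate_expression(cfg: SynthConfig, gm: GenotypeMatrix,
                        truth: TruthSet,
                        rng: np.random.Generator | None = None):
    """Modular expression with hub genes, a north-south factor, and
    planted trans-eQTL effects.

    Each module has one latent factor per individual; hub genes load
    ``hub_loading`` on their module factor and others ``base_loading``.
    A latitude factor loads on every gene (removed downstream by PC
    correction).  Planted eQTL pairs add effect x source-SNP dosage to
    the target's expression.  Returns (expression DataFrame, TruthSet
    with modules/hubs/eqtl pairs filled in).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    genes = pd.unique(gm.sites["gene"]).tolist()
    all_genes = sorted(set(genes) | {f"g{i:05d}" for i in range(cfg.n_genes)})
    G, n_ind = len(all_genes), gm.n_individuals

    module = rng.integers(1, cfg.n_modules + 1, size=G)
    p_hub = np.full(G, cfg.hub_fraction)
    is_out = np.array([g in truth.outlier_genes for g in all_genes])
    p_hub[is_out] = np.minimum(cfg.hub_fraction * cfg.outlier_hub_boost, 1.0)
    hub = rng.random(G) < p_hub
    factors = rng.normal(0, 1, size=(cfg.n_modules, n_ind))
    lat = gm.samples["lat"].to_numpy(float)
    lat_z = (lat - lat.mean()) / lat.std()

    loading = np.where(hub, cfg.hub_loading, cfg.base_loading)
    expr = loading[:, None] * factors[module - 1]
    expr = expr + cfg.ns_loading * lat_z[None, :]
    expr = expr + rng.normal(0, cfg.noise_sd, size=(G, n_ind))

    # plant trans-eQTLs: sources preferentially among outlier genes
    gene_sites = {g: np.flatnonzero(gm.sites["gene"].to_numpy() == g)
                  for g in genes}
    gidx = {g: i for i, g in enumerate(all_genes)}
    pairs = []
    for g in all_genes:
        if g not in gene_sites or len(gene_sites[g]) == 0:
            continue
        is_out = g in truth.outlier_genes
        frac = cfg.frac_eqtl_outliers if is_out else cfg.frac_eqtl_background
        if rng.random() >= frac:
            continue
        n_t = cfg.eqtl_targets_outlier if is_out else cfg.eqtl_targets_background
        # causal variant must be common enough to survive MAF filtering:
        # a trans-eQTL detectable in a 74-individual panel is a common SNP
        cand = gene_sites[g]
        freqs = np.array([np.nanmean(np.where(gm.dosages[:, j] >= 0,
                                              gm.dosages[:, j], np.nan)) / 2
                          for j in cand])
        maf = np.minimum(freqs, 1 - freqs)
        common = cand[maf >= 0.20]
        if len(common) == 0:
            continue  # no common variant: the gene cannot act as an eQTL
        snp = int(rng.choice(common))
        dos = gm.dosages[:, snp].astype(float)
        dos[dos < 0] = np.nan
        dos = np.nan_to_num(dos, nan=np.nanmean(dos))
        if dos.std() == 0:
            continue
        # targets avoid the adaptive genes: outliers act as trans
        # regulators (sources), mirroring the eGene depletion among
        # selection outliers the analysis is meant to detect
        pool = [x for x in all_genes
                if x != g and x not in truth.outlier_genes]
        targets = rng.choice(pool, size=n_t, replace=False)
        for t in targets:
            expr[gidx[t]] += cfg.eqtl_effect * dos
            pairs.append((g, t, cfg.eqtl_effect))

    em = pd.DataFrame(expr, index=all_genes,
                      columns=gm.samples["sample"].tolist())
    truth.eqtl_pairs = pairs
    truth.hub_genes = {all_genes[i] for i in np.flatnonzero(hub)}
    truth.module_assignment = {all_genes[i]: int(module[i]) for i in range(G)}
    return em, truth


# ---------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------

def write_fixture(outdir, gm: GenotypeMatrix, em: pd.DataFrame,
                  truth: TruthSet) -> dict:
    """Write VCF, expression TSV, sample metadata TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(gm, paths["vcf"])
    write_expression(em, paths["expression"])
    meta = gm.samples.copy()
    if gm.admixture is not None:
        for k in range(gm.admixture.shape[1]):
            meta[f"q{k + 1}"] = gm.admixture[:, k]
    meta.to_csv(paths["samples"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
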