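"""Core data containers and VCF/tabular input-output.

Genotypes are stored as alt-allele dosages (0/1/2) in an individuals x
sites integer matrix with ``MISSING = -1`` as sentinel.  One contig is
one gene: transcriptome-derived variants carry their gene identity in
the VCF CHROM column unless an explicit contig->gene map overrides it.
All positions are 1-based (VCF convention); internal indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["gene", "pos", "ref", "alt", "ancestral", "qual"]

#: order in which filter rules are attributed when a site fails several
FILTER_ORDER = ["site_quality", "genotype_quality", "depth", "het", "missing", "maf"]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages with per-site and per-sample metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_sites)`` integer array of alt-allele counts,
        ``MISSING`` (-1) for uncalled genotypes.
    sites
        Per-site frame with columns ``gene, pos, ref, alt, ancestral,
        qual``; ``ancestral`` is one of ``"ref"``, ``"alt"``,
        ``"unknown"``.
    samples
        Per-individual frame with at least ``sample``; typically also
        ``population, lat, lon``.
    depth, gq
        Optional per-cell read depth / genotype quality (float, NaN when
        absent).
    admixture
        Optional ``(n_individuals, K)`` admixture-proportion simplex.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    admixture: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")
        if len(self.sites) != self.dosages.shape[1]:
            raise ValueError("site metadata length does not match dosage columns")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample metadata length does not match dosage rows")
        if self.admixture is not None:
            q = np.asarray(self.admixture, dtype=float)
            if np.abs(q.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("admixture rows must sum to 1")
            self.admixture = q

    # -- basic geometry ------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def n_haploid(self) -> np.ndarray:
        """Per-site haploid sample size: 2 x non-missing individuals."""
        return 2 * self.called_mask().sum(axis=0)

    def alt_counts(self) -> np.ndarray:
        """Per-site alt-allele counts over non-missing genotypes."""
        d = self.dosages.astype(np.int64)
        d[d == MISSING] = 0
        return d.sum(axis=0)

    def alt_freq(self) -> np.ndarray:
        n = self.n_haploid()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_counts() / np.maximum(n, 1), np.nan)

    def derived_dosages(self) -> np.ndarray:
        """Dosages polarized to the derived allele.

        Sites with ``ancestral == "alt"`` are flipped (d -> 2 - d);
        unknown-ancestral sites are returned unpolarized — callers that
        need polarization must subset to known sites first.
        """
        out = self.dosages.copy()
        flip = (self.sites["ancestral"].to_numpy() == "alt")
        cols = out[:, flip]
        called = cols != MISSING
        cols[called] = 2 - cols[called]
        out[:, flip] = cols
        return out

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            sites=self.sites.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
            admixture=None if self.admixture is None else self.admixture[idx],
        )


@dataclass
class SFS:
    """Site frequency spectrum over derived-allele counts 1..n-1."""

    counts: np.ndarray
    n: int
    normalized: bool = False
    folded: bool = False
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n - 1:
            raise ValueError("SFS must have n-1 frequency classes")
        if (self.counts < 0).any():
            raise ValueError("SFS counts must be non-negative")

    def normalize(self) -> "SFS":
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty SFS")
        return SFS(self.counts / total, self.n, normalized=True,
                   folded=self.folded, n_excluded=self.n_excluded)


@dataclass
class FilterSpec:
    """Site/genotype filter thresholds.

    Defaults follow standard transcriptome-SNP practice: site quality
    >= 30, genotype quality >= 20, genotype depth >= 6, per-site
    heterozygosity < 80%, missingness < 20%, and minor allele frequency
    >= 0.05 on non-missing genotypes.
    """

    site_quality_min: float = 30.0
    genotype_quality_min: float = 20.0
    depth_min: float = 6.0
    max_het_fraction: float = 0.80
    max_missing_fraction: float = 0.20
    maf_min: float = 0.05
    biallelic_snps_only: bool = True

    def __post_init__(self) -> None:
        for name in ("max_het_fraction", "max_missing_fraction", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.maf_min >= 0.5:
            raise ValueError("maf_min >= 0.5 would remove every site")


# ---------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------

def read_vcf(path, gene_map: dict | None = None,
             sample_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    CHROM names the gene (one contig per gene) unless ``gene_map``
    supplies a contig->gene mapping.  Ancestral alleles are taken from
    the ``AA`` INFO field when present; per-genotype DP and GQ from
    FORMAT.  Non-diploid genotypes raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dos_rows, meta_rows, dp_rows, gq_rows = [], [], [], []
    any_dp = any_gq = False
    for i, v in enumerate(vcf):
        gts = v.genotypes
        for g in gts:
            if len(g) != 3:  # [allele0, allele1, phased]
                raise ValueError(
                    f"non-diploid genotype at {v.CHROM}:{v.POS} (record {i + 1})")
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int64)
        miss = (alleles < 0).any(axis=1)
        dos = alleles.clip(min=0).sum(axis=1)
        dos[miss] = MISSING
        dos_rows.append(dos.astype(np.int8))

        gene = v.CHROM if gene_map is None else gene_map.get(v.CHROM, v.CHROM)
        aa = v.INFO.get("AA")
        if aa is None:
            anc = "unknown"
        elif aa == v.REF:
            anc = "ref"
        elif len(v.ALT) and aa == v.ALT[0]:
            anc = "alt"
        else:
            anc = "unknown"
        meta_rows.append((gene, v.POS, v.REF, v.ALT[0] if v.ALT else ".",
                          anc, v.QUAL if v.QUAL is not None else np.nan))

        dp = v.format("DP")
        if dp is not None:
            any_dp = True
            dp = dp.astype(float).reshape(-1)
            dp[dp < 0] = np.nan
        dp_rows.append(dp)
        gq = v.format("GQ")
        if gq is not None:
            any_gq = True
            gq = gq.astype(float).reshape(-1)
            gq[gq < 0] = np.nan
        gq_rows.append(gq)

    if not dos_rows:
        raise ValueError(f"no variant records in {path}")
    dosages = np.stack(dos_rows, axis=1)
    sites = pd.DataFrame(meta_rows, columns=SITE_COLUMNS)
    n_ind = len(samples)

    def _stack(rows, present):
        if not present:
            return None
        filled = [r if r is not None else np.full(n_ind, np.nan) for r in rows]
        return np.stack(filled, axis=1)

    if sample_meta is not None:
        smeta = sample_meta.set_index("sample").loc[samples].reset_index()
    else:
        smeta = pd.DataFrame({"sample": samples})
    adm_cols = [c for c in smeta.columns if c.startswith("q") and c[1:].isdigit()]
    admixture = smeta[adm_cols].to_numpy(float) if adm_cols else None
    return GenotypeMatrix(dosages, sites, smeta,
                          depth=_stack(dp_rows, any_dp),
                          gq=_stack(gq_rows, any_gq),
                          admixture=admixture)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for gene in pd.unique(gm.sites["gene"]):
            fh.write(f"##contig=<ID={gene}>\n")
        names = "\t".join(gm.samples["sample"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        sites = gm.sites
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            anc = row["ancestral"]
            info = "."
            if anc == "ref":
                info = f"AA={row['ref']}"
            elif anc == "alt":
                info = f"AA={row['alt']}"
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            fields = []
            for i in range(gm.n_individuals):
                g = gt_str[int(gm.dosages[i, j])]
                dp = "." if gm.depth is None or np.isnan(gm.depth[i, j]) \
                    else str(int(round(gm.depth[i, j])))
                gq = "." if gm.gq is None or np.isnan(gm.gq[i, j]) \
                    else str(int(round(gm.gq[i, j])))
                fields.append(f"{g}:{dp}:{gq}")
            fh.write(f"{row['gene']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                     f"\t{qual}\t.\t{info}\tGT:DP:GQ\t" + "\t".join(fields) + "\n")


# ---------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------

def apply_filters(gm: GenotypeMatrix, spec: FilterSpec):
    """Apply site and genotype filters; return (filtered, removal counts).

    Genotype-level rules (GQ, depth) mask individual genotypes to
    missing; site-level rules then act on the masked matrix.  Removal
    counts attribute each removed site to the first failing rule in
    :data:`FILTER_ORDER`.
    """
    if gm.n_sites == 0:
        raise ValueError("empty GenotypeMatrix")
    counts = {name: 0 for name in FILTER_ORDER}

    dos = gm.dosages.copy()
    called0 = dos != MISSING

    qual = gm.sites["qual"].to_numpy(float)
    ok_qual = np.isnan(qual) | (qual >= spec.site_quality_min)

    # genotype-quality mask
    if gm.gq is not None and spec.genotype_quality_min > 0:
        mask_gq = called0 & ~np.isnan(gm.gq) & (gm.gq < spec.genotype_quality_min)
    else:
        mask_gq = np.zeros_like(called0)
    called_after_gq = called0 & ~mask_gq
    # depth mask
    if gm.depth is not None and spec.depth_min > 0:
        mask_dp = called_after_gq & ~np.isnan(gm.depth) & (gm.depth < spec.depth_min)
    else:
        mask_dp = np.zeros_like(called0)
    called_final = called_after_gq & ~mask_dp
    dos[~called_final] = MISSING

    n_called = called_final.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0,
                            ((dos == 1) & called_final).sum(axis=0) / np.maximum(n_called, 1),
                            1.0)
        miss_frac = 1.0 - n_called / gm.n_individuals
        ac = np.where(called_final, dos, 0).sum(axis=0)
        freq = np.where(n_called > 0, ac / np.maximum(2 * n_called, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    ok_gq_site = (called_after_gq.sum(axis=0) > 0)
    ok_dp_site = n_called > 0
    ok_het = het_frac < spec.max_het_fraction
    ok_miss = miss_frac < spec.max_missing_fraction
    ok_maf = maf >= spec.maf_min

    keep = np.ones(gm.n_sites, dtype=bool)
    for name, ok in (("site_quality", ok_qual), ("genotype_quality", ok_gq_site),
                     ("depth", ok_dp_site), ("het", ok_het),
                     ("missing", ok_miss), ("maf", ok_maf)):
        newly = keep & ~ok
        counts[name] = int(newly.sum())
        keep &= ok

    filtered = gm.take_sites(np.flatnonzero(keep))
    filtered = replace(filtered, dosages=dos[:, keep])
    counts["kept"] = int(keep.sum())
    return filtered, counts


def coverage_genotype_qc(gm: GenotypeMatrix) -> dict:
    """Squared correlations between genotype and read depth.

    ``r2_additive`` correlates the 0/1/2 dosage with per-cell depth over
    non-missing cells; ``r2_het`` uses a heterozygote indicator instead.
    Zero variance on either side yields r^2 = 0 by convention.
    """
    if gm.depth is None:
        raise ValueError("depth matrix required for coverage QC")
    called = gm.called_mask() & ~np.isnan(gm.depth)
    d = gm.dosages[called].astype(float)
    dp = gm.depth[called]

    def _r2(x, y):
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    return {"r2_additive": _r2(d, dp), "r2_het": _r2((d == 1).astype(float), dp)}


# ---------------------------------------------------------------------
# SFS and gene indexing
# ---------------------------------------------------------------------

def unfolded_sfs(gm: GenotypeMatrix, site_subset: np.ndarray | None = None) -> SFS:
    """Unfolded SFS over polarized, fully-called polymorphic sites.

    Sites with unknown ancestral state or any missing genotype are
    excluded (tallied in ``n_excluded``) so every included site shares
    the same haploid sample size n = 2 x individuals.  Sites monomorphic
    for ancestral or derived allele are excluded as well.
    """
    sub = gm if site_subset is None else gm.take_sites(site_subset)
    known = sub.sites["ancestral"].isin(["ref", "alt"]).to_numpy()
    if not known.any():
        raise ValueError("no sites with known ancestral state")
    complete = sub.called_mask().all(axis=0)
    use = known & complete
    n = 2 * sub.n_individuals
    der = sub.derived_dosages()[:, use].astype(np.int64).sum(axis=0)
    poly = (der > 0) & (der < n)
    counts = np.bincount(der[poly], minlength=n)[1:n]
    n_excluded = int((~use).sum() + (~poly).sum())
    return SFS(counts.astype(float), n=n, n_excluded=n_excluded)


def per_gene_index(gm: GenotypeMatrix) -> dict:
    """Map gene id -> dict(sites=<column indices>, S=<segregating count>).

    S counts sites polymorphic among non-missing genotypes; genes whose
    surviving sites are all monomorphic are absent.
    """
    ac = gm.alt_counts()
    n = gm.n_haploid()
    poly = (ac > 0) & (ac < n)
    genes = gm.sites["gene"].to_numpy()
    index: dict = {}
    for j in np.flatnonzero(poly):
        rec = index.setdefault(genes[j], {"sites": [], "S": 0})
        rec["sites"].append(j)
        rec["S"] += 1
    for rec in index.values():
        rec["sites"] = np.asarray(rec["sites"])
    return index


# ---------------------------------------------------------------------
# Tabular helpers
# ---------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t")


def read_sample_meta(path) -> pd.DataFrame:
    """Sample metadata TSV: sample, population, lat, lon, q1..qK."""
    return pd.read_csv(path, sep="\t")
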