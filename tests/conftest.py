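import numpy as np
import pandas as pd
import pytest

from pleioscan import SynthConfig, simulate_genotypes, simulate_expression
from pleioscan.io import FilterSpec, GenotypeMatrix, apply_filters


def make_gm(dosages, genes=None, pos=None, ancestral=None, qual=None,
            populations=None, lat=None, depth=None, gq=None, admixture=None):
    """Construct a small GenotypeMatrix from raw pieces."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    sites = pd.DataFrame({
        "gene": genes if genes is not None else ["g1"] * n_sites,
        "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 10,
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
        "ancestral": ancestral if ancestral is not None else ["ref"] * n_sites,
        "qual": qual if qual is not None else [100.0] * n_sites,
    })
    samples = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n_ind)],
        "population": populations if populations is not None else ["P1"] * n_ind,
        "lat": lat if lat is not None else np.linspace(30, 45, n_ind),
        "lon": np.linspace(-95, -88, n_ind),
    })
    return GenotypeMatrix(dosages, sites, samples, depth=depth, gq=gq,
                          admixture=admixture)


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate synthetic cohort with planted truth, shared across tests."""
    cfg = SynthConfig(n_genes=300, sites_per_gene_mean=10,
                      frac_outlier_genes=0.1, seed=42)
    with pytest.warns(UserWarning, match="clipped"):
        gm, truth = simulate_genotypes(cfg)
    em, truth = simulate_expression(cfg, gm, truth)
    return cfg, gm, em, truth


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    """Cohort after standard filtering (MAF filter off, as for SFS work)."""
    cfg, gm, em, truth = default_cohort
    filt, _ = apply_filters(gm, FilterSpec(maf_min=0.0))
    return cfg, filt, em, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort without planted selection signal (no cline, no sweeps)."""
    cfg = SynthConfig(n_genes=250, sites_per_gene_mean=10, clinal_shift=0.0,
                      sweep_alpha=0.0, frac_eqtl_outliers=0.0,
                      frac_eqtl_background=0.0, seed=7)
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth
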