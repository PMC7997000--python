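import numpy as np
import pandas as pd
import pytest

from snipage import age, interaction, motif, simulate
from snipage.core_io import CohortData, CovariateTable, GenotypeTable


def small_config(**overrides):
    """A fast fixture configuration for unit tests."""
    defaults = dict(seed=11, n_samples=150, n_tfs=10, n_age_tfs=4,
                    n_target_genes=15, n_planted=6, n_decoy_asb=4,
                    n_both_allele=2, n_peer=4, n_peer_age_correlated=1,
                    chrom_length=200_000, snp_start=60_000,
                    snp_spacing=2_000)
    defaults.update(overrides)
    return simulate.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate.simulate_cohort(small_config())


@pytest.fixture(scope="session")
def strong_bundle():
    """The identifiability fixture: 30 planted triplets, interaction
    effect 1.0, target noise sd 0.5, 400 samples."""
    return simulate.simulate_cohort(simulate.preset("strong", seed=7))


@pytest.fixture(scope="session")
def strong_run(strong_bundle):
    """Full pipeline artifacts on the strong fixture, computed once."""
    b = strong_bundle
    calls = motif.filter_open_chromatin(
        motif.call_asb_table(b.pwms, b.cohort.genotypes.snps, b.genome),
        b.dhs)
    age_set = age.detect_age_tfs(b.cohort, b.tf_panel)
    table = interaction.run_pipeline(b.cohort, age_set, calls,
                                     b.annotations)
    return {"bundle": b, "asb_calls": calls, "age_set": age_set,
            "table": table}


def make_covariates(rng, n, n_pcs=3, n_peer=2, index=None):
    """Random covariate table for regression-level tests."""
    idx = index if index is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame({
        "age": rng.uniform(20, 70, n),
        "sex": rng.integers(0, 2, n).astype(float)}, index=idx)
    for l in range(n_pcs):
        df[f"SNP_PC{l + 1}"] = rng.normal(size=n)
    for k in range(n_peer):
        df[f"PEER{k + 1}"] = rng.normal(size=n)
    return CovariateTable(df, n_pcs)


def make_cohort(rng, n_samples=60, genes=("g1", "g2"), n_snps=2):
    """Minimal hand-built cohort for io/pipeline-level tests."""
    sids = [f"s{i:03d}" for i in range(n_samples)]
    cov = make_covariates(rng, n_samples, index=sids)
    expr = pd.DataFrame(rng.normal(size=(len(genes), n_samples)),
                        index=list(genes), columns=sids)
    snps = pd.DataFrame(
        {"chrom": "chr1",
         "pos": 1000 * (1 + np.arange(n_snps)),
         "ref": ["A"] * n_snps, "alt": ["G"] * n_snps},
        index=pd.Index([f"rs{i}" for i in range(n_snps)], name="snp_id"))
    dos = pd.DataFrame(rng.binomial(2, 0.4, size=(n_snps, n_samples))
                       .astype(float), index=snps.index, columns=sids)
    return CohortData(expr, cov, GenotypeTable(snps, dos))
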