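"""Shared fixtures: small simulated populations and toy model systems."""

import numpy as np
import pytest

from ssbayesn import pedsim
from ssbayesn.relationship import PedigreeGraph


def random_pedigree(n: int, seed: int = 0, p_founder: float = 0.3) -> PedigreeGraph:
    """Random topologically ordered pedigree allowing inbred matings."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(2, n):
        if rng.random() > p_founder:
            s, d = rng.choice(i, size=2, replace=False)
            sire[i], dam[i] = s, d
    return PedigreeGraph(sire, dam)


@pytest.fixture(scope="session")
def small_population():
    """A bred population small enough for dense linear algebra everywhere."""
    panel = pedsim.simulate_founders(110, n_chr=2, snps_per_chr=25,
                                     ld_rho=0.5, seed=41)
    pop = pedsim.forward_breed(panel, n_generations=2, n_males=10,
                               n_females=100, seed=42)
    return pop


@pytest.fixture(scope="session")
def small_dataset(small_population):
    """Population + QTL + traits + a random genotype/phenotype mask."""
    pop = small_population
    qtl = pedsim.select_qtl(pop, 8, target_mean_maf=0.2, tol=0.05, seed=43)
    qtl = pedsim.assign_qtl_groups(qtl, seed=44)
    qtl = pedsim.simulate_effects_n5(qtl, seed=45)
    traits = pedsim.simulate_phenotypes(pop, qtl, seed=46)
    rng = np.random.default_rng(47)
    genotyped = rng.random(pop.n_ind) < 0.45
    phenotyped = rng.random(pop.n_ind) < 0.6
    y_obs = np.where(phenotyped[:, None], traits.phenotypes, np.nan)
    return pop, qtl, traits, genotyped, phenotyped, y_obs


def build_toy_ss(small_dataset, n_traits=2, region_size=10):
    """Assemble a SingleStepSystem on the small data set."""
    from ssbayesn.regions import (derive_priors_multitrait,
                                  derive_priors_singletrait, partition_regions)
    from ssbayesn.relationship import partition_blocks
    from ssbayesn.singlestep import build_ss_system

    pop, qtl, traits, genotyped, phenotyped, y_obs = small_dataset
    keep = qtl.analysis_snps(pop.n_snp)
    ped = PedigreeGraph.from_population(pop)
    blocks = partition_blocks(ped, genotyped)
    M_raw = pop.genotypes[np.ix_(blocks.genotyped_idx, keep)].astype(float)
    p = M_raw.mean(0) / 2
    poly = (p > 0) & (p < 1)
    M_raw = M_raw[:, poly]
    p = p[poly]
    rmap = partition_regions(pop.chrom[keep][poly], mode="fixed_n",
                             region_size=region_size)
    if n_traits == 2:
        priors = derive_priors_multitrait(np.cov(traits.tbv.T),
                                          np.diag(traits.residual_var), p)
        y = y_obs
    else:
        priors = derive_priors_singletrait(traits.tbv[:, 1].var(ddof=1),
                                           traits.residual_var[1], p)
        y = y_obs[:, [1]]
    system = build_ss_system(y, genotyped, phenotyped, M_raw, blocks, rmap,
                             priors)
    return system, blocks, traits
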