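import numpy as np
import pytest

import fibermap as fm


@pytest.fixture(scope="session")
def genome():
    return fm.GenomeModel.default()


@pytest.fixture(scope="session")
def tiny_genome():
    """One short chromosome: fast causal-genotype-only simulations."""
    return fm.GenomeModel(
        chromosomes=(fm.Chromosome("c1", 1_000_000, 1.0),),
        causal_locus=("c1", 500_000),
    )


@pytest.fixture(scope="session")
def small_genome():
    """Three 6-Mb chromosomes: desk-scale end-to-end runs in seconds."""
    return fm.GenomeModel(
        chromosomes=tuple(fm.Chromosome(f"S{i:02d}", 6_000_000, 6.0) for i in (1, 2, 3)),
        causal_locus=("S02", 3_000_000),
    )


@pytest.fixture(scope="session")
def small_population(small_genome):
    cfg = fm.CrossConfig(n_f2=120, bulk_size=12, seed=11)
    pop = fm.simulate_f2(small_genome, cfg)
    fm.assign_phenotypes(pop, cfg)
    return pop


@pytest.fixture(scope="session")
def locus_seqs():
    return fm.simulate_locus_sequences(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
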