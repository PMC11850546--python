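import numpy as np
import pytest

from hlacompat.alleles import AlleleSequence, AlleleStore
from hlacompat.synthetic import (
    SimulationSpec,
    gen_allele_store,
    gen_eplet_registry,
    gen_exposure_maps,
    gen_grooves,
    gen_haplotype_table,
    sample_genotype,
)

SEED = 7


@pytest.fixture(scope="session")
def spec():
    return SimulationSpec(seed=SEED)


@pytest.fixture(scope="session")
def generated(spec):
    return gen_allele_store(spec)


@pytest.fixture(scope="session")
def store(generated):
    return generated.store


@pytest.fixture(scope="session")
def exposure(generated):
    return gen_exposure_maps(generated, SEED)


@pytest.fixture(scope="session")
def registry(generated, spec):
    return gen_eplet_registry(generated, spec)


@pytest.fixture(scope="session")
def haplotable(generated, spec):
    return gen_haplotype_table(generated, spec)


@pytest.fixture(scope="session")
def grooves(generated):
    return gen_grooves(generated)


@pytest.fixture()
def genotype_sampler(haplotable, spec):
    def sampler(seed):
        rng = np.random.default_rng(seed)
        return (sample_genotype(haplotable, spec.population, rng),
                sample_genotype(haplotable, spec.population, rng))

    return sampler


@pytest.fixture(scope="session")
def toy_store():
    """Four hand-built alleles at one locus over six alignment columns."""
    def seq(name, letters):
        return AlleleSequence(locus="A", name=name,
                              residues={i + 1: c for i, c in enumerate(letters)})

    return AlleleStore([
        seq("A*01:01", "ACDEFG"),
        seq("A*02:01", "AGDEFG"),
        seq("A*03:01", "ACDXXG"),
        seq("A*04:01", "ACDXXX"),
    ])
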