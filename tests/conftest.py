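from collections import Counter

import pytest

from kirpop import (
    HlaGenotype,
    KirGenotype,
    PopulationSample,
    generate_haplotype_pool,
    load_catalog,
    sample_population,
)
from kirpop.nomenclature import AlleleName


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def amerindian_pool():
    return generate_haplotype_pool("amerindian")


@pytest.fixture(scope="session")
def cosmopolitan_pool():
    return generate_haplotype_pool("cosmopolitan")


@pytest.fixture(scope="session")
def amerindian_synth(amerindian_pool):
    return sample_population(amerindian_pool, n=150, seed=101, name="AME")


@pytest.fixture(scope="session")
def cosmopolitan_synth(cosmopolitan_pool):
    return sample_population(cosmopolitan_pool, n=150, seed=202, name="COS")


def make_kir(ind="IND1", **loci):
    """Build a KirGenotype from locus=[allele tokens] keyword arguments."""
    copy_number = {}
    alleles = {}
    for locus, tokens in loci.items():
        if isinstance(tokens, int):
            copy_number[locus] = tokens
            continue
        copy_number[locus] = len(tokens)
        if tokens:
            alleles[locus] = Counter(
                AlleleName.parse(t, locus=locus) for t in tokens
            )
    return KirGenotype(individual_id=ind, copy_number=copy_number, alleles=alleles)


def make_hla(ind="IND1", a=("A*02:01", "A*02:01"), b=("B*35:01", "B*35:01"), c=("C*07:02", "C*07:02")):
    return HlaGenotype(individual_id=ind, alleles={"A": tuple(a), "B": tuple(b), "C": tuple(c)})


@pytest.fixture
def kir_factory():
    return make_kir


@pytest.fixture
def hla_factory():
    return make_hla


@pytest.fixture
def single_individual_population():
    kir = make_kir(
        "IND1",
        KIR3DL3=["00201", "00201"],
        KIR2DL3=["00201", "00201"],
        KIR2DL1=["00302", "00302"],
        KIR2DL4=["00102", "00102"],
        KIR3DL1=["01502", "01502"],
        KIR2DS4=["00101", "00101"],
        KIR3DL2=["00201", "00201"],
        KIR2DP1=2,
        KIR3DP1=2,
    )
    hla = make_hla("IND1", b=("B*51:01", "B*35:01"), c=("C*04:01", "C*07:02"))
    return PopulationSample(name="single", records=[(kir, hla)])
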