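from importlib import resources

import pytest

from famprio import read_ped, read_variant_table
from famprio.pedigree import Member, Pedigree


@pytest.fixture(scope="session")
def family5():
    """The packaged two-generation family fixture (11 members, 9 sampled)."""
    with resources.as_file(resources.files("famprio.data") / "family5.ped") as p:
        return read_ped(p)


@pytest.fixture(scope="session")
def pot1_variant(family5):
    """The packaged co-segregating missense variant fixture."""
    with resources.as_file(resources.files("famprio.data") / "family5_pot1.tsv") as p:
        (variant,) = read_variant_table(p, "tsv", family5)
    return variant


@pytest.fixture(scope="session")
def pot1_genotypes(pot1_variant):
    return pot1_variant.genotypes


@pytest.fixture
def small_pedigree():
    """Six members: founder couple + 4 children with mixed roles,
    small enough for exhaustive dosage enumeration."""
    return Pedigree(
        [
            Member("f", "male", 1, role="unknown"),
            Member("m", "female", 1, role="carrier"),
            Member("c1", "female", 2, father="f", mother="m", role="case"),
            Member("c2", "male", 2, father="f", mother="m", role="case"),
            Member("c3", "female", 2, father="f", mother="m", role="control"),
            Member("c4", "male", 2, father="f", mother="m", role="carrier"),
        ],
        name="small",
    )
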