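import numpy as np
import pytest

from tetradrive import (
    Allele,
    CrossSpec,
    Haplotype,
    Locus,
    build_cross_registry,
    build_strain_library,
)


@pytest.fixture(scope="session")
def library():
    return build_strain_library()


@pytest.fixture(scope="session")
def registry(library):
    return build_cross_registry(library)


@pytest.fixture
def rng():
    return np.random.default_rng(20140515)


def single_killer_cross(s, n_asci=1000, seed=7, packaging="binucleate_tetrad",
                        covers_self=True):
    """Minimal cross: one heterozygous killer locus with SDS frequency s."""
    alleles = {
        "K": Allele(
            "K", "L", distorter_active=True,
            responder_covers=frozenset({"K"}) if covers_self else frozenset(),
        ),
        "k0": Allele("k0", "L"),
    }
    return CrossSpec(
        parent1=Haplotype("killer", {"L": "K"}),
        parent2=Haplotype("sensitive", {"L": "k0"}),
        loci=(Locus("L", "chr1", s),),
        alleles=alleles,
        n_asci=n_asci,
        seed=seed,
        packaging=packaging,
        name=f"single-killer-s{s}",
    )
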