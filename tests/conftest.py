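import numpy as np
import pytest

from capensim.karyotype import (
    CsdLocus,
    MarkerLocus,
    MarkerPanel,
    founder_genome,
)
from capensim.synthio import draw_founders, make_panel


def single_locus_panel(centromere_distance: float) -> MarkerPanel:
    """One marker locus + csd on separate chromosomes; minimal and fast."""
    loc = MarkerLocus(
        id="M", chromosome=1, centromere_distance=centromere_distance,
        allele_alphabet=frozenset({1, 2, 3, 4, 5, 6}),
    )
    csd = CsdLocus(
        id="csd", chromosome=2, centromere_distance=0.0,
        allele_alphabet=frozenset({91, 92, 93, 94, 95, 96}),
    )
    return MarkerPanel([loc], csd, chromosome_count=2)


@pytest.fixture
def locus_panel():
    return single_locus_panel(0.2)


@pytest.fixture
def centromeric_panel():
    """All loci at the centromere: recombination cannot shuffle alleles."""
    loci = [
        MarkerLocus(id=f"L{i}", chromosome=i, centromere_distance=0.0,
                    allele_alphabet=frozenset(range(10 * i, 10 * i + 8)))
        for i in range(1, 4)
    ]
    csd = CsdLocus(id="csd", chromosome=4, centromere_distance=0.0,
                   allele_alphabet=frozenset({91, 92, 93, 94, 95, 96}))
    return MarkerPanel(loci, csd, chromosome_count=4)


@pytest.fixture
def panel7():
    """A seven-locus informative panel on a compact karyotype."""
    return make_panel(7, 8, rng=11, chromosome_count=8)


@pytest.fixture
def diploid_cross(panel7):
    """Fully informative diploid queen x 4 unrelated drones."""
    queen, drones = draw_founders(panel7, 2, 4, np.random.default_rng(7))
    return panel7, queen, drones


@pytest.fixture
def triploid_cross(panel7):
    """Fully informative triploid queen x 1 drone."""
    queen, drones = draw_founders(panel7, 3, 1, np.random.default_rng(8))
    return panel7, queen, drones


def het_diploid(panel, a=1, b=2, csd=(91, 92)):
    alleles = {loc.id: (a, b) for loc in panel.loci}
    alleles["csd"] = csd
    return founder_genome(panel, alleles, "Q")
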