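"""Meiosis with crossovers for diploid and triploid germ cells.

Honey-bee eggs are laid arrested at the first meiotic division; after
oviposition meiosis completes, leaving four maternal pronuclei arranged
in a tetrad. The two *central* pronuclei descend from opposite
meiosis-I poles, which is why their fusion (central-fusion automixis,
the *A. m. capensis* thelytoky mechanism) restores the maternal
genotype except where recombination between centromere and locus has
exchanged alleles — the source of loss of heterozygosity (LOH) in
thelytokous offspring.

For a triploid germ cell we implement the two-step model proposed for
triploid queens: at meiosis I all chromosomes send two homologs to one
pole and one to the other (after replication: a tetraploid and a
diploid daughter cell); meiosis II reduces each, yielding two diploid
and two haploid products per tetrad. The two diploid products carry
non-sister chromosomes. A proportion of central pronuclei may then
fuse into a triploid nucleus (see :mod:`capensim.reproduction`).

A disjunction-error mode moves single chromatid copies between tetrad
products, producing eggs with unbalanced chromosome sets — one
hypothesised cause of the low egg viability of triploid queens.

Crossovers: the count per chromosome is Poisson (optionally forced
>= 1), positions uniform on the genetic map, no chiasma interference.
With the default mean of ``2 x chromosome_length`` (in Morgans) the
per-chromatid recombination fraction between centromere and a locus at
distance d follows Haldane's map function, r = (1 - e^(-2d)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .karyotype import CellGenome, Chromatid, MarkerPanel

__all__ = [
    "CrossoverModel",
    "MeioticTetrad",
    "perform_meiosis",
    "triploid_meiosis",
    "central_fusion",
    "apply_disjunction_errors",
]

TETRAD_POSITIONS = ("peripheral-1", "central-1", "central-2", "peripheral-2")


@dataclass(frozen=True)
class CrossoverModel:
    """Crossover process for one meiosis.

    ``mean_crossovers_per_chromosome`` is the Poisson mean of crossover
    events per bivalent (tetrad level). ``chromosome_length`` is the map
    length in Morgans over which positions are uniform. The default pair
    (2.0, 1.0) makes per-chromatid recombination Haldane-consistent.
    ``obligate_crossover`` forces at least one event per chromosome.
    """

    mean_crossovers_per_chromosome: float = 2.0
    obligate_crossover: bool = False
    chromosome_length: float = 1.0

    def __post_init__(self):
        if self.mean_crossovers_per_chromosome < 0:
            raise ValueError("mean_crossovers_per_chromosome must be >= 0")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be > 0")

    def draw_count(self, rng: np.random.Generator) -> int:
        k = int(rng.poisson(self.mean_crossovers_per_chromosome))
        if self.obligate_crossover and k == 0:
            k = 1
        return k


class MeioticTetrad:
    """The four ordered products of one meiosis.

    ``products`` are CellGenomes at positions
    ``[peripheral-1, central-1, central-2, peripheral-2]``; positions 1
    and 2 (the central pronuclei) descend from opposite meiosis-I poles.
    """

    def __init__(self, products: Sequence[CellGenome]):
        if len(products) != 4:
            raise ValueError("a tetrad has exactly 4 products")
        self.products = list(products)

    @property
    def central(self) -> tuple:
        return self.products[1], self.products[2]

    @property
    def peripheral(self) -> tuple:
        return self.products[0], self.products[3]

    def copy_numbers(self, chromosome: int) -> list:
        return [p.copy_number(chromosome) for p in self.products]


def _crossover(
    strands_a: list, strands_b: list, loci: list, xo: CrossoverModel,
    rng: np.random.Generator,
) -> None:
    """Apply crossovers in place between two sister-pairs of chromatids.

    Each event picks one chromatid from each pair and swaps alleles (and
    origin labels) at all loci distal to a uniform breakpoint.
    """
    if not loci:
        return
    for _ in range(xo.draw_count(rng)):
        x = rng.uniform(0.0, xo.chromosome_length)
        a = strands_a[rng.integers(len(strands_a))]
        b = strands_b[rng.integers(len(strands_b))]
        for loc in loci:
            if loc.centromere_distance > x and loc.id in a.alleles:
                a.alleles[loc.id], b.alleles[loc.id] = (
                    b.alleles[loc.id],
                    a.alleles[loc.id],
                )
                a.origin[loc.id], b.origin[loc.id] = (
                    b.origin[loc.id],
                    a.origin[loc.id],
                )


def _assemble(products_chromatids: list) -> MeioticTetrad:
    genomes = [
        CellGenome({ch: cs for ch, cs in prod.items()})
        for prod in products_chromatids
    ]
    return MeioticTetrad(genomes)


def perform_meiosis(
    germ: CellGenome,
    panel: MarkerPanel,
    xo: CrossoverModel,
    rng: Union[np.random.Generator, int],
) -> MeioticTetrad:
    """Meiosis of a diploid germ cell -> tetrad of 4 haploid pronuclei.

    Per chromosome: the two homologs replicate into two sister pairs;
    crossovers exchange distal blocks between non-sister chromatids;
    meiosis I separates the sister pairs to opposite poles (independent
    assortment across chromosomes) and meiosis II separates sisters.
    Conservation: the four products jointly carry each homolog's two
    chromatid copies.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if germ.ploidy != 2:
        raise ValueError(f"perform_meiosis requires a diploid germ cell, got ploidy {germ.ploidy}")
    prods: list = [dict(), dict(), dict(), dict()]
    for ch, homologs in germ.chromatids.items():
        loci = panel.loci_on(ch)
        pair_a = [homologs[0].copy(), homologs[0].copy()]
        pair_b = [homologs[1].copy(), homologs[1].copy()]
        _crossover(pair_a, pair_b, loci, xo, rng)
        poles = [pair_a, pair_b]
        if rng.integers(2):  # independent assortment
            poles.reverse()
        for pole in poles:
            if rng.integers(2):  # meiosis II spindle orientation
                pole.reverse()
        # pole 0 -> positions 0 (peripheral-1), 1 (central-1)
        # pole 1 -> positions 2 (central-2), 3 (peripheral-2)
        prods[0][ch] = [poles[0][0]]
        prods[1][ch] = [poles[0][1]]
        prods[2][ch] = [poles[1][0]]
        prods[3][ch] = [poles[1][1]]
    return _assemble(prods)


def triploid_meiosis(
    germ: CellGenome,
    panel: MarkerPanel,
    xo: CrossoverModel,
    rng: Union[np.random.Generator, int],
) -> MeioticTetrad:
    """Meiosis of a triploid germ cell -> two diploid + two haploid products.

    Meiosis I sends two homologs to one pole and one to the other —
    coherently across chromosomes, so the meiosis-I daughters are a
    tetraploid and a diploid cell after replication. Which two of the
    three homologs travel together is drawn independently per
    chromosome, and crossovers act between those two. Meiosis II then
    reduces both daughters, giving tetrad product ploidies {1,1,2,2}
    with the two diploid products carrying non-sister chromosomes.
    One central position descends from each pole, so central fusion
    yields a triploid nucleus.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if germ.ploidy != 3:
        raise ValueError(f"triploid_meiosis requires a triploid germ cell, got ploidy {germ.ploidy}")
    # Which pole (0 or 1) receives two homologs; fixed for the whole cell.
    big_pole = int(rng.integers(2))
    prods: list = [dict(), dict(), dict(), dict()]
    for ch, homologs in germ.chromatids.items():
        loci = panel.loci_on(ch)
        idx = list(rng.permutation(3))
        paired = [homologs[idx[0]], homologs[idx[1]]]
        lone = homologs[idx[2]]
        pair_a = [paired[0].copy(), paired[0].copy()]
        pair_b = [paired[1].copy(), paired[1].copy()]
        _crossover(pair_a, pair_b, loci, xo, rng)
        lone_pair = [lone.copy(), lone.copy()]
        # Meiosis II on the two-homolog pole: each daughter receives one
        # chromatid of each sister pair (non-sister combination).
        if rng.integers(2):
            pair_a.reverse()
        if rng.integers(2):
            pair_b.reverse()
        big_daughters = [[pair_a[0], pair_b[0]], [pair_a[1], pair_b[1]]]
        if rng.integers(2):
            lone_pair.reverse()
        small_daughters = [[lone_pair[0]], [lone_pair[1]]]
        if big_pole == 0:
            pole0, pole1 = big_daughters, small_daughters
        else:
            pole0, pole1 = small_daughters, big_daughters
        prods[0][ch] = pole0[0]
        prods[1][ch] = pole0[1]
        prods[2][ch] = pole1[0]
        prods[3][ch] = pole1[1]
    return _assemble(prods)


def central_fusion(tetrad: MeioticTetrad) -> CellGenome:
    """Fuse the two central pronuclei into one nucleus.

    For a diploid meiosis this restores a diploid (thelytokous) nucleus;
    for the triploid-queen tetrad (one diploid + one haploid central
    product) it yields a triploid fusion nucleus.
    """
    c1, c2 = tetrad.central
    return c1.merged_with(c2)


def apply_disjunction_errors(
    tetrad: MeioticTetrad,
    error_rate: float,
    rng: Union[np.random.Generator, int],
) -> MeioticTetrad:
    """Missegregate chromosomes between tetrad products.

    With probability ``error_rate`` per chromosome, one chromatid copy
    moves from a random product carrying it to a different random
    product. Total copy number per chromosome is conserved; affected
    products are flagged aneuploid. Models the disjunction-error
    hypothesis for the inviability of most triploid-queen eggs: eggs
    with varying, possibly missing, chromosome numbers.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    products = [p.copy() for p in tetrad.products]
    chromosomes = sorted(
        {ch for p in products for ch in p.chromatids}
    )
    for ch in chromosomes:
        if rng.uniform() >= error_rate:
            continue
        donors = [i for i, p in enumerate(products) if p.copy_number(ch) > 0]
        donor = donors[rng.integers(len(donors))]
        others = [i for i in range(4) if i != donor]
        recipient = others[rng.integers(len(others))]
        moved = products[donor].chromatids[ch].pop(
            rng.integers(products[donor].copy_number(ch))
        )
        products[recipient].chromatids.setdefault(ch, []).append(moved)
        products[donor].aneuploid_flag = True
        products[recipient].aneuploid_flag = True
    return MeioticTetrad(products)
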