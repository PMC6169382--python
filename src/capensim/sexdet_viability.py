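"""Complementary sex determination (*csd*) and brood viability filters.

Sex in honey bees hinges on allelic state at the single *csd* locus:
any individual carrying two or more distinct *csd* alleles develops as
female, whatever its ploidy; hemizygotes (haploids) are normal males;
diploid or higher genomes homozygous at *csd* are diploid males, which
workers cannibalise at the first larval instar.

Viability between egg and pupa is modelled phenomenologically: a
per-class Bernoulli survival probability, plus two mechanistic
switches — removal of aneuploid (karyotypically unbalanced) eggs and
removal of diploid males. The triploid-queen preset encodes the
observation that a triploid queen's eggs almost never hatch (2.1% in
worker cells, 0% in drone cells) while her rare tetraploid offspring
reach pupation, whereas diploid sister queens hatch ~93% of eggs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .karyotype import CellGenome, CsdLocus, allele_set_at
from .reproduction import EggOutcome

__all__ = [
    "ViabilityPolicy",
    "determine_sex",
    "apply_viability",
    "diploid_queen_policy",
    "triploid_queen_policy",
]


@dataclass
class ViabilityPolicy:
    """Survival rules applied between egg stage and later stages.

    ``class_viability`` maps a true class label to the probability that
    an egg of that class survives the egg stage; classes absent from
    the map raise, so policies are explicit about what they cover.
    """

    require_balanced_karyotype: bool = False
    remove_diploid_males: bool = True
    class_viability: dict = field(default_factory=dict)

    def __post_init__(self):
        for cls, p in self.class_viability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"viability for {cls} out of [0,1]: {p}")


def diploid_queen_policy() -> ViabilityPolicy:
    """Baseline policy for a normally-mated diploid queen (~93% hatch)."""
    return ViabilityPolicy(
        remove_diploid_males=True,
        class_viability={
            "haploid": 0.93,
            "diploid_unfertilized": 0.93,
            "diploid_fertilized": 0.93,
            "triploid_unfertilized": 0.93,
            "triploid_fertilized": 0.93,  # triploid workers are fully viable
            "tetraploid_fertilized": 0.93,
        },
    )


def triploid_queen_policy() -> ViabilityPolicy:
    """Policy reproducing the brood profile of a triploid queen.

    Fertilised triploid eggs (diploid oocyte + sperm) never reached
    pupation and almost no egg of any class hatched; only tetraploids
    (fertilised triploid oocytes) and a few unfertilised triploids
    appeared as pupae. Rates are calibrated to the observed hatch of
    2.1% in worker cells and the pupal class mix.
    """
    return ViabilityPolicy(
        remove_diploid_males=True,
        class_viability={
            "haploid": 0.0,
            "diploid_unfertilized": 0.0,
            "diploid_fertilized": 0.0,
            "triploid_unfertilized": 0.1,
            "triploid_fertilized": 0.0,
            "tetraploid_fertilized": 0.1,
        },
    )


def determine_sex(genome: CellGenome, csd: CsdLocus) -> str:
    """Sex of one cell line from its *csd* allele state.

    Returns ``"female"`` (>= 2 distinct csd alleles), ``"male"``
    (hemizygous single allele) or ``"diploid_male"`` (>= 2 copies, all
    identical). Raises if the genome carries no csd allele.
    """
    copies = genome.allele_multiset_at(csd)
    if not copies:
        raise ValueError("genome carries no csd allele")
    distinct = set(copies)
    if len(distinct) >= 2:
        return "female"
    return "male" if len(copies) == 1 else "diploid_male"


def apply_viability(
    egg: EggOutcome,
    policy: ViabilityPolicy,
    rng: Union[np.random.Generator, int, None] = None,
    csd: Optional[CsdLocus] = None,
) -> EggOutcome:
    """Set ``egg.viable`` (and per-line ``egg.sexes``) under a policy.

    A mosaic is sexed per cell line and counts as female if any line is
    female. Deterministic filters (karyotype balance, diploid-male
    removal) apply before the per-class Bernoulli draw.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if csd is not None:
        egg.sexes = [determine_sex(line, csd) for line in egg.cell_lines]
    if policy.require_balanced_karyotype and any(
        line.aneuploid_flag for line in egg.cell_lines
    ):
        egg.viable = False
        return egg
    if policy.remove_diploid_males and egg.sexes is not None:
        if "female" not in egg.sexes and "diploid_male" in egg.sexes:
            egg.viable = False
            return egg
    try:
        p = policy.class_viability[egg.true_class]
    except KeyError:
        raise KeyError(f"policy has no viability for class {egg.true_class!r}") from None
    egg.viable = bool(rng.uniform() < p)
    return egg
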