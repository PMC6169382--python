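"""Egg formation: composing meiotic products and sperm into offspring.

Haplodiploidy lets a honey-bee egg develop with or without
fertilisation, and polyspermy plus a thelytoky-competent maternal line
multiplies the possible fates of the four maternal pronuclei. This
module enumerates those fates as :class:`ReproductionMode`:

- ``ARRHENOTOKY``: one pronucleus survives unfertilised -> haploid male.
- ``FERTILIZED``: one pronucleus + one sperm -> diploid female.
- ``THELYTOKY``: the two central pronuclei fuse -> unfertilised diploid.
- ``THELYTOKY_THEN_FERTILIZED``: a thelytokous fusion nucleus is also
  fertilised -> triploid carrying two maternal and one paternal allele,
  the class that CO2-narcosed *A. m. capensis* queens produce at high
  frequency.
- ``TWO_SPERM_ONE_MATERNAL``: one pronucleus fuses with two sperm of
  different fathers -> triploid with one maternal and two paternal
  alleles.
- ``MOSAIC_TWO_ZYGOTES``: two pronuclei each fuse with a different
  sperm -> two diploid cell lines in one egg (microsatellites cannot
  distinguish this from a triploid; flow cytometry can).
- ``ANDROGENESIS``: a sperm nucleus alone clones the drone.
- ``TRIPLOID_QUEEN_EGG``: triploid meiosis; the egg carries either an
  unfused haploid or diploid oocyte nucleus (equally likely) or, with
  probability ``fusion_probability``, a triploid central-fusion
  nucleus; fertilisation then follows a cell-type-specific policy
  (worker cells mostly fertilised, drone cells mostly not).

Offspring keep their true class (the Table-3-style taxonomy of ploidy x
fertilisation) so that simulate-then-classify round trips can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .karyotype import CellGenome, MarkerPanel
from .meiosis import (
    CrossoverModel,
    apply_disjunction_errors,
    central_fusion,
    perform_meiosis,
    triploid_meiosis,
)

__all__ = [
    "ReproductionMode",
    "EggOutcome",
    "ModeMixture",
    "EggFormationParams",
    "sample_sperm",
    "fertilize",
    "make_egg",
    "simulate_brood",
    "TRUE_CLASSES",
]


class ReproductionMode(str, Enum):
    ARRHENOTOKY = "arrhenotoky"
    FERTILIZED = "fertilized"
    THELYTOKY = "thelytoky"
    THELYTOKY_THEN_FERTILIZED = "thelytoky_then_fertilized"
    TWO_SPERM_ONE_MATERNAL = "two_sperm_one_maternal"
    MOSAIC_TWO_ZYGOTES = "mosaic_two_zygotes"
    ANDROGENESIS = "androgenesis"
    TRIPLOID_QUEEN_EGG = "triploid_queen_egg"


#: The brood-class taxonomy used for truth labels and classifier calls.
TRUE_CLASSES = (
    "haploid",
    "diploid_unfertilized",
    "diploid_fertilized",
    "triploid_unfertilized",
    "triploid_fertilized",
    "tetraploid_fertilized",
)

WORKER_CELL = "worker_cell"
DRONE_CELL = "drone_cell"


@dataclass
class EggOutcome:
    """One egg: its cell line(s), provenance and truth labels."""

    cell_lines: list
    mode: ReproductionMode
    cell_type: str
    fertilized: bool
    sperm_donors: list
    true_class: str
    laid_by: str = "queen"
    stage: str = "egg"
    viable: Optional[bool] = None
    sexes: Optional[list] = None  # per cell line, set by sexdet_viability
    egg_id: Optional[str] = None

    def __post_init__(self):
        if self.fertilized != bool(self.sperm_donors):
            raise ValueError("fertilized must match presence of sperm donors")
        if len(self.cell_lines) < 1:
            raise ValueError("an egg has at least one cell line")

    @property
    def is_mosaic(self) -> bool:
        return len(self.cell_lines) > 1


@dataclass
class ModeMixture:
    """Per-cell-type probabilities over reproduction modes."""

    probabilities: dict  # cell_type -> {ReproductionMode: prob}

    def __post_init__(self):
        for cell_type, dist in self.probabilities.items():
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"mode probabilities for {cell_type} sum to {total}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ValueError("mode probabilities must be >= 0")

    def draw(self, cell_type: str, rng: np.random.Generator) -> ReproductionMode:
        dist = self.probabilities[cell_type]
        modes = list(dist)
        probs = np.array([dist[m] for m in modes], dtype=float)
        return modes[rng.choice(len(modes), p=probs / probs.sum())]


@dataclass(frozen=True)
class EggFormationParams:
    """Tunable rates of egg formation for a triploid queen.

    ``fusion_probability`` is the chance that the central pronuclei fuse
    into a triploid nucleus (default 0.2, calibrated to the observed
    drone-cell egg mix of a triploid queen, where fertilisation does not
    mask fusion). Fertilisation probabilities default to 0.85 (worker
    cells) and 0.05 (drone cells). ``haploid_pair_fusion_probability``
    enables an optional extra pathway — thelytokous fusion of the two
    haploid pronuclei — proposed to explain the excess of diploid over
    haploid oocytes; off by default. ``disjunction_error_rate`` feeds
    :func:`capensim.meiosis.apply_disjunction_errors`.
    """

    fusion_probability: float = 0.2
    p_fertilize_worker_cell: float = 0.85
    p_fertilize_drone_cell: float = 0.05
    haploid_pair_fusion_probability: float = 0.0
    disjunction_error_rate: float = 0.0

    def p_fertilize(self, cell_type: str) -> float:
        return (
            self.p_fertilize_worker_cell
            if cell_type == WORKER_CELL
            else self.p_fertilize_drone_cell
        )


def sample_sperm(drone: CellGenome) -> CellGenome:
    """A sperm cell from a drone.

    Drones are haploid, so every sperm cell of a drone is genetically
    identical: a copy of his genome.
    """
    if drone.ploidy != 1:
        raise ValueError(f"drones are haploid; got ploidy {drone.ploidy}")
    return drone.copy()


def fertilize(oocyte: CellGenome, sperm_list: Sequence[CellGenome]) -> CellGenome:
    """Fuse an oocyte nucleus with one or more sperm nuclei."""
    if not sperm_list:
        raise ValueError("fertilize requires at least one sperm")
    out = oocyte
    for sperm in sperm_list:
        if sperm.ploidy != 1:
            raise ValueError("sperm must be haploid")
        out = out.merged_with(sperm)
    return out


def _pick_drones(drones: Mapping[str, CellGenome], k: int, distinct: bool,
                 rng: np.random.Generator) -> list:
    ids = sorted(drones)
    if distinct and len(ids) < k:
        raise ValueError(f"mode requires {k} distinct drones, got {len(ids)}")
    chosen = rng.choice(len(ids), size=k, replace=not distinct)
    return [ids[i] for i in np.atleast_1d(chosen)]


def make_egg(
    queen: CellGenome,
    drones: Mapping[str, CellGenome],
    mode: ReproductionMode,
    cell_type: str,
    panel: MarkerPanel,
    xo: Optional[CrossoverModel] = None,
    rng: Union[np.random.Generator, int, None] = None,
    params: Optional[EggFormationParams] = None,
) -> EggOutcome:
    """Form one egg under the given reproduction mode.

    The queen must be diploid for every mode except
    ``TRIPLOID_QUEEN_EGG``, which requires a triploid queen.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    xo = xo or CrossoverModel()
    params = params or EggFormationParams()

    required = 3 if mode is ReproductionMode.TRIPLOID_QUEEN_EGG else 2
    if mode is not ReproductionMode.ANDROGENESIS and queen.ploidy != required:
        raise ValueError(
            f"mode {mode.value} requires a {required}n queen, got ploidy {queen.ploidy}"
        )

    if mode is ReproductionMode.TRIPLOID_QUEEN_EGG:
        return _triploid_queen_egg(queen, drones, cell_type, panel, xo, rng, params)

    if mode is ReproductionMode.ANDROGENESIS:
        donor = _pick_drones(drones, 1, False, rng)
        line = sample_sperm(drones[donor[0]])
        return EggOutcome([line], mode, cell_type, True, donor, "haploid")

    tetrad = perform_meiosis(queen, panel, xo, rng)
    if params.disjunction_error_rate > 0:
        tetrad = apply_disjunction_errors(tetrad, params.disjunction_error_rate, rng)

    def surviving_pronucleus() -> CellGenome:
        # which of the four pronuclei escapes degeneration: uniform
        return tetrad.products[rng.integers(4)].copy()

    if mode is ReproductionMode.ARRHENOTOKY:
        return EggOutcome([surviving_pronucleus()], mode, cell_type, False, [], "haploid")

    if mode is ReproductionMode.FERTILIZED:
        donor = _pick_drones(drones, 1, False, rng)
        line = fertilize(surviving_pronucleus(), [sample_sperm(drones[donor[0]])])
        return EggOutcome([line], mode, cell_type, True, donor, "diploid_fertilized")

    if mode is ReproductionMode.THELYTOKY:
        return EggOutcome(
            [central_fusion(tetrad)], mode, cell_type, False, [], "diploid_unfertilized"
        )

    if mode is ReproductionMode.THELYTOKY_THEN_FERTILIZED:
        # Sequential model: thelytokous fusion nucleus, then sperm fusion.
        # A simultaneous three-nucleus fusion is genotypically identical.
        donor = _pick_drones(drones, 1, False, rng)
        line = fertilize(central_fusion(tetrad), [sample_sperm(drones[donor[0]])])
        return EggOutcome([line], mode, cell_type, True, donor, "triploid_fertilized")

    if mode is ReproductionMode.TWO_SPERM_ONE_MATERNAL:
        donors = _pick_drones(drones, 2, True, rng)
        line = fertilize(
            surviving_pronucleus(), [sample_sperm(drones[d]) for d in donors]
        )
        return EggOutcome([line], mode, cell_type, True, donors, "triploid_fertilized")

    if mode is ReproductionMode.MOSAIC_TWO_ZYGOTES:
        donors = _pick_drones(drones, 2, False, rng)
        c1, c2 = tetrad.central
        lines = [
            fertilize(c1.copy(), [sample_sperm(drones[donors[0]])]),
            fertilize(c2.copy(), [sample_sperm(drones[donors[1]])]),
        ]
        return EggOutcome(
            lines, mode, cell_type, True, sorted(set(donors)), "diploid_fertilized"
        )

    raise ValueError(f"unhandled mode {mode}")


def _triploid_queen_egg(queen, drones, cell_type, panel, xo, rng, params) -> EggOutcome:
    tetrad = triploid_meiosis(queen, panel, xo, rng)
    if params.disjunction_error_rate > 0:
        tetrad = apply_disjunction_errors(tetrad, params.disjunction_error_rate, rng)
    u = rng.uniform()
    if u < params.fusion_probability:
        nucleus = central_fusion(tetrad)
        nominal = 3
    elif u < params.fusion_probability + params.haploid_pair_fusion_probability:
        # optional pathway: the two haploid (sister) pronuclei fuse
        haploids = [
            p for p in tetrad.products
            if all(len(cs) == 1 for cs in p.chromatids.values())
        ]
        if len(haploids) >= 2:
            nucleus = haploids[0].merged_with(haploids[1])
            nominal = 2
        else:  # disjunction errors removed the neat haploid pair
            nucleus = tetrad.products[rng.integers(4)].copy()
            nominal = max(len(cs) for cs in nucleus.chromatids.values())
    else:
        idx = rng.integers(4)
        nucleus = tetrad.products[idx].copy()
        # nominal ploidy by tetrad position, robust to disjunction errors
        counts = [max(len(cs) for cs in p.chromatids.values()) for p in tetrad.products]
        nominal = 2 if counts[idx] >= 2 else 1

    fert = rng.uniform() < params.p_fertilize(cell_type)
    if fert:
        donor = _pick_drones(drones, 1, False, rng)
        line = fertilize(nucleus, [sample_sperm(drones[donor[0]])])
        true_class = {1: "diploid_fertilized", 2: "triploid_fertilized",
                      3: "tetraploid_fertilized"}[nominal]
        return EggOutcome([line], ReproductionMode.TRIPLOID_QUEEN_EGG, cell_type,
                          True, donor, true_class)
    true_class = {1: "haploid", 2: "diploid_unfertilized",
                  3: "triploid_unfertilized"}[nominal]
    return EggOutcome([nucleus], ReproductionMode.TRIPLOID_QUEEN_EGG, cell_type,
                      False, [], true_class)


def simulate_brood(
    queen: CellGenome,
    drones: Mapping[str, CellGenome],
    mixture: ModeMixture,
    n_eggs: Mapping[str, int],
    panel: MarkerPanel,
    xo: Optional[CrossoverModel] = None,
    rng: Union[np.random.Generator, int, None] = None,
    params: Optional[EggFormationParams] = None,
    worker_laid_rate: float = 0.0,
    laying_workers: Optional[Sequence[CellGenome]] = None,
) -> list:
    """Simulate a brood nest: ``n_eggs[cell_type]`` eggs per cell type.

    Modes are drawn from ``mixture``; optionally a fraction
    ``worker_laid_rate`` of eggs are laid (arrhenotokously) by unrelated
    ``laying_workers`` instead of the queen — these carry alleles
    foreign to the queen/father set and model the worker-laid brood
    found in a triploid queen's drone cells.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    xo = xo or CrossoverModel()
    if worker_laid_rate > 0 and not laying_workers:
        raise ValueError("worker_laid_rate > 0 requires laying_workers")
    eggs = []
    for cell_type in sorted(n_eggs):
        for i in range(n_eggs[cell_type]):
            if worker_laid_rate > 0 and rng.uniform() < worker_laid_rate:
                worker = laying_workers[rng.integers(len(laying_workers))]
                egg = make_egg(worker, drones, ReproductionMode.ARRHENOTOKY,
                               cell_type, panel, xo, rng, params)
                egg.laid_by = "worker"
            else:
                mode = mixture.draw(cell_type, rng)
                egg = make_egg(queen, drones, mode, cell_type, panel, xo, rng, params)
            egg.egg_id = f"{cell_type}_{i:04d}"
            eggs.append(egg)
    return eggs
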