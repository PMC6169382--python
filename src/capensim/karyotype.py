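"""Chromosomes, marker loci and genomes at arbitrary ploidy.

The honey bee (*Apis mellifera*) karyotype has n = 16 chromosomes; males
develop from unfertilized (haploid) eggs and females from fertilized
(diploid) eggs, but thelytokous lineages such as *A. m. capensis* also
produce diploid, triploid and tetraploid individuals through fusion of
meiotic products and multiple fertilisation. This module provides the
ploidy-agnostic genome representation the simulator and classifier share:
a genome is a multiset of chromatids per chromosome, each chromatid
carrying microsatellite alleles (opaque integer fragment sizes) plus a
founder-origin label per allele, so that maternal/paternal provenance can
be recovered exactly in simulated crosses.

Genetic positions are distances from the centromere in Morgans. The
microsatellite panels used in the crosses this package models give no map
positions, so positions are free parameters (default 0.2 M) and panel loci
sit on distinct chromosomes to avoid unmodelled linkage.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Union

__all__ = [
    "MarkerLocus",
    "CsdLocus",
    "MarkerPanel",
    "Chromatid",
    "CellGenome",
    "ploidy_of",
    "allele_set_at",
    "founder_genome",
    "read_panel_csv",
    "write_panel_csv",
]

#: Honey-bee haploid chromosome number.
HONEYBEE_CHROMOSOME_COUNT = 16

#: Default locus-to-centromere distance (Morgans) when a map gives none.
DEFAULT_CENTROMERE_DISTANCE = 0.2


@dataclass(frozen=True)
class MarkerLocus:
    """A microsatellite marker locus.

    Parameters
    ----------
    id
        Short label, e.g. ``"A8"``.
    chromosome
        1-based chromosome index.
    centromere_distance
        Genetic distance from the centromere, in Morgans (>= 0).
    allele_alphabet
        Allele labels (integer fragment sizes) segregating at the locus.
    """

    id: str
    chromosome: int
    centromere_distance: float = DEFAULT_CENTROMERE_DISTANCE
    allele_alphabet: frozenset = frozenset()

    def __post_init__(self):
        if self.chromosome < 1:
            raise ValueError(f"chromosome must be >= 1, got {self.chromosome}")
        if self.centromere_distance < 0:
            raise ValueError("centromere_distance must be >= 0")
        object.__setattr__(self, "allele_alphabet", frozenset(self.allele_alphabet))


@dataclass(frozen=True)
class CsdLocus(MarkerLocus):
    """The complementary sex determiner (*csd*) locus.

    Heterozygosity at *csd* triggers female development; hemizygotes are
    normal males and homozygous diploids are diploid males (removed by
    workers in honey bees). Shaped like a marker locus with its own
    allele alphabet; exactly one per panel.
    """


class MarkerPanel:
    """An ordered set of marker loci plus the single *csd* locus.

    Locus ids must be unique and every locus must sit on a chromosome
    index within ``chromosome_count`` (default 16, the honey-bee
    karyotype).
    """

    def __init__(
        self,
        loci: Iterable[MarkerLocus],
        csd: CsdLocus,
        chromosome_count: int = HONEYBEE_CHROMOSOME_COUNT,
    ):
        self.loci = list(loci)
        self.csd = csd
        self.chromosome_count = chromosome_count
        ids = [loc.id for loc in self.all_loci]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate locus ids in panel: {ids}")
        for loc in self.all_loci:
            if loc.chromosome > chromosome_count:
                raise ValueError(
                    f"locus {loc.id} on chromosome {loc.chromosome} "
                    f"> chromosome_count {chromosome_count}"
                )
        self._by_id = {loc.id: loc for loc in self.all_loci}

    @property
    def all_loci(self) -> list:
        """Marker loci followed by the csd locus."""
        return self.loci + [self.csd]

    def locus(self, locus_id: str) -> MarkerLocus:
        try:
            return self._by_id[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus id {locus_id!r}") from None

    def loci_on(self, chromosome: int) -> list:
        return [loc for loc in self.all_loci if loc.chromosome == chromosome]

    @property
    def chromosomes_with_loci(self) -> list:
        return sorted({loc.chromosome for loc in self.all_loci})

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MarkerPanel)
            and self.loci == other.loci
            and self.csd == other.csd
            and self.chromosome_count == other.chromosome_count
        )

    def __repr__(self) -> str:
        return (
            f"MarkerPanel({len(self.loci)} marker loci + csd, "
            f"{self.chromosome_count} chromosomes)"
        )


@dataclass
class Chromatid:
    """One chromatid: alleles and founder-origin labels keyed by locus id.

    ``origin[locus_id]`` records which founder copy the allele descends
    from (e.g. ``"Q.0"`` for the queen's first homolog or a drone id);
    recombination transfers origin labels together with alleles.
    ``centromere_origin`` tracks the founder copy of the centromere, which
    segregation (unlike crossover) follows.
    """

    chromosome: int
    alleles: dict = field(default_factory=dict)
    origin: dict = field(default_factory=dict)
    centromere_origin: str = ""

    def copy(self) -> "Chromatid":
        return Chromatid(
            chromosome=self.chromosome,
            alleles=dict(self.alleles),
            origin=dict(self.origin),
            centromere_origin=self.centromere_origin,
        )


class CellGenome:
    """A genome as a multiset of chromatids per chromosome.

    ``chromatids`` maps chromosome index -> list of :class:`Chromatid`.
    A well-formed euploid genome carries the same number of copies of
    every chromosome; after disjunction errors copy numbers may differ
    and ``aneuploid_flag`` is set.
    """

    def __init__(self, chromatids: Mapping[int, list], aneuploid_flag: bool = False):
        self.chromatids = {ch: list(cs) for ch, cs in chromatids.items()}
        self.aneuploid_flag = aneuploid_flag
        for ch, cs in self.chromatids.items():
            for c in cs:
                if c.chromosome != ch:
                    raise ValueError(
                        f"chromatid for chromosome {c.chromosome} filed under {ch}"
                    )

    def copy(self) -> "CellGenome":
        return CellGenome(
            {ch: [c.copy() for c in cs] for ch, cs in self.chromatids.items()},
            aneuploid_flag=self.aneuploid_flag,
        )

    @property
    def ploidy(self) -> Union[int, Literal["aneuploid"]]:
        return ploidy_of(self)

    def copy_number(self, chromosome: int) -> int:
        return len(self.chromatids.get(chromosome, []))

    def allele_multiset_at(self, locus: MarkerLocus) -> list:
        """Alleles at `locus` with multiplicity, in chromatid order."""
        out = []
        for c in self.chromatids.get(locus.chromosome, []):
            if locus.id in c.alleles:
                out.append(c.alleles[locus.id])
        return out

    def merged_with(self, other: "CellGenome") -> "CellGenome":
        """Union of two nuclei (pronuclear fusion / fertilisation)."""
        chroms = {ch: [c.copy() for c in cs] for ch, cs in self.chromatids.items()}
        for ch, cs in other.chromatids.items():
            chroms.setdefault(ch, []).extend(c.copy() for c in cs)
        return CellGenome(
            chroms, aneuploid_flag=self.aneuploid_flag or other.aneuploid_flag
        )


def ploidy_of(genome: CellGenome) -> Union[int, Literal["aneuploid"]]:
    """Uniform chromosome copy number, or ``"aneuploid"`` when copies differ.

    Raises ``ValueError`` on an empty genome.
    """
    counts = {len(cs) for cs in genome.chromatids.values()}
    if not counts:
        raise ValueError("empty genome has no ploidy")
    if len(counts) == 1:
        return counts.pop()
    return "aneuploid"


def allele_set_at(genome: CellGenome, locus: MarkerLocus) -> set:
    """Deduplicated allele set observed at `locus`.

    This is what a microsatellite electropherogram shows: distinct
    fragment sizes, without dosage. Its size never exceeds the copy
    number of the locus's chromosome.
    """
    return set(genome.allele_multiset_at(locus))


def founder_genome(
    panel: MarkerPanel,
    alleles_per_locus: Mapping[str, tuple],
    label: str,
) -> CellGenome:
    """Build a founder genome from per-locus allele tuples.

    Every locus (including csd) must map to a tuple of the same length
    ``k`` = the founder's ploidy; copy ``i`` of each chromosome carries
    allele ``alleles_per_locus[locus][i]`` with origin label
    ``"{label}.{i}"``. Chromosomes without loci still get ``k`` (empty)
    chromatids so that whole-genome ploidy is well defined.
    """
    ploidies = {len(v) for v in alleles_per_locus.values()}
    if len(ploidies) != 1:
        raise ValueError("all loci must list the same number of allele copies")
    k = ploidies.pop()
    chroms: dict = {
        ch: [
            Chromatid(chromosome=ch, centromere_origin=f"{label}.{i}")
            for i in range(k)
        ]
        for ch in range(1, panel.chromosome_count + 1)
    }
    for loc in panel.all_loci:
        copies = alleles_per_locus[loc.id]
        for i, allele in enumerate(copies):
            chrom = chroms[loc.chromosome][i]
            chrom.alleles[loc.id] = allele
            chrom.origin[loc.id] = f"{label}.{i}"
    return CellGenome(chroms)


# ---------------------------------------------------------------------------
# Panel I/O: CSV with columns locus_id,chromosome,centromere_distance_M,alleles
# (alleles semicolon-separated). The row whose locus_id is "csd" defines the
# sex locus.


def write_panel_csv(panel: MarkerPanel, path) -> None:
    lines = ["locus_id,chromosome,centromere_distance_M,alleles"]
    for loc in panel.all_loci:
        alleles = ";".join(str(a) for a in sorted(loc.allele_alphabet))
        lines.append(f"{loc.id},{loc.chromosome},{loc.centromere_distance},{alleles}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel_csv(path, chromosome_count: int = HONEYBEE_CHROMOSOME_COUNT) -> MarkerPanel:
    import csv as _csv

    loci, csd = [], None
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            kwargs = dict(
                id=row["locus_id"],
                chromosome=int(row["chromosome"]),
                centromere_distance=float(row["centromere_distance_M"]),
                allele_alphabet=frozenset(
                    int(a) for a in row["alleles"].split(";") if a
                ),
            )
            if row["locus_id"].lower() == "csd":
                csd = CsdLocus(**kwargs)
            else:
                loci.append(MarkerLocus(**kwargs))
    if csd is None:
        raise ValueError(f"panel file {path} has no 'csd' row")
    return MarkerPanel(loci, csd, chromosome_count=chromosome_count)
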