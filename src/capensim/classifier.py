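"""Microsatellite-based ploidy, fertilisation and origin inference.

Given per-locus observed allele sets for an offspring plus the queen's
and candidate fathers' genotypes, infer:

- allele origin per observed allele: *maternal* (queen only),
  *paternal* (a father only), *shared* (both) or *foreign* (neither —
  evidence of worker-laid brood);
- ploidy: from the pattern of distinct-allele counts (3 alleles at
  multiple loci indicate triploidy; a locus with 4 alleles, or 3
  maternal-consistent alleles in a fertilised individual, indicates
  tetraploidy);
- fertilisation: presence of strictly paternal alleles;
- paternity in multi-drone crosses;

and combine them into a class label from the brood taxonomy
(haploid ... tetraploid_fertilized).

Heuristics worth noting (the field data never state an explicit rule):
triploid vs tetraploid is resolved parsimoniously toward the lower
ploidy unless a locus demands four allele copies; loss of
heterozygosity can make a thelytokous diploid look haploid at
individual loci, so a haploid call requires *every* typed locus to be
single-allele; shared alleles never count as fertilisation evidence on
their own; a worker-laid call requires foreign alleles at two or more
loci to guard against single-locus genotyping error.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .karyotype import CellGenome, MarkerPanel, allele_set_at
from .reproduction import EggOutcome

__all__ = [
    "GenotypeRecord",
    "ClassCall",
    "CallThresholds",
    "observe_genotype",
    "genotype_of",
    "assign_allele_origin",
    "call_class",
    "paternity_assign",
    "tabulate_classes",
]


@dataclass
class GenotypeRecord:
    """Observed per-locus allele sets for one individual.

    ``calls`` maps locus id -> frozenset of observed alleles; an empty
    set means the locus failed to amplify (missing data).
    """

    individual_id: str
    stage: str = "egg"
    cell_type: str = "worker_cell"
    tissue: Optional[str] = None
    calls: dict = field(default_factory=dict)

    def __post_init__(self):
        self.calls = {k: frozenset(v) for k, v in self.calls.items()}

    @property
    def typed_loci(self) -> list:
        return [l for l, s in self.calls.items() if s]


@dataclass
class CallThresholds:
    """Evidence thresholds for class calling.

    ``min_loci_multiallele``: loci with >= 3 alleles needed to raise a
    ploidy call above 2 (default 2; the stricter "at least four of
    seven loci" rule used to select cytometry specimens is available by
    configuration). ``min_loci_typed``: below this many amplified loci
    an individual is unclassifiable. ``paternal_evidence_loci``: loci
    with strictly paternal alleles required to call fertilisation.
    """

    min_loci_multiallele: int = 2
    min_loci_typed: int = 4
    paternal_evidence_loci: int = 1

    def __post_init__(self):
        for name in ("min_loci_multiallele", "min_loci_typed", "paternal_evidence_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ClassCall:
    """The inferred class of one individual."""

    individual_id: str
    ploidy_call: Union[int, str]  # 1|2|3|4|"ambiguous"
    fertilized_call: str  # "yes"|"no"|"ambiguous"
    origin_call: str  # "queen_laid"|"worker_laid"|"ambiguous"
    class_label: str  # taxonomy label or "unclassifiable"
    supporting_loci: int


def genotype_of(genome: CellGenome, panel: MarkerPanel) -> dict:
    """Per-locus observed allele sets of a genome (marker loci only)."""
    return {loc.id: frozenset(allele_set_at(genome, loc)) for loc in panel.loci}


def observe_genotype(
    egg: EggOutcome,
    panel: MarkerPanel,
    dropout_rate: float = 0.0,
    tissue: str = "hind-leg",
    rng: Union[np.random.Generator, int, None] = None,
    pool_lines: bool = False,
) -> GenotypeRecord:
    """Simulate genotyping one tissue of an egg or bee.

    By default a mosaic individual reports only the cell line the
    sampled tissue descends from; the tissue-to-line assignment is a
    stable hash of the tissue name, so repeat PCRs of the same tissue
    (and any tissue of a non-mosaic) agree. With ``pool_lines`` the
    tissue is a mixture of all cell lines — the regime in which a
    diploid mosaic is genotypically indistinguishable from a triploid.
    Each locus independently fails to amplify with probability
    ``dropout_rate``.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if pool_lines:
        lines = egg.cell_lines
    else:
        lines = [egg.cell_lines[zlib.crc32(tissue.encode()) % len(egg.cell_lines)]]
    calls = {}
    for loc in panel.loci:
        if dropout_rate > 0 and rng.uniform() < dropout_rate:
            calls[loc.id] = frozenset()
        else:
            calls[loc.id] = frozenset().union(
                *(allele_set_at(line, loc) for line in lines)
            )
    return GenotypeRecord(
        individual_id=egg.egg_id or "egg",
        stage=egg.stage,
        cell_type=egg.cell_type,
        tissue=tissue,
        calls=calls,
    )


MATERNAL, PATERNAL, SHARED, FOREIGN = "maternal", "paternal", "shared", "foreign"


def assign_allele_origin(
    rec: GenotypeRecord,
    queen: Mapping[str, frozenset],
    fathers: Mapping[str, Mapping[str, frozenset]],
) -> dict:
    """Label every observed allele by parental origin.

    Returns ``{locus_id: {allele: label}}`` with labels ``maternal``,
    ``paternal`` (some father, not the queen), ``shared`` (queen and a
    father) or ``foreign`` (neither — not attributable to the cross).
    """
    if not fathers:
        raise ValueError("at least one father genotype is required")
    out = {}
    for locus, alleles in rec.calls.items():
        if not alleles:
            continue
        if locus not in queen:
            raise KeyError(f"locus {locus!r} absent from queen genotype")
        q = queen[locus]
        p = set()
        for fid, geno in fathers.items():
            if locus not in geno:
                raise KeyError(f"locus {locus!r} absent from father {fid!r}")
            p |= set(geno[locus])
        labels = {}
        for a in alleles:
            if a in q and a in p:
                labels[a] = SHARED
            elif a in q:
                labels[a] = MATERNAL
            elif a in p:
                labels[a] = PATERNAL
            else:
                labels[a] = FOREIGN
        out[locus] = labels
    return out


def call_class(
    rec: GenotypeRecord,
    queen: Mapping[str, frozenset],
    fathers: Mapping[str, Mapping[str, frozenset]],
    thresholds: Optional[CallThresholds] = None,
) -> ClassCall:
    """Infer ploidy, fertilisation and origin for one individual."""
    th = thresholds or CallThresholds()
    typed = rec.typed_loci
    n_typed = len(typed)
    if n_typed < th.min_loci_typed:
        return ClassCall(rec.individual_id, "ambiguous", "ambiguous", "ambiguous",
                         "unclassifiable", n_typed)

    origins = assign_allele_origin(rec, queen, fathers)

    def labels_at(locus):
        return origins.get(locus, {})

    foreign_loci = sum(
        1 for l in typed if any(v == FOREIGN for v in labels_at(l).values())
    )
    origin_call = "worker_laid" if foreign_loci >= 2 else "queen_laid"

    paternal_loci = sum(
        1 for l in typed if any(v == PATERNAL for v in labels_at(l).values())
    )
    if paternal_loci >= th.paternal_evidence_loci:
        fertilized = "yes"
    elif paternal_loci == 0:
        fertilized = "no"
    else:
        fertilized = "ambiguous"

    # --- ploidy from distinct-allele patterns -------------------------
    multi3 = [l for l in typed if len(rec.calls[l]) >= 3]
    if len(multi3) >= th.min_loci_multiallele:
        # triploid unless some locus demands four allele copies:
        # either 4 distinct alleles, or (in a fertilised individual)
        # 3 alleles all maternal-consistent — the single paternal copy
        # must then hide inside a shared allele, implying 3 maternal
        # copies + 1 paternal = 4.
        tetra_loci = [
            l for l in multi3
            if len(rec.calls[l]) >= 4
            or (
                fertilized == "yes"
                and not any(v == PATERNAL for v in labels_at(l).values())
                and all(v in (MATERNAL, SHARED) for v in labels_at(l).values())
            )
        ]
        if fertilized == "yes" and tetra_loci:
            ploidy: Union[int, str] = 4
        else:
            ploidy = 3
        support = len(multi3)
    else:
        # 1 vs 2: loss of heterozygosity can silence individual loci,
        # so haploidy requires single alleles at *every* typed locus.
        maternal_het_loci = [
            l for l in typed
            if sum(1 for v in labels_at(l).values() if v in (MATERNAL, SHARED)) >= 2
        ]
        all_single = all(len(rec.calls[l]) == 1 for l in typed)
        if fertilized == "yes":
            all_paternal_only = all(
                all(v == PATERNAL for v in labels_at(l).values()) for l in typed
            )
            if all_single and all_paternal_only:
                ploidy = 1  # androgenetic: a clone of the sperm donor
            else:
                ploidy = 2
            support = paternal_loci
        elif all_single:
            ploidy = 1
            support = n_typed
        else:
            ploidy = 2
            support = len(maternal_het_loci) or sum(
                1 for l in typed if len(rec.calls[l]) >= 2
            )

    label = _class_label(ploidy, fertilized)
    return ClassCall(rec.individual_id, ploidy, fertilized, origin_call, label, support)


def _class_label(ploidy, fertilized) -> str:
    if fertilized == "ambiguous" or ploidy == "ambiguous":
        return "unclassifiable"
    key = {
        (1, "no"): "haploid",
        (1, "yes"): "haploid",  # androgenetic clone of the drone
        (2, "no"): "diploid_unfertilized",
        (2, "yes"): "diploid_fertilized",
        (3, "no"): "triploid_unfertilized",
        (3, "yes"): "triploid_fertilized",
        (4, "yes"): "tetraploid_fertilized",
    }
    return key.get((ploidy, fertilized), "unclassifiable")


def paternity_assign(
    rec: GenotypeRecord,
    queen: Mapping[str, frozenset],
    fathers: Mapping[str, Mapping[str, frozenset]],
) -> str:
    """The unique father compatible with all paternal-labelled alleles.

    A father is compatible when he carries every strictly paternal
    allele the offspring shows. Returns the father id, or
    ``"ambiguous"`` when zero or several fathers are compatible (e.g.
    no strictly paternal allele was observed).
    """
    if len(fathers) < 2:
        raise ValueError("paternity assignment needs >= 2 candidate fathers")
    origins = assign_allele_origin(rec, queen, fathers)
    paternal = {
        (locus, a)
        for locus, labels in origins.items()
        for a, v in labels.items()
        if v == PATERNAL
    }
    compatible = [
        fid
        for fid, geno in fathers.items()
        if all(a in geno[locus] for locus, a in paternal)
    ]
    if len(compatible) == 1:
        return compatible[0]
    return "ambiguous"


#: Row order of the brood-class tabulation.
TABLE_CLASS_ORDER = (
    "tetraploid_fertilized",
    "triploid_unfertilized",
    "triploid_fertilized",
    "diploid_fertilized",
    "diploid_unfertilized",
    "haploid",
    "worker_laid",
    "unclassifiable",
)


def tabulate_classes(
    records: Sequence[GenotypeRecord],
    calls: Sequence[ClassCall],
    group_by: tuple = ("stage", "cell_type"),
) -> pd.DataFrame:
    """Count class calls per stratum (stage x cell type by default).

    Worker-laid individuals are tallied in their own row regardless of
    their ploidy call, mirroring how worker-laid pupae are reported
    separately from the queen's own brood. A ``Total`` row closes the
    table.
    """
    strata = sorted(
        {tuple(getattr(r, f) for f in group_by) for r in records}
    )
    cols = (
        pd.MultiIndex.from_tuples(strata, names=list(group_by))
        if strata
        else pd.MultiIndex.from_tuples([], names=list(group_by))
    )
    table = pd.DataFrame(0, index=list(TABLE_CLASS_ORDER), columns=cols, dtype=int)
    for rec, call in zip(records, calls):
        stratum = tuple(getattr(rec, f) for f in group_by)
        row = "worker_laid" if call.origin_call == "worker_laid" else call.class_label
        table.loc[row, stratum] += 1
    totals = pd.DataFrame(
        [table.sum(axis=0)], index=["Total"], columns=table.columns, dtype=int
    )
    return pd.concat([table, totals])
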