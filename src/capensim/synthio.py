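"""Synthetic crosses, genotype-table I/O and end-to-end experiment runs.

Three crossing designs are modelled, mirroring the study system this
package simulates:

1. Reciprocal single-drone crosses between a thelytoky-competent
   (*capensis*-like) queen and an arrhenotokous (*scutellata*-like)
   drone — the design in which a fraction of offspring turn out to
   carry two maternal alleles and one paternal allele.
2. Queens inseminated with four unrelated drones, for paternity x
   ploidy cross-tabulation and for picking 2-allele vs 3-allele
   specimens for flow cytometry.
3. A triploid queen inseminated with a single drone, whose brood spans
   haploid to tetraploid classes.

Everything is seeded: one global seed is expanded into independent
per-stage streams (founders, brood, genotyping dropout, viability) so
stages can be re-run in isolation and output files are byte-identical
across runs.

Genotype tables use a long CSV schema
``individual_id,stage,cell_type,tissue,locus_id,alleles`` with alleles
joined by ``";"`` and an empty field for a missing genotype; parental
genotypes use the same schema. Spreadsheet-shaped external tables can
be adapted by renaming columns onto this schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .karyotype import (
    CellGenome,
    CsdLocus,
    MarkerLocus,
    MarkerPanel,
    founder_genome,
)
from .classifier import (
    CallThresholds,
    GenotypeRecord,
    call_class,
    genotype_of,
    observe_genotype,
    tabulate_classes,
)
from .meiosis import CrossoverModel
from .reproduction import (
    DRONE_CELL,
    WORKER_CELL,
    EggFormationParams,
    ModeMixture,
    ReproductionMode,
    simulate_brood,
)
from .sexdet_viability import (
    ViabilityPolicy,
    apply_viability,
    diploid_queen_policy,
    triploid_queen_policy,
)

__all__ = [
    "CrossDesign",
    "make_panel",
    "default_named_panel",
    "draw_founders",
    "build_cross",
    "run_experiment",
    "write_genotype_table",
    "read_genotype_table",
    "write_parent_genotypes",
    "read_parent_genotypes",
    "load_design_yaml",
    "load_policy_yaml",
]

#: The seven-locus microsatellite panel used for worker genotyping.
EXPERIMENT2_LOCI = ("A8", "A29", "A79", "A88", "A113", "B124", "Ap43")
#: The six-locus panel used to type queens and triploid-queen brood.
EXPERIMENT3_LOCI = ("A14", "A29", "A88", "A107", "A113", "B124")


@dataclass
class CrossDesign:
    """A crossing design: founders, mode mixture and brood sizes.

    ``three_allele_rate`` is the fraction of worker-cell eggs formed by
    fertilisation of a thelytokous fusion nucleus in experiments 1-2
    (default 0.14, the average per-colony rate induced by CO2
    narcosis). Experiment 3 uses a triploid queen and the
    triploid-queen egg mode instead.
    """

    experiment: int = 1
    n_drones: int = 1
    queen_ploidy: int = 2
    three_allele_rate: float = 0.14
    n_eggs: dict = field(default_factory=lambda: {WORKER_CELL: 200})
    fully_informative: bool = True
    worker_laid_rate: float = 0.0
    egg_params: EggFormationParams = field(default_factory=EggFormationParams)
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2 or 3")
        if self.experiment == 3 and self.queen_ploidy != 3:
            raise ValueError("experiment 3 requires a triploid queen")
        if self.experiment == 2 and self.n_drones != 4:
            raise ValueError("experiment 2 uses 4 unrelated drones")
        if self.experiment in (1, 3) and self.n_drones != 1:
            raise ValueError(f"experiment {self.experiment} uses a single drone")


def _experiment_defaults(experiment: int) -> "CrossDesign":
    if experiment == 1:
        return CrossDesign(experiment=1)
    if experiment == 2:
        return CrossDesign(experiment=2, n_drones=4)
    return CrossDesign(
        experiment=3,
        queen_ploidy=3,
        n_drones=1,
        n_eggs={WORKER_CELL: 186, DRONE_CELL: 48},
        worker_laid_rate=0.0,
    )


CrossDesign.for_experiment = staticmethod(_experiment_defaults)


def make_panel(
    n_loci: int = 7,
    alleles_per_locus: int = 6,
    rng: Union[np.random.Generator, int, None] = None,
    locus_ids: Optional[Sequence[str]] = None,
    centromere_distance: float = 0.2,
    chromosome_count: int = 16,
) -> MarkerPanel:
    """A random multi-allelic panel on distinct chromosomes.

    Allele labels imitate microsatellite fragment sizes (distinct even
    integers per locus). The csd locus gets at least six alleles, as
    expected for a locus under strong balancing selection.
    """
    if n_loci < 1 or alleles_per_locus < 1:
        raise ValueError("n_loci and alleles_per_locus must be >= 1")
    if n_loci + 1 > chromosome_count:
        raise ValueError("need a free chromosome per locus plus one for csd")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ids = list(locus_ids) if locus_ids else [f"L{i+1}" for i in range(n_loci)]
    if len(ids) != n_loci:
        raise ValueError("locus_ids length must equal n_loci")
    loci = []
    for i, locus_id in enumerate(ids):
        sizes = 100 + 2 * rng.choice(100, size=alleles_per_locus, replace=False)
        loci.append(
            MarkerLocus(
                id=locus_id,
                chromosome=i + 1,
                centromere_distance=centromere_distance,
                allele_alphabet=frozenset(int(s) for s in sizes),
            )
        )
    n_csd = max(6, alleles_per_locus)
    csd_alleles = 1 + rng.choice(50, size=n_csd, replace=False)
    csd = CsdLocus(
        id="csd",
        chromosome=n_loci + 1,
        centromere_distance=centromere_distance,
        allele_alphabet=frozenset(int(a) for a in csd_alleles),
    )
    return MarkerPanel(loci, csd, chromosome_count=chromosome_count)


def default_named_panel(experiment: int = 2,
                        rng: Union[np.random.Generator, int, None] = 0) -> MarkerPanel:
    """The named microsatellite panel for an experiment (7 or 6 loci)."""
    ids = EXPERIMENT3_LOCI if experiment == 3 else EXPERIMENT2_LOCI
    return make_panel(n_loci=len(ids), rng=rng, locus_ids=ids)


def draw_founders(
    panel: MarkerPanel,
    queen_ploidy: int,
    n_drones: int,
    rng: Union[np.random.Generator, int, None] = None,
    fully_informative: bool = True,
) -> Tuple[CellGenome, dict]:
    """Sample a queen and drone genomes from the panel's alphabets.

    With ``fully_informative`` every founder allele copy at every locus
    is distinct (requires alphabets of size >= queen_ploidy +
    n_drones), so allele origin is unambiguous — the regime in which
    classification is exact. Otherwise copies are drawn independently
    with replacement and queen/drone allele sharing can occur.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    need = queen_ploidy + n_drones
    queen_alleles, drone_alleles = {}, {i: {} for i in range(n_drones)}
    for loc in panel.all_loci:
        alphabet = sorted(loc.allele_alphabet)
        if fully_informative:
            if len(alphabet) < need:
                raise ValueError(
                    f"locus {loc.id}: {len(alphabet)} alleles < {need} founder copies"
                )
            picks = rng.choice(len(alphabet), size=need, replace=False)
            chosen = [alphabet[i] for i in picks]
        else:
            picks = rng.choice(len(alphabet), size=need, replace=True)
            chosen = [alphabet[i] for i in picks]
        queen_alleles[loc.id] = tuple(chosen[:queen_ploidy])
        for i in range(n_drones):
            drone_alleles[i][loc.id] = (chosen[queen_ploidy + i],)
    queen = founder_genome(panel, queen_alleles, "Q")
    drones = {
        f"D{i+1}": founder_genome(panel, drone_alleles[i], f"D{i+1}")
        for i in range(n_drones)
    }
    return queen, drones


def build_cross(
    design: CrossDesign,
    panel: MarkerPanel,
    rng: Union[np.random.Generator, int, None] = None,
) -> Tuple[CellGenome, dict, ModeMixture]:
    """Founder genomes and the mode mixture implied by a design."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    queen, drones = draw_founders(
        panel, design.queen_ploidy, design.n_drones, rng,
        fully_informative=design.fully_informative,
    )
    if design.experiment == 3:
        dist = {ReproductionMode.TRIPLOID_QUEEN_EGG: 1.0}
        mixture = ModeMixture({ct: dict(dist) for ct in design.n_eggs})
    else:
        r = design.three_allele_rate
        mixture = ModeMixture(
            {
                ct: {
                    ReproductionMode.FERTILIZED: 1.0 - r,
                    ReproductionMode.THELYTOKY_THEN_FERTILIZED: r,
                }
                for ct in design.n_eggs
            }
        )
    return queen, drones, mixture


def run_experiment(
    design: CrossDesign,
    out_dir,
    seed: int = 0,
    panel: Optional[MarkerPanel] = None,
    thresholds: Optional[CallThresholds] = None,
    policy: Optional[ViabilityPolicy] = None,
    xo: Optional[CrossoverModel] = None,
) -> dict:
    """Simulate a cross end to end and write all artifacts.

    Writes, under ``out_dir``: ``panel.csv``, ``parents.csv``,
    ``genotypes.csv`` (egg-stage records for every egg plus pupa-stage
    records for survivors), ``truth.csv``, ``class_calls.csv`` and
    ``summary.tsv`` (the brood-class count table). Identical seeds give
    identical bytes. Returns the in-memory objects for further use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_founders, rng_brood, rng_dropout, rng_viab = (
        np.random.default_rng(s) for s in streams
    )
    panel = panel or default_named_panel(design.experiment, rng=rng_founders)
    thresholds = thresholds or CallThresholds()
    policy = policy or (
        triploid_queen_policy() if design.experiment == 3 else diploid_queen_policy()
    )
    xo = xo or CrossoverModel()

    queen, drones, mixture = build_cross(design, panel, rng_founders)
    laying_workers = None
    if design.worker_laid_rate > 0:
        # unrelated workers from an independent founder draw
        lw_queen, lw_drones = draw_founders(panel, 2, 1, rng_founders,
                                            fully_informative=False)
        laying_workers = [lw_queen]
    eggs = simulate_brood(
        queen, drones, mixture, design.n_eggs, panel, xo, rng_brood,
        params=design.egg_params, worker_laid_rate=design.worker_laid_rate,
        laying_workers=laying_workers,
    )
    normal_policy = diploid_queen_policy()
    for egg in eggs:
        apply_viability(
            egg, normal_policy if egg.laid_by == "worker" else policy,
            rng_viab, csd=panel.csd,
        )

    records = []
    for egg in eggs:
        records.append(observe_genotype(egg, panel, design.dropout_rate,
                                        "hind-leg", rng_dropout))
        if egg.viable:
            pupa = observe_genotype(egg, panel, design.dropout_rate,
                                    "hind-leg", rng_dropout)
            pupa.individual_id = f"{egg.egg_id}_pupa"
            pupa.stage = "pupa"
            records.append(pupa)

    queen_geno = genotype_of(queen, panel)
    father_genos = {fid: genotype_of(g, panel) for fid, g in drones.items()}
    calls = [call_class(r, queen_geno, father_genos, thresholds) for r in records]

    # --- write artifacts ---------------------------------------------
    from .karyotype import write_panel_csv

    write_panel_csv(panel, out / "panel.csv")
    write_parent_genotypes(queen_geno, father_genos, out / "parents.csv")
    write_genotype_table(records, out / "genotypes.csv")

    truth = pd.DataFrame(
        [
            dict(
                egg_id=e.egg_id, cell_type=e.cell_type, stage=e.stage,
                true_mode=e.mode.value, true_class=e.true_class,
                ploidy=e.cell_lines[0].ploidy, viable=e.viable,
                laid_by=e.laid_by,
            )
            for e in eggs
        ]
    )
    truth.to_csv(out / "truth.csv", index=False)

    call_df = pd.DataFrame(
        [
            dict(
                individual_id=c.individual_id, stage=r.stage,
                cell_type=r.cell_type, ploidy_call=c.ploidy_call,
                fertilized_call=c.fertilized_call, origin_call=c.origin_call,
                class_label=c.class_label, supporting_loci=c.supporting_loci,
            )
            for r, c in zip(records, calls)
        ]
    )
    call_df.to_csv(out / "class_calls.csv", index=False)

    summary = tabulate_classes(records, calls)
    summary.to_csv(out / "summary.tsv", sep="\t")

    return dict(panel=panel, queen=queen, drones=drones, eggs=eggs,
                records=records, calls=calls, summary=summary)


# --- genotype-table I/O ----------------------------------------------------

GENOTYPE_COLUMNS = ["individual_id", "stage", "cell_type", "tissue",
                    "locus_id", "alleles"]


def _join(alleles) -> str:
    return ";".join(str(a) for a in sorted(alleles))


def write_genotype_table(records: Sequence[GenotypeRecord], path) -> None:
    rows = []
    for rec in records:
        for locus_id in sorted(rec.calls):
            rows.append(
                dict(
                    individual_id=rec.individual_id, stage=rec.stage,
                    cell_type=rec.cell_type, tissue=rec.tissue or "",
                    locus_id=locus_id, alleles=_join(rec.calls[locus_id]),
                )
            )
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, index=False)


def read_genotype_table(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for (iid, stage, cell_type, tissue), sub in df.groupby(
        ["individual_id", "stage", "cell_type", "tissue"], sort=True
    ):
        calls = {
            row.locus_id: frozenset(
                int(a) for a in row.alleles.split(";") if a
            )
            for row in sub.itertuples()
        }
        records.append(
            GenotypeRecord(
                individual_id=iid, stage=stage, cell_type=cell_type,
                tissue=tissue or None, calls=calls,
            )
        )
    return records


def write_parent_genotypes(queen: Mapping[str, frozenset],
                           fathers: Mapping[str, Mapping[str, frozenset]],
                           path) -> None:
    rows = []
    for locus_id in sorted(queen):
        rows.append(dict(individual_id="queen", role="queen",
                         locus_id=locus_id, alleles=_join(queen[locus_id])))
    for fid in sorted(fathers):
        for locus_id in sorted(fathers[fid]):
            rows.append(dict(individual_id=fid, role="drone",
                             locus_id=locus_id, alleles=_join(fathers[fid][locus_id])))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parent_genotypes(path) -> Tuple[dict, dict]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    queen, fathers = {}, {}
    for row in df.itertuples():
        alleles = frozenset(int(a) for a in row.alleles.split(";") if a)
        if row.role == "queen":
            queen[row.locus_id] = alleles
        else:
            fathers.setdefault(row.individual_id, {})[row.locus_id] = alleles
    return queen, fathers


# --- YAML configuration ----------------------------------------------------


def load_design_yaml(path) -> CrossDesign:
    """Read a cross design from YAML (keys match CrossDesign fields)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "egg_params" in data:
        data["egg_params"] = EggFormationParams(**data["egg_params"])
    return CrossDesign(**data)


def load_policy_yaml(path) -> ViabilityPolicy:
    """Read a viability policy from YAML.

    Recognised keys: ``require_balanced_karyotype``,
    ``remove_diploid_males`` and ``class_viability`` (class -> prob).
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    return ViabilityPolicy(**data)
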