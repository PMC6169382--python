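import numpy as np
import pytest

from capensim.classifier import (
    CallThresholds,
    GenotypeRecord,
    assign_allele_origin,
    call_class,
    genotype_of,
    observe_genotype,
    paternity_assign,
    tabulate_classes,
)
from capensim.reproduction import ReproductionMode, WORKER_CELL, make_egg
from capensim.synthio import draw_founders

M = ReproductionMode
LOCI = [f"L{i}" for i in range(1, 8)]


def record(calls, **kw):
    full = {l: frozenset() for l in LOCI}
    full.update({k: frozenset(v) for k, v in calls.items()})
    return GenotypeRecord(individual_id=kw.pop("iid", "x"), calls=full, **kw)


QUEEN = {l: frozenset({5, 7}) for l in LOCI}
FATHERS = {"D1": {l: frozenset({9}) for l in LOCI}}


def test_assign_allele_origin_examples():
    rec = record({l: {5, 7, 9} for l in LOCI})
    origins = assign_allele_origin(rec, QUEEN, FATHERS)
    assert origins["L1"] == {5: "maternal", 7: "maternal", 9: "paternal"}

    shared_father = {"D1": {l: frozenset({5}) for l in LOCI}}
    rec = record({"L1": {5}, "L2": {5}, "L3": {5}, "L4": {5}})
    origins = assign_allele_origin(rec, QUEEN, shared_father)
    assert origins["L1"] == {5: "shared"}  # expected homozygote

    rec = record({"L1": {11}})
    origins = assign_allele_origin(rec, QUEEN, FATHERS)
    assert origins["L1"] == {11: "foreign"}


def test_assign_allele_origin_requires_parental_locus():
    rec = record({"L1": {5}})
    with pytest.raises(KeyError):
        assign_allele_origin(rec, {}, FATHERS)
    with pytest.raises(ValueError):
        assign_allele_origin(rec, QUEEN, {})


def test_call_triploid_fertilized_from_three_allele_loci():
    # three alleles (2 maternal + 1 paternal) at 5 of 7 loci
    calls = {l: {5, 7, 9} for l in LOCI[:5]}
    calls.update({l: {5, 9} for l in LOCI[5:]})
    call = call_class(record(calls), QUEEN, FATHERS)
    assert call.class_label == "triploid_fertilized"
    assert call.ploidy_call == 3 and call.fertilized_call == "yes"


def test_call_diploid_unfertilized_maternal_only():
    calls = {l: {5, 7} for l in LOCI[:3]}
    calls.update({l: {5} for l in LOCI[3:]})
    call = call_class(record(calls), QUEEN, FATHERS)
    assert call.class_label == "diploid_unfertilized"
    assert call.origin_call == "queen_laid"


def test_call_worker_laid_on_foreign_alleles():
    calls = {l: {11, 13} for l in LOCI[:4]}
    calls.update({l: {5, 9} for l in LOCI[4:]})
    call = call_class(record(calls, cell_type="drone_cell"), QUEEN, FATHERS)
    assert call.origin_call == "worker_laid"
    # a single foreign locus is treated as genotyping error, not worker origin
    calls = {l: {5, 9} for l in LOCI}
    calls["L1"] = {11}
    assert call_class(record(calls), QUEEN, FATHERS).origin_call == "queen_laid"


def test_call_tetraploid_requires_four_copy_evidence():
    q3 = {l: frozenset({3, 5, 7}) for l in LOCI}  # triploid queen
    # fusion nucleus (3 maternal) + sperm: a 4-allele locus somewhere
    calls = {l: {3, 5, 7, 9} for l in LOCI[:4]}
    calls.update({l: {3, 5, 9} for l in LOCI[4:]})
    call = call_class(record(calls), q3, FATHERS)
    assert call.class_label == "tetraploid_fertilized"
    # 2 maternal + 1 paternal everywhere: parsimony prefers triploid
    calls = {l: {3, 5, 9} for l in LOCI}
    assert call_class(record(calls), q3, FATHERS).class_label == "triploid_fertilized"
    # 3 maternal alleles with the paternal copy hidden in a shared allele
    shared_father = {"D1": {l: frozenset({7}) for l in LOCI}}
    calls = {l: {3, 5, 7} for l in LOCI[:2]}
    calls.update({l: {3, 7} for l in LOCI[2:]})
    rec = record(calls)
    # fertilisation cannot be proven (no strictly paternal allele), so
    # this individual stays an unfertilized triploid
    assert call_class(rec, q3, shared_father).class_label == "triploid_unfertilized"


def test_loh_diploid_never_called_haploid():
    """Thelytokous diploids with LOH at most loci stay diploid calls as
    long as one locus retains both maternal alleles."""
    calls = {l: {5} for l in LOCI}
    calls["L6"] = {5, 7}
    call = call_class(record(calls), QUEEN, FATHERS)
    assert call.class_label == "diploid_unfertilized"
    # but with single alleles everywhere the egg is called haploid
    calls = {l: {5} for l in LOCI}
    assert call_class(record(calls), QUEEN, FATHERS).class_label == "haploid"


def test_too_few_typed_loci_unclassifiable():
    calls = {l: {5, 7, 9} for l in LOCI[:3]}  # only 3 loci amplified
    call = call_class(record(calls), QUEEN, FATHERS,
                      CallThresholds(min_loci_typed=4))
    assert call.class_label == "unclassifiable"
    assert call.supporting_loci == 3


def test_observe_genotype_matches_genome_without_dropout(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(0)
    egg = make_egg(queen, drones, M.THELYTOKY_THEN_FERTILIZED, WORKER_CELL,
                   panel, rng=rng)
    egg.egg_id = "e1"
    rec = observe_genotype(egg, panel, 0.0, rng=rng)
    from capensim.karyotype import allele_set_at

    for loc in panel.loci:
        assert rec.calls[loc.id] == allele_set_at(egg.cell_lines[0], loc)


def test_observe_genotype_mosaic_tissue_consistency(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(1)
    egg = make_egg(queen, drones, M.MOSAIC_TWO_ZYGOTES, WORKER_CELL, panel,
                   rng=rng)
    egg.egg_id = "m1"
    a = observe_genotype(egg, panel, 0.0, tissue="hind-leg", rng=rng)
    b = observe_genotype(egg, panel, 0.0, tissue="hind-leg", rng=rng)
    assert a.calls == b.calls  # a second PCR of the same tissue agrees


def test_observe_genotype_dropout_rate(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(2)
    egg = make_egg(queen, drones, M.FERTILIZED, WORKER_CELL, panel, rng=rng)
    egg.egg_id = "d1"
    n, rate = 4000, 0.1
    missing = sum(
        len(panel.loci) - len(observe_genotype(egg, panel, rate, rng=rng).typed_loci)
        for _ in range(n)
    )
    mean_missing = missing / n
    assert mean_missing == pytest.approx(rate * len(panel.loci), abs=0.05)


def test_dropout_monotonicity():
    """More dropout never increases the number of confident calls."""
    rng = np.random.default_rng(3)
    base = [record({l: {5, 7, 9} for l in LOCI}, iid=f"i{k}") for k in range(60)]
    u = rng.uniform(size=(60, len(LOCI)))
    confident = []
    for rate in (0.0, 0.25, 0.5, 0.75):
        n_conf = 0
        for k, rec in enumerate(base):
            masked = {
                l: (frozenset() if u[k, j] < rate else rec.calls[l])
                for j, l in enumerate(LOCI)
            }
            call = call_class(GenotypeRecord(individual_id=rec.individual_id,
                                             calls=masked), QUEEN, FATHERS)
            n_conf += call.class_label != "unclassifiable"
        confident.append(n_conf)
    assert confident == sorted(confident, reverse=True)


def test_paternity_round_trip(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(4)
    qg = genotype_of(queen, panel)
    fg = {k: genotype_of(v, panel) for k, v in drones.items()}
    correct = 0
    for i in range(200):
        egg = make_egg(queen, drones, M.FERTILIZED, WORKER_CELL, panel, rng=rng)
        egg.egg_id = f"e{i}"
        rec = observe_genotype(egg, panel, 0.0, rng=rng)
        correct += paternity_assign(rec, qg, fg) == egg.sperm_donors[0]
    assert correct == 200


def test_paternity_ambiguous_for_indistinguishable_fathers():
    fathers = {"D1": {l: frozenset({9}) for l in LOCI},
               "D2": {l: frozenset({9}) for l in LOCI}}
    rec = record({l: {5, 9} for l in LOCI})
    assert paternity_assign(rec, QUEEN, fathers) == "ambiguous"
    with pytest.raises(ValueError):
        paternity_assign(rec, QUEEN, {"D1": fathers["D1"]})


def test_tabulate_classes_round_trip(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(5)
    qg = genotype_of(queen, panel)
    fg = {k: genotype_of(v, panel) for k, v in drones.items()}
    records, truth = [], []
    for i, mode in enumerate([M.FERTILIZED] * 30 + [M.THELYTOKY_THEN_FERTILIZED] * 10):
        egg = make_egg(queen, drones, mode, WORKER_CELL, panel, rng=rng)
        egg.egg_id = f"e{i}"
        records.append(observe_genotype(egg, panel, 0.0, rng=rng))
        truth.append(egg.true_class)
    calls = [call_class(r, qg, fg) for r in records]
    table = tabulate_classes(records, calls)
    col = ("egg", WORKER_CELL)
    assert table.loc["diploid_fertilized", col] == truth.count("diploid_fertilized")
    assert table.loc["triploid_fertilized", col] == truth.count("triploid_fertilized")
    assert table.loc["Total", col] == 40


def test_tabulate_empty_input():
    table = tabulate_classes([], [])
    assert table.shape[1] == 0
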