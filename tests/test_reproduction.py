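import numpy as np
import pytest
from scipy import stats as sps

from capensim.karyotype import allele_set_at
from capensim.meiosis import CrossoverModel
from capensim.reproduction import (
    DRONE_CELL,
    WORKER_CELL,
    EggFormationParams,
    ModeMixture,
    ReproductionMode,
    fertilize,
    make_egg,
    sample_sperm,
    simulate_brood,
)
from capensim.synthio import draw_founders, make_panel

M = ReproductionMode


def test_sperm_is_clonal(diploid_cross):
    _, _, drones = diploid_cross
    d = drones["D1"]
    s1, s2 = sample_sperm(d), sample_sperm(d)
    for loc_alleles_1, loc_alleles_2 in zip(
        (c.alleles for cs in s1.chromatids.values() for c in cs),
        (c.alleles for cs in s2.chromatids.values() for c in cs),
    ):
        assert loc_alleles_1 == loc_alleles_2
    with pytest.raises(ValueError):
        sample_sperm(fertilize(s1, [s2]))  # a diploid cell is not a drone


def test_fertilize_adds_one_ploidy_per_sperm(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(0)
    from capensim.meiosis import central_fusion, perform_meiosis

    tet = perform_meiosis(queen, panel, CrossoverModel(), rng)
    oocyte = tet.products[0]
    assert fertilize(oocyte, [sample_sperm(drones["D1"])]).ploidy == 2
    fusion = central_fusion(tet)
    assert fertilize(fusion, [sample_sperm(drones["D1"])]).ploidy == 3
    with pytest.raises(ValueError):
        fertilize(oocyte, [])


def test_single_drone_offspring_share_paternal_allele(panel7):
    queen, drones = draw_founders(panel7, 2, 1, np.random.default_rng(1))
    rng = np.random.default_rng(2)
    for loc in panel7.loci:
        (paternal,) = allele_set_at(drones["D1"], loc)
        for _ in range(5):
            egg = make_egg(queen, drones, M.FERTILIZED, WORKER_CELL, panel7, rng=rng)
            assert paternal in allele_set_at(egg.cell_lines[0], loc)


# --- mode -> genotypic signature ------------------------------------------

# (ploidy, maternal alleles, strictly-paternal alleles, cell lines) on
# fully informative founders with centromeric loci (no LOH possible)
SIGNATURES = {
    M.ARRHENOTOKY: (1, 1, 0, 1),
    M.FERTILIZED: (2, 1, 1, 1),
    M.THELYTOKY: (2, 2, 0, 1),
    M.THELYTOKY_THEN_FERTILIZED: (3, 2, 1, 1),
    M.TWO_SPERM_ONE_MATERNAL: (3, 1, 2, 1),
    M.ANDROGENESIS: (1, 0, 1, 1),
}


@pytest.mark.parametrize("mode", list(SIGNATURES))
def test_mode_signatures_unique_on_informative_founders(centromeric_panel, mode):
    panel = centromeric_panel
    queen, drones = draw_founders(panel, 2, 4, np.random.default_rng(3))
    rng = np.random.default_rng(4)
    maternal = {loc.id: allele_set_at(queen, loc) for loc in panel.loci}
    paternal = {
        loc.id: set().union(*(allele_set_at(d, loc) for d in drones.values()))
        for loc in panel.loci
    }
    exp_ploidy, exp_m, exp_p, exp_lines = SIGNATURES[mode]
    for _ in range(150):
        egg = make_egg(queen, drones, mode, WORKER_CELL, panel, rng=rng)
        assert len(egg.cell_lines) == exp_lines
        line = egg.cell_lines[0]
        assert line.ploidy == exp_ploidy
        for loc in panel.loci:
            obs = allele_set_at(line, loc)
            assert len(obs & maternal[loc.id]) == exp_m
            assert len(obs & paternal[loc.id]) == exp_p


def test_mosaic_two_zygotes_has_two_diploid_lines(centromeric_panel):
    queen, drones = draw_founders(centromeric_panel, 2, 4, np.random.default_rng(5))
    rng = np.random.default_rng(6)
    maternal = {
        loc.id: allele_set_at(queen, loc) for loc in centromeric_panel.loci
    }
    for _ in range(100):
        egg = make_egg(queen, drones, M.MOSAIC_TWO_ZYGOTES, WORKER_CELL,
                       centromeric_panel, rng=rng)
        assert egg.is_mosaic and len(egg.cell_lines) == 2
        assert all(line.ploidy == 2 for line in egg.cell_lines)
        for loc in centromeric_panel.loci:
            joint = set().union(*(allele_set_at(l, loc) for l in egg.cell_lines))
            # jointly two maternal alleles (the two centrals) + 1-2 paternal
            assert len(joint & maternal[loc.id]) == 2
            assert 1 <= len(joint - maternal[loc.id]) <= 2


def test_unfertilized_eggs_never_carry_paternal_alleles(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(7)
    paternal = {
        loc.id: set().union(*(allele_set_at(d, loc) for d in drones.values()))
        for loc in panel.loci
    }
    for mode in (M.ARRHENOTOKY, M.THELYTOKY):
        for _ in range(100):
            egg = make_egg(queen, drones, mode, WORKER_CELL, panel, rng=rng)
            assert not egg.fertilized and not egg.sperm_donors
            for loc in panel.loci:
                assert not allele_set_at(egg.cell_lines[0], loc) & paternal[loc.id]


def test_androgenesis_clones_the_drone(diploid_cross):
    panel, queen, drones = diploid_cross
    rng = np.random.default_rng(8)
    egg = make_egg(queen, drones, M.ANDROGENESIS, DRONE_CELL, panel, rng=rng)
    donor = drones[egg.sperm_donors[0]]
    for loc in panel.loci:
        assert allele_set_at(egg.cell_lines[0], loc) == allele_set_at(donor, loc)


def test_two_sperm_mode_requires_two_distinct_drones(panel7):
    queen, drones = draw_founders(panel7, 2, 1, np.random.default_rng(9))
    with pytest.raises(ValueError):
        make_egg(queen, drones, M.TWO_SPERM_ONE_MATERNAL, WORKER_CELL, panel7,
                 rng=np.random.default_rng(0))


def test_mode_ploidy_mismatch_raises(diploid_cross, triploid_cross):
    panel, queen2, drones = diploid_cross
    _, queen3, _ = triploid_cross
    rng = np.random.default_rng(10)
    with pytest.raises(ValueError):
        make_egg(queen2, drones, M.TRIPLOID_QUEEN_EGG, WORKER_CELL, panel, rng=rng)
    with pytest.raises(ValueError):
        make_egg(queen3, drones, M.THELYTOKY, WORKER_CELL, panel, rng=rng)


def test_brood_mixture_fraction():
    """14% thelytoky-then-fertilisation -> ~14% triploid offspring."""
    panel = make_panel(2, 8, rng=12, chromosome_count=3)
    queen, drones = draw_founders(panel, 2, 1, np.random.default_rng(13))
    mixture = ModeMixture({WORKER_CELL: {M.FERTILIZED: 0.86,
                                         M.THELYTOKY_THEN_FERTILIZED: 0.14}})
    eggs = simulate_brood(queen, drones, mixture, {WORKER_CELL: 2000}, panel,
                          rng=np.random.default_rng(14))
    frac = np.mean([e.true_class == "triploid_fertilized" for e in eggs])
    assert frac == pytest.approx(0.14, abs=0.02)
    assert all(e.cell_lines[0].ploidy in (2, 3) for e in eggs)


def test_triploid_queen_unfertilized_class_mix():
    """Unfused oocytes split 1:1 haploid:diploid; fusions are triploid."""
    panel = make_panel(1, 8, rng=15, chromosome_count=2)
    queen, drones = draw_founders(panel, 3, 1, np.random.default_rng(16))
    f = 0.2
    params = EggFormationParams(
        fusion_probability=f, p_fertilize_worker_cell=0.0,
        p_fertilize_drone_cell=0.0,
    )
    mixture = ModeMixture({DRONE_CELL: {M.TRIPLOID_QUEEN_EGG: 1.0}})
    eggs = simulate_brood(queen, drones, mixture, {DRONE_CELL: 10000}, panel,
                          rng=np.random.default_rng(17), params=params)
    counts = {
        cls: sum(e.true_class == cls for e in eggs)
        for cls in ("triploid_unfertilized", "haploid", "diploid_unfertilized")
    }
    assert sum(counts.values()) == len(eggs)
    expected = np.array([f, (1 - f) / 2, (1 - f) / 2]) * len(eggs)
    stat, p = sps.chisquare(list(counts.values()), expected)
    assert p > 0.001


def test_triploid_queen_drone_cells_mostly_unfertilized(triploid_cross):
    panel, queen, drones = triploid_cross
    mixture = ModeMixture({DRONE_CELL: {M.TRIPLOID_QUEEN_EGG: 1.0}})
    eggs = simulate_brood(queen, drones, mixture, {DRONE_CELL: 300}, panel,
                          rng=np.random.default_rng(18))
    assert np.mean([not e.fertilized for e in eggs]) > 0.8


def test_worker_laid_contamination_injects_haploid_worker_eggs(panel7):
    queen, drones = draw_founders(panel7, 2, 1, np.random.default_rng(19))
    worker_queen, _ = draw_founders(panel7, 2, 1, np.random.default_rng(20),
                                    fully_informative=False)
    mixture = ModeMixture({DRONE_CELL: {M.FERTILIZED: 1.0}})
    eggs = simulate_brood(
        queen, drones, mixture, {DRONE_CELL: 200}, panel7,
        rng=np.random.default_rng(21), worker_laid_rate=0.3,
        laying_workers=[worker_queen],
    )
    laid_by = {e.laid_by for e in eggs}
    assert laid_by == {"queen", "worker"}
    for egg in eggs:
        if egg.laid_by == "worker":
            assert not egg.fertilized and egg.true_class == "haploid"


def test_mode_mixture_validation():
    with pytest.raises(ValueError):
        ModeMixture({WORKER_CELL: {M.FERTILIZED: 0.5}})
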