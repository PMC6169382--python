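# capensim

Forward simulation and marker-based inference for the unusual
reproductive cytogenetics of honey bees — in particular the Cape honey
bee (*Apis mellifera capensis*), whose females can reproduce
thelytokously by **central-fusion automixis**: two of the four products
of meiosis fuse, as if one acted as a sperm, restoring a diploid
(female) genotype without fertilisation.

The package is for researchers interpreting microsatellite and
flow-cytometry data from crosses in which ploidy is in play: queens
whose CO2 narcosis induces fertilisation *of* a thelytokous fusion
nucleus (producing triploid workers with two maternal alleles and one
paternal allele), triploid queens whose brood spans haploid to
tetraploid, diploid mosaics arising from polyspermy, androgenesis, and
worker-laid brood.

## What it models

**Meiosis.** Eggs complete meiosis after laying, leaving a tetrad of
four pronuclei `[peripheral-1, central-1, central-2, peripheral-2]`;
the centrals descend from opposite meiosis-I poles. Crossovers per
chromosome are Poisson with mean `2L` for map length `L` Morgans
(Haldane-consistent), positions uniform, no interference. Central
fusion of a heterozygous locus at centromere distance `d` then loses
heterozygosity at a rate that is 0 at `d = 0` and approaches 1/3 under
free recombination. A triploid germ cell segregates two homologs to
one meiosis-I pole and one to the other, yielding two diploid and two
haploid products — so a triploid queen's unfertilised eggs are haploid
or diploid 1:1 unless the central pronuclei fuse into a triploid
nucleus.

**Egg formation.** Eight `ReproductionMode`s: arrhenotoky, normal
fertilisation, thelytoky, thelytoky-then-fertilisation (3n),
one-maternal-plus-two-sperm (3n), two-zygote mosaics, androgenesis and
the triploid-queen egg, plus a per-chromosome disjunction-error mode
producing aneuploid eggs. Sex follows *csd*: two or more distinct
alleles → female at any ploidy; hemizygous → male; homozygous
multiploid → diploid male. Viability is a per-class Bernoulli filter
with optional aneuploidy and diploid-male removal.

**Inference.** From per-locus observed allele sets plus parental
genotypes: allele origin (maternal / paternal / shared / foreign),
ploidy (three alleles at ≥ 2 loci → 3n; a four-copy pattern → 4n),
fertilisation, worker-laid detection, paternity, and brood-class count
tables. Synthetic DAPI flow cytometry (Gaussian C1–C4 mixtures) with a
calibration-based nearest-peak caller resolves what microsatellites
cannot: a true triploid (C3-dominant brain) versus a diploid mosaic
(C2-dominant).

## Worked example

`python examples/thelytoky_loh.py` simulates 20,000 central fusions per
map position:

```
centromere distance (M)  ->  LOH rate in thelytokous offspring
  0.00                     0.000
  0.05                     0.046
  0.20                     0.148
  1.00                     0.314
```

Heterozygosity survives central fusion at the centromere and erodes
toward the free-recombination limit of 1/3 with map distance — the
reason thelytokous lineages lose heterozygosity locus by locus.

`python examples/classify_genotype_table.py` simulates a four-drone
cross with 14% thelytoky-then-fertilisation, classifies 200 offspring
from their genotype table and cross-tabulates paternity by ploidy:

```
paternity correct for 200/200 offspring
father   diploid  triploid
  D1       38        5
  D2       51       10
  D3       41        5
  D4       41        9

paternity x ploidy chi-square = 1.446, df = 3, p = 0.695
```

No father is over-represented among triploids: the third genome copy is
maternal. The other examples cover the triploid queen's brood table
(`triploid_queen_brood.py`), the cytometric triploid-vs-mosaic test
(`cytometry_ploidy.py`) and colony-level three-allele proportions
(`narcosis_cross.py`).

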