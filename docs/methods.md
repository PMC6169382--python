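# Methods

This note records the model behind `capensim`, its assumptions, the
parameters that matter, and the choices made where the underlying
biology leaves the design open.

## Genome representation

A genome is a multiset of chromatids per chromosome (`CellGenome`);
each chromatid carries integer microsatellite alleles keyed by locus id
plus a founder-origin label per allele and for the centromere, so
simulated crosses retain exact provenance. Ploidy is the uniform
chromosome copy number, or "aneuploid" when copies differ. Alleles are
opaque labels (fragment sizes): there is no mutation or stutter model,
because the inference problem treats alleles as exact.

Map positions are distances from the centromere in **Morgans**. No
genetic map exists for the named marker panels, so positions are free
parameters, default 0.2 M, and panel loci sit on distinct chromosomes
(of the 16 in the honey-bee karyotype) to avoid asserting unknown
linkage. The `csd` sex locus is one more locus on its own chromosome.

## Meiosis

Diploid meiosis replicates the two homologs into sister pairs, applies
crossovers, then separates homologous pairs at meiosis I (independent
assortment per chromosome) and sisters at meiosis II. The four
products are kept in tetrad order with the two central pronuclei
descending from opposite meiosis-I poles — the geometry that makes
central fusion heterozygosity-restoring.

Crossovers per chromosome are Poisson(`mean_crossovers_per_chromosome`,
default 2.0), optionally forced ≥ 1, with breakpoints uniform on the
genetic map (`chromosome_length`, default 1.0 M) and no chiasma
interference; each event exchanges all alleles distal to the
breakpoint between one chromatid of each sister pair. With the default
mean of `2 × length`, the per-chromatid recombination fraction between
centromere and a locus at distance d is Haldane's
`r = (1 − e^(−2d))/2`. The test suite verifies the emergent
central-fusion LOH rate against an independent exact enumeration of
chromatid states (a small Markov chain over the 4-strand allele
configuration), including the limits LOH(0) = 0 and LOH(∞) = 1/3.

Anaphase-I arrest in the laid egg is not represented as a state:
meiosis completes atomically at egg formation, which is
indistinguishable for every downstream quantity modelled here.

### Triploid meiosis

A triploid germ cell segregates two homologs to one pole and one to
the other at meiosis I. The pole receiving two homologs is fixed for
the whole cell (giving the tetraploid-plus-diploid meiosis-I daughter
pair and, after meiosis II, whole-cell product ploidies {1,1,2,2});
**which** two of the three homologs travel together is drawn uniformly
and independently per chromosome. A per-chromosome-independent choice
of the *pole* itself would instead make every product aneuploid, which
contradicts the observation of euploid haploid-to-tetraploid brood;
this is the one point where the segregation model is constrained by
outcome rather than mechanism. Crossovers act between the two paired
homologs; the lone homolog does not recombine. The two diploid
products receive one chromatid from each sister pair and therefore
carry non-sister chromosomes (heterozygous except distal to
crossovers).

### Disjunction errors

`apply_disjunction_errors` moves, with probability `error_rate` per
chromosome, one chromatid copy from one tetrad product to another,
conserving total copy number and flagging both products aneuploid.
This implements the hypothesis that most of a triploid queen's eggs
fail because trivalent segregation is not neat; the balanced-tetrad
fraction follows `(1 − rate)^16` across the karyotype.

## Egg formation

Modes and their genotypic signatures (fully informative founders):

| mode | ploidy | maternal/paternal alleles | notes |
|---|---|---|---|
| arrhenotoky | 1 | 1 / 0 | surviving pronucleus uniform among the 4 |
| fertilized | 2 | 1 / 1 | |
| thelytoky | 2 | 2 / 0 | central fusion |
| thelytoky_then_fertilized | 3 | 2 / 1 | the CO2-narcosis triploid class |
| two_sperm_one_maternal | 3 | 1 / 2 | requires 2 distinct drones |
| mosaic_two_zygotes | 2+2 | 2 / ≤2 | two cell lines, confounded with 3n |
| androgenesis | 1 | 0 / 1 | clone of the sperm donor |
| triploid_queen_egg | 1–4 | varies | see below |

Thelytoky-then-fertilisation is modelled sequentially (fusion nucleus,
then sperm); the simultaneous three-pronucleus alternative is
genotypically identical, so only one mechanism is implemented.
Polyspermy is fixed at two sperm. Which single pronucleus survives in
one-pronucleus modes is uniform over the four, as nothing identifies
the survivor.

**Triploid-queen eggs.** With probability `fusion_probability`
(default **0.2**) the central pronuclei fuse into a 3n nucleus;
otherwise a uniformly chosen product survives (haploid or diploid,
1:1). The egg is then fertilised with probability 0.85 in worker cells
and 0.05 in drone cells. The fertilisation rates are fitted to the
observed brood mix; the fusion rate is calibrated against drone-cell
eggs (10 of 48 triploid unfertilised ≈ 0.21), where fertilisation does
not mask fusion. The neutral 1:1 oocyte split necessarily predicts
roughly equal diploid-fertilised and triploid-fertilised worker-cell
eggs; real broods show far more triploid-fertilised eggs, an excess of
diploid oocytes that the segregation model does not explain. An
optional extra pathway — thelytokous fusion of the two haploid
pronuclei (`haploid_pair_fusion_probability`, default 0) — is provided
to explore that discrepancy and is off by default.

## Sex and viability

Sex is determined per cell line from `csd`: ≥ 2 distinct alleles →
female at any ploidy; a single hemizygous allele → male; ≥ 2 identical
copies → diploid male. A mosaic counts as female if any line is
female. Viability is phenomenological: deterministic removal of
aneuploid eggs (optional) and diploid males, then a per-class
Bernoulli draw. Two presets: `diploid_queen_policy` (0.93 hatch across
classes) and `triploid_queen_policy`, calibrated so that almost no egg
hatches (observed 2.1% in worker cells) and only tetraploid-fertilised
and triploid-unfertilised classes reach pupation (rate 0.1 each).
Whether triploid-fertilised egg death is karyotypic imbalance or
something else is unresolved; both the aneuploidy switch and the
per-class rates exist so either hypothesis can be simulated.

## Marker classification

Observed data are per-locus allele **sets** (no dosage). Origin labels
per allele: maternal, paternal, shared (both parents), foreign
(neither). Calling rules, with `CallThresholds` defaults:

- fewer than 4 typed loci → unclassifiable;
- fertilised iff strictly paternal alleles at ≥ 1 locus; shared
  alleles alone never prove fertilisation;
- worker-laid iff foreign alleles at ≥ 2 loci (one locus is treated as
  genotyping error);
- ploidy > 2 requires ≥ 3 alleles at ≥ 2 loci (`min_loci_multiallele`;
  the stricter four-of-seven rule used when selecting cytometry
  specimens is available by configuration);
- tetraploid only when some locus demands four copies: four distinct
  alleles, or three maternal-consistent alleles in a fertilised
  individual (the paternal copy hidden in a shared allele); otherwise
  parsimony prefers triploid;
- haploid only when *every* typed locus is single-allele, so
  LOH-affected thelytokous diploids are never demoted to haploid while
  one locus retains both maternal alleles;
- an all-paternal single-allele fertilised genotype is an androgenetic
  haploid clone.

The triploid/tetraploid and LOH rules are implementation heuristics:
no explicit published rule exists for either boundary. Paternity is
the unique father carrying every strictly paternal allele, else
ambiguous. With fully informative founders and zero dropout, the
simulate→classify round trip is exact for every non-mosaic mode; a
two-zygote mosaic genotyped as pooled tissue is indistinguishable from
a triploid — the motivation for cytometry.

## Flow cytometry

Event lists are Gaussian mixtures with component means `k × C1` (k =
1..4) and a common coefficient of variation (instrument spread scales
with intensity), truncated positive. Peak calling is
nearest-expected-peak gating against a haploid calibration intensity,
mirroring the standards-based analysis of real data, not free mixture
fitting. Because spread grows with k, a narrow absolute gate
preferentially discards C3/C4 nuclei and biases the fractions; the
default half-width is therefore 0.45 × C1, just inside the
disjointness limit of 0.5, giving near-uniform retention up to
cv ≈ 0.06 and composition recovery within ±0.03 at 20,000 events.
Tissue presets encode autopolyploidization: brain reflects the true
karyotype, thorax reads one class higher (a haploid drone's thorax is
C2-dominant). Group comparison is a two-sided Mann–Whitney test per
tissue and component with a bootstrap percentile CI on the difference
of means — a rank-based replacement for nested GLMs, whose Wald
statistics are deliberately not reproduced. Real FCS file parsing,
debris and S-phase modelling are out of scope.

## Summary statistics

`chisq_contingency` is Pearson's test without continuity correction
(delegated to scipy; the test suite checks it against a hand-rolled
expected-counts oracle to 1e-9). `viability_summary` reports
one-decimal hatch percentages; note that correct rounding gives 92.8
for 193/208 where 92.7 has been printed elsewhere. The headline
three-allele rate is the **unweighted mean of per-colony percentages**
(13.6 → 14%), not the pooled proportion (15.6%), because colonies are
the sampling unit; headline integers round half-up, so the smallest
colony rate 1/18 = 5.6% reports as 6 even though 5 has been printed
(truncation).

## Synthetic data and what passing tests show

`make_panel` draws multi-allelic panels (7 loci by default, 6 for the
triploid-queen design) with fragment-size-like alleles and a ≥ 6-allele
csd locus; `draw_founders` makes every founder allele copy distinct
("fully informative") unless told otherwise. The generator emulates
multi-allelic codominant markers with locus dropout, but not
genotyping artefacts (stutter, null alleles, allele dosage), linkage
between panel loci, mutation, or colony demography. Exact round-trip
accuracy therefore demonstrates internal consistency of simulator and
classifier under ideal markers, not expected field accuracy; the
partially informative regime (shared founder alleles) is exercised
separately and resolves ties toward "ambiguous" rather than guessing.

Problem sizes used by the test suite and acceptance script — 50,000
fusions for LOH endpoints, 10,000 triploid meioses, 1,000 round-trip
eggs, 20,000 cytometry events — keep every Monte-Carlo standard error
well below the asserted tolerances.

## Determinism

All randomness flows through `numpy.random.Generator`; drivers expand
one seed into independent per-stage streams (founders, brood, dropout,
viability) via `SeedSequence.spawn`, so stages can be re-run in
isolation and `run_experiment` output files are byte-identical for a
given seed.

## Known limitations

- No chiasma interference, gene conversion, or trivalent pairing
  mechanics; triploid meiosis ignores pairing failure.
- The diploid-oocyte excess in triploid-queen broods is not produced
  by the default model (see above).
- Allele sets carry no dosage information, so ploidy calls lean on
  multi-allele patterns only.
- Cytometry synthesis has no debris/doublet component; the caller's
  accuracy statement applies to clean mixtures.
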