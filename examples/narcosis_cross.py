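"""A single-drone cross whose queen produces some triploid offspring.

CO2-narcosed thelytoky-competent queens lay a fraction of eggs in which
a thelytokous fusion nucleus is *also* fertilised: the offspring are
triploid, carrying two maternal alleles and one paternal allele at
informative loci. We simulate such a cross, classify every offspring
from its microsatellite genotype, and summarise per-colony three-allele
proportions the way a crossing table would.
"""

import numpy as np

from capensim import (
    CrossDesign,
    colony_proportions,
    run_experiment,
)

counts = {}
for colony, seed in zip("efgh", [11, 12, 13, 14]):
    design = CrossDesign(experiment=1, n_eggs={"worker_cell": 18})
    out = run_experiment(design, f"scratch/colony_{colony}", seed=seed)
    calls = [c.class_label for r, c in zip(out["records"], out["calls"])
             if r.stage == "egg"]
    three = sum(c == "triploid_fertilized" for c in calls)
    counts[colony] = (len(calls) - three, three)
    print(f"colony {colony}: {len(calls)} pupae genotyped, "
          f"{three} with three alleles at multiple loci")

res = colony_proportions(counts)
print(f"\nper-colony three-allele %: {res.per_colony}")
print(f"mean {res.mean_pct}% (range {res.min_pct}-{res.max_pct}%)")
print("\nEach three-allele individual is a triploid from fertilisation of")
print("a central-fusion (thelytokous) nucleus; the rate varies by colony.")
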