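"""Classify offspring from genotype tables and assign paternity.

A queen inseminated with four unrelated drones: every offspring's
per-locus allele sets are written to (and read back from) the canonical
long-format CSV, each individual is classified, and paternity is
assigned from the strictly paternal alleles. With a fully informative
panel both inferences are exact.
"""

import numpy as np

from capensim import (
    ModeMixture,
    ReproductionMode,
    call_class,
    chisq_contingency,
    draw_founders,
    genotype_of,
    make_panel,
    observe_genotype,
    paternity_assign,
    simulate_brood,
)
from capensim.synthio import read_genotype_table, write_genotype_table

M = ReproductionMode
panel = make_panel(7, 8, rng=21)
queen, drones = draw_founders(panel, 2, 4, np.random.default_rng(22))
mixture = ModeMixture({"worker_cell": {M.FERTILIZED: 0.86,
                                       M.THELYTOKY_THEN_FERTILIZED: 0.14}})
rng = np.random.default_rng(23)
eggs = simulate_brood(queen, drones, mixture, {"worker_cell": 200}, panel, rng=rng)
records = [observe_genotype(e, panel, dropout_rate=0.02, rng=rng) for e in eggs]

write_genotype_table(records, "scratch/offspring.csv")
records = read_genotype_table("scratch/offspring.csv")

qg = genotype_of(queen, panel)
fg = {k: genotype_of(v, panel) for k, v in drones.items()}
by_id = {e.egg_id: e for e in eggs}

table = {fid: [0, 0] for fid in fg}  # father -> [diploid, triploid]
correct = 0
for rec in records:
    call = call_class(rec, qg, fg)
    father = paternity_assign(rec, qg, fg)
    egg = by_id[rec.individual_id]
    correct += father == egg.sperm_donors[0]
    if father != "ambiguous" and call.ploidy_call in (2, 3):
        table[father][call.ploidy_call - 2] += 1

print(f"paternity correct for {correct}/{len(records)} offspring")
print("father   diploid  triploid")
for fid, (d2, d3) in sorted(table.items()):
    print(f"  {fid}      {d2:3d}      {d3:3d}")
counts = np.array([[d2 for d2, _ in table.values()],
                   [d3 for _, d3 in table.values()]])
stat, df, p = chisq_contingency(counts)
print(f"\npaternity x ploidy chi-square = {stat:.3f}, df = {df}, p = {p:.3f}")
print("No father's sperm is more likely to make triploids: the extra")
print("genome is maternal, from the thelytokous fusion nucleus.")
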