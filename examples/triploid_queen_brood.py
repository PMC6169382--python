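"""The brood of a triploid queen, from meiosis to the class-count table.

A triploid germ cell is modelled as segregating two homologs to one
meiosis-I pole and one to the other, so unfertilised eggs carry a
haploid or diploid oocyte nucleus (1:1) or, if the central pronuclei
fuse, a triploid nucleus. Worker-cell eggs are usually fertilised,
drone-cell eggs usually not; almost nothing hatches, but fertilised
triploid oocytes can reach pupation as viable tetraploids.
"""

from capensim import CrossDesign, run_experiment

design = CrossDesign.for_experiment(3)
design.n_eggs = {"worker_cell": 600, "drone_cell": 150}
out = run_experiment(design, "scratch/triploid_queen", seed=55)

print("Brood classes called from 6-locus genotypes (columns: stage, cell type)\n")
print(out["summary"].to_string())
print("\nTetraploid pupae (fertilised triploid oocytes) survive while the")
print("commonest egg classes never reach pupation, matching the viability")
print("profile of a triploid queen's colony.")
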