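"""Anatomy of TE-gene overlap: exons, introns and 500 bp flanks.

Merges the simulated TE annotation into a non-redundant interval set and
intersects it with every gene's subregions, then prints the per-region
occupancy and the distribution of merged TE regions per gene.
"""

import telandscape as tl

config = tl.SimConfig(
    seed=3,
    n_species=1,
    genome_length=400_000,
    superfamilies=[tl.Superfamily("L2", "LINE", 1300)],
    bursts=[tl.Burst("sp1", "L2", 60, target_k=0.1)],
    n_genes=12,
    fraction_te_in_genes=0.5,
)
result = tl.simulate_genome(config)

te_set = tl.reduce_fragments(result.fragments["sp1"])
subregions = [
    tl.build_subregions(g, seq_length=config.genome_length, flank=500)
    for g in result.genes["sp1"]
]
summaries = tl.overlap_summary(te_set, subregions, superfamily="L2")

totals = {"exons": [0, 0], "introns": [0, 0], "upstream": [0, 0], "downstream": [0, 0]}
for rec in summaries:
    for name, (_, bp, length) in rec.subregions.items():
        totals[name][0] += bp
        totals[name][1] += length

print("subregion   TE bp  region bp  occupancy")
for name, (bp, length) in totals.items():
    print(f"{name:10s} {bp:6d}  {length:9d}  {bp / length:8.2%}")

hist = tl.fragment_count_distribution(summaries)
print("\nmerged TE regions per gene:", dict(sorted(hist.items())))
print("\nThe simulator places in-gene copies in introns only, so intronic"
      "\noccupancy dominates while exons stay clean - the pattern expected"
      "\nwhen selection purges exonic insertions.")
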