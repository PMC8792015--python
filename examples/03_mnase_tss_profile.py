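"""TSS-aligned nucleosome occupancy from simulated MNase fragments.

Simulates IP and control fragment populations with a planted, sharply
positioned +1 nucleosome ~110 bp downstream of enriched genes' TSSs,
filters to mononucleosome-sized inserts, builds the TSS-oriented
1-bp occupancy matrix, and reads off the aggregate +1 peak and the
>4.7-fold enriched gene set.
"""

import nucbubble as nb

cfg = nb.FragmentSimConfig(n_genes=100, seed=3)
sim = nb.simulate_mnase_fragments(cfg)

ip = nb.filter_by_insert_size(sim.ip, 120, 180)
enriched_truth = set(sim.truth.loc[sim.truth["enriched"], "gene_id"])
anchors = [a for a in sim.anchors if a.gene_id in enriched_truth]

matrix = nb.tss_matrix(ip, anchors, window_bp=500)
profile = nb.aggregate_profile(matrix)
peak = int(matrix.positions[profile.argmax()])
print(f"mononucleosome fragments kept: {len(ip)}/{len(sim.ip)}")
print(f"aggregate occupancy peak: {peak:+d} bp from the TSS (planted dyad at +110)")

enrich = nb.gene_enrichment(sim.ip, sim.input, sim.anchors, window_bp=300)
called = set(enrich.loc[enrich["enriched"], "gene_id"])
tp = len(called & enriched_truth)
print(
    f"genes above 4.7-fold: {len(called)}; "
    f"precision {100 * tp / max(len(called), 1):.0f}%, "
    f"recall {100 * tp / len(enriched_truth):.0f}%"
)
# The peak position estimates the planted +1 nucleosome dyad; fold
# enrichment flags the genes whose promoters the factor precipitated.
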