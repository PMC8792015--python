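"""Simulate one crosslink-EM dataset and recover nucleosome counts.

Builds 150 traced molecules of a 461-bp template carrying Poisson-
distributed nucleosome-sized single-stranded bubbles, runs the geometry
-> threshold -> bubble -> nucleosome-calling chain, and compares the
called per-molecule counts with the planted ground truth.
"""

import numpy as np

import nucbubble as nb
from nucbubble.bubbles import call_molecule
from nucbubble.pipeline import profile_molecules

cfg = nb.TraceSimConfig(n_molecules=150, lambda_true=1.3, seed=7)
sim = nb.simulate_trace_dataset(cfg)

profiles, ambiguous = profile_molecules(sim.molecules)
threshold = nb.calibrate_threshold(profiles)
calls = [call_molecule(p, threshold) for p in profiles]
counts = np.array([c.nucleosome_count for c in calls])
truth = sim.planted_nucleosome_counts().to_numpy()

print(f"calibrated single-stranded threshold: {threshold:.2f} px")
print(f"molecules analyzed: {counts.size} ({len(ambiguous)} ambiguous excluded)")
print(f"mean nucleosomes per molecule: called {counts.mean():.3f}, planted {truth.mean():.3f}")
print(f"exact per-molecule agreement: {100 * (counts == truth).mean():.1f}%")
# The threshold separates the duplex (~2 px) from the open (~10 px)
# separation; exact agreement means every molecule's bubble count was
# recovered from raw strand coordinates alone.
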