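"""Decompose heavy junctions against VJ / VDJ / VDDJ references.

Every junction is explained as trimmed segments plus non-templated
insertions; recurrent (public) antibodies have conspicuously simpler
junctions than arbitrary ones — fewer inserted bases — which is why they
recur by chance at all.
"""

import numpy as np

from bcrcoherence import (
    PublicPlan,
    SimulationConfig,
    classify_cells,
    count_recurrences,
    decompose_cells,
    decompose_junction,
    infer_alleles,
    insertion_profile,
    simulate_repertoire,
)

config = SimulationConfig(
    seed=8, n_donors=4, naive_per_donor=250, memory_per_donor=250,
    vddj_rate=0.01,
    public=PublicPlan(n_keys=20, donors_per_key=4, copies_per_donor=2,
                      p_coherent=0.8),
)
sim = simulate_repertoire(config)
table = infer_alleles(sim.cells, sim.reference)
classify_cells(sim.cells, table, sim.reference)

decomps = decompose_cells(sim.cells, sim.reference)
one = next(iter(decomps.values()))
print("one decomposition:")
print(f"  topology {one.topology}, D genes {one.d_genes}, "
      f"{one.inserted_bases} inserted, {one.deleted_bases} trimmed, "
      f"{one.substitutions} substitutions over {one.aligned_bases} aligned")

ins = [d.inserted_bases for d in decomps.values()]
vddj = np.mean([d.topology == "VDDJ" for d in decomps.values()])
print(f"\nall cells: mean inserted bases {np.mean(ins):.2f}, "
      f"VDDJ rate {100 * vddj:.2f}%")

profile = insertion_profile(sim.cells, decomps)
print("insertion histogram by class (first five counts):")
for label, series in sorted(profile.items()):
    head = ", ".join(f"{k}:{v:.2f}" for k, v in series.head(5).items())
    print(f"  {label}: {head}")

rec = count_recurrences(sim.cells, "memory", decompositions=decomps)
print(f"\nrecurrent memory cells (cross-donor heavy V + CDRH3 key): "
      f"{rec.n_recurrent_cells}")
print(f"  mean inserted bases among recurrent cells: "
      f"{rec.mean_insertion_length:.2f}  (vs {np.mean(ins):.2f} overall)")
print("planted public keys reuse one junction, so their members dominate")
print("the recurrent set; in real data recurrent junctions are the simple,")
print("low-insertion ones.")

# an exact concatenation decomposes with zero events
v = sim.reference.get("IGHV1-1")
j = sim.reference.get("IGHJ1")
exact = (v.seq[v.cys_position:] + sim.reference.get("IGHD1-1").seq
         + j.seq[: j.junction_overlap])
r = decompose_junction(exact, "IGHV1-1", "IGHJ1", sim.reference)
print(f"\nexact V+D+J concatenation: {r.inserted_bases} inserted, "
      f"{r.deleted_bases} trimmed, {r.substitutions} substitutions")
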