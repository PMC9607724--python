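"""Simulate a paired repertoire, infer donor alleles, classify naive/memory.

A donor-specific germline variant looks exactly like a somatic mutation
unless alleles are inferred first; this script shows classification being
exact on labeled synthetic data, and an inferred alternate allele
rescuing its carriers from misclassification.
"""

import numpy as np

from bcrcoherence import (
    PublicPlan,
    SimulationConfig,
    classify_cells,
    count_nonjunction_mutations,
    infer_alleles,
    simulate_repertoire,
)
from bcrcoherence.alleles import AlleleTable
from bcrcoherence.synthetic import make_pileup_cells

config = SimulationConfig(seed=2, n_donors=2, naive_per_donor=300,
                          memory_per_donor=300, public=PublicPlan(n_keys=0))
sim = simulate_repertoire(config)
print(f"simulated {len(sim.cells)} cells from {config.n_donors} donors")

table = infer_alleles(sim.cells, sim.reference)
classify_cells(sim.cells, table, sim.reference)
truth = sim.truth.set_index("cell_id")["true_class"]
agreement = np.mean([c.cell_class == truth[c.cell_id] for c in sim.cells])
print(f"classifier agreement with ground truth: {agreement:.3f}")
print("  (1.0 means every zero-SHM cell was called naive and every cell")
print("   with >=1 substitution outside its junctions was called memory)")

# plant a germline variant carried by half of a donor's cells
cells = make_pileup_cells(sim.reference, "IGHV1-1", "dX", 10, 5, [100])
inferred = infer_alleles(cells, sim.reference)
variant = inferred.variants_for("dX", "IGHV1-1")[0]
print(f"\nplanted variant recovered: position {variant.positions[0]}, "
      f"base {variant.footprint}, carried by {variant.support_count} cells")
with_alleles = count_nonjunction_mutations(cells[0], inferred, sim.reference)
without = count_nonjunction_mutations(cells[0], AlleleTable(), sim.reference)
print(f"carrier SHM count with inferred alleles: {with_alleles.total} "
      f"(would be {without.total} against the bare reference)")
print("  -> without allele inference this naive cell would be mislabeled memory")
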