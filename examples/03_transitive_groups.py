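"""Transitive grouping: from pairwise similarity to functional groups.

Memory cells are grouped by chaining similarity (same clonotype, or same
heavy V gene with >=90% CDRH3 identity). The planted public keys surface
as multi-donor groups with near-perfect light chain agreement.
"""

from bcrcoherence import (
    PublicPlan,
    SimulationConfig,
    build_transitive_groups,
    classify_cells,
    compute_clonotypes,
    group_coherence,
    infer_alleles,
    positionwise_entropy,
    simulate_repertoire,
)
from bcrcoherence.groups import group_entropy_profiles

config = SimulationConfig(
    seed=5, n_donors=4, naive_per_donor=300, memory_per_donor=300,
    public=PublicPlan(n_keys=15, donors_per_key=4, copies_per_donor=3,
                      p_coherent=1.0),
)
sim = simulate_repertoire(config)
table = infer_alleles(sim.cells, sim.reference)
classify_cells(sim.cells, table, sim.reference)
assignment = compute_clonotypes(sim.cells)

groups = build_transitive_groups(sim.cells, identity_threshold=90.0,
                                 assignment=assignment)
multi = [g for g in groups if len(g.donors) >= 2]
print(f"{len(groups)} transitive groups; {len(multi)} span multiple donors")

cells_by_id = {c.cell_id: c for c in sim.cells}
print("\nlargest multi-donor groups:")
for g in multi[:5]:
    gc = group_coherence(g, cells_by_id)
    print(f"  {g.group_id}: {g.size} cells, donors {','.join(g.donors)}, "
          f"modal light gene {gc.modal_light_gene} "
          f"({gc.n_consistent_cells}/{gc.n_cells} cells consistent, "
          f"cross-donor pair coherence {gc.pair_coherence:.2f})")

profiles = group_entropy_profiles(multi[0], cells_by_id)
print(f"\nCDRH3 per-position entropy of {multi[0].group_id} (bits):")
print("  " + " ".join(f"{e:.2f}" for e in profiles["cdrh3"]))
print("zero bits everywhere = perfectly conserved CDRH3, as planted;")
print("real groups show conservation at anchor positions and diversity")
print("in the loop (cf. positionwise_entropy on any aligned column set:")
print(f"  50/50 split -> {positionwise_entropy(['A', 'C'])[0]:.1f} bit).")
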