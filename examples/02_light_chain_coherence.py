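"""The central measurement: light chain coherence by CDRH3 identity.

Builds a repertoire with planted public heavy configurations (80%
coherent), then shows the coherence curve rising with CDRH3 identity for
memory cells, the permutation null sitting at the chance match rate, and
the slope F test separating signal from null.
"""

from bcrcoherence import (
    PublicPlan,
    SimulationConfig,
    classify_cells,
    coherence_curve,
    compute_clonotypes,
    enumerate_pairs,
    infer_alleles,
    permute_light_chains,
    simulate_repertoire,
    slope_f_test,
)
from bcrcoherence.coherence import BINS, CoherenceCurve

config = SimulationConfig(
    seed=3, n_donors=4, naive_per_donor=600, memory_per_donor=600,
    public=PublicPlan(n_keys=40, donors_per_key=4, copies_per_donor=2,
                      p_coherent=0.8),
)
sim = simulate_repertoire(config)
table = infer_alleles(sim.cells, sim.reference)
classify_cells(sim.cells, table, sim.reference)
assignment = compute_clonotypes(sim.cells)

pairs = enumerate_pairs(sim.cells, "cross_donor", "memory")
curve = coherence_curve(pairs)["all"]
print("memory coherence by CDRH3 identity bin (cross-donor pairs):")
for b, n, frac in zip(curve.bins, curve.pair_count, curve.fraction()):
    if n:
        print(f"  bin {b:>3}%: {n:>6} pairs, coherence {frac:.3f}")
print("high-identity recurrences share light chains; low-identity pairs")
print("match only at the chance rate.")

null = permute_light_chains(sim.cells, n_perm=300, seed=3,
                            assignment=assignment)
print(f"\npermutation null mean: {null.overall_mean:.4f} "
      f"+/- {null.overall_sem:.4f} (analytic {null.analytic:.4f})")

# slope test: donor-pair curves vs permuted-light curves
donor_curves = list(coherence_curve(pairs, stratify_by="donor_pair").values())
null_curve = CoherenceCurve(label="null")
for i, b in enumerate(BINS):
    null_curve.pair_count[i] = 1000
    mean = null.bin_mean[i]
    null_curve.coherent_count[i] = int(round(1000 * (
        mean if mean == mean else null.analytic)))
result = slope_f_test(donor_curves, [null_curve])
print(f"slope F test (data vs permuted): F = {result.F:.1f}, "
      f"df = {result.df_num}/{result.df_den}, p = {result.p:.2e}")
print("the real curves' slope differs from the flat permuted slope.")
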