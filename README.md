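# bcrcoherence

Paired single-B-cell antibody repertoire analysis centered on **light chain
coherence**: when two unrelated B cells recur with the same heavy chain V
gene and the same CDRH3 amino acid sequence — a public clonotype — how
often do they also use the same light chain V gene?

For naive B cells such recurrences are chance products of V(D)J
recombination and the light chains agree only at the background gene-usage
rate (~Σ_g f_g², the squared-frequency match probability). For memory
B cells, which have passed selection, the heavy chain largely determines
the light chain: coherence reaches ~80%. Measuring this cleanly requires a
stack of supporting machinery, all provided here:

- **`repio`** — AIRR Rearrangement TSV, 10x contig-annotation CSV,
  germline FASTA, and a canonical per-cell TSV; assembly of barcodes into
  one-heavy + one-light `CellRecord`s.
- **`alleles`** — per-donor germline V allele inference from expressed
  pileups (variant positions need ≥4 carriers making up ≥25% of the
  pileup, excluding the junction-proximal 15 bases), so donor
  polymorphisms are not counted as mutations.
- **`classify`** — somatic hypermutation counted outside the junctions on
  both chains against assigned alleles; a cell is computationally *naive*
  iff that count is zero. Plus a documented single-linkage clonotyper,
  one-cell-per-clonotype sampling, and same-donor independent-recombination
  checks (FWR4 evidence of distinct J genes, or differing CDRL3 lengths).
- **`coherence`** — eligible-pair enumeration, CDRH3-identity binning
  (floor to 10%), coherence curves with binomial errors, a light-chain
  permutation null (mean provably Σ c(c−1)/(n(n−1))), an
  extra-sum-of-squares F test on curve slopes, a Monte-Carlo Vh/Vl
  contingency test, gene-free edit-distance coherence, recurrence
  counting, and cross-dataset super-donor comparisons.
- **`groups`** — transitive similarity grouping (same clonotype, or same
  heavy V with ≥90% CDRH3 identity; union-find components) with pair- and
  modal-gene coherence and per-position CDR3 entropy profiles.
- **`junctions`** — decomposition of heavy junctions against VJ / VDJ /
  VDDJ reference concatenations via a segment-anchored dynamic program,
  yielding inserted bases, trims, substitutions, and substitution rates.
- **`synthetic`** — a seeded generator of paired repertoires with exact
  ground truth: categorical gene usage, geometric trims and N insertions,
  a small VDDJ rate, substitution-only SHM outside junctions, clonal
  expansion, and planted cross-donor public configurations with tunable
  light chain coherence.
- **`pipeline` / CLI** — `run_pipeline(config)` orchestrates
  ingest → alleles → classify → clonotype → coherence → groups → junctions
  and writes a deterministic JSON summary; `bcrcoherence` exposes thin
  subcommands (`simulate`, `alleles`, `classify`, `clonotype`,
  `coherence`, `groups`, `junctions`, `run`).

See `docs/methods.md` for the statistical model, parameter meanings, and
known limitations, and `examples/` for narrative scripts, one per
capability.

## Worked example

```python
from bcrcoherence import (
    PublicPlan, SimulationConfig, simulate_repertoire,
    infer_alleles, classify_cells, compute_clonotypes,
    enumerate_pairs, coherence_curve, permute_light_chains,
)

config = SimulationConfig(
    seed=1, n_donors=4, naive_per_donor=500, memory_per_donor=500,
    public=PublicPlan(n_keys=30, donors_per_key=4, copies_per_donor=2,
                      p_coherent=0.8),
)
sim = simulate_repertoire(config)

table = infer_alleles(sim.cells, sim.reference)
classify_cells(sim.cells, table, sim.reference)
assignment = compute_clonotypes(sim.cells)

pairs = enumerate_pairs(sim.cells, "cross_donor", "memory")
curve = coherence_curve(pairs)["all"]
n100, c100 = curve.at_bin(100)
print(f"memory bin-100 pairs: {n100}   coherence: {c100 / n100:.3f}")
null = permute_light_chains(sim.cells, n_perm=200, seed=1,
                            assignment=assignment)
print(f"permutation null: {null.overall_mean:.3f}   "
      f"analytic: {null.analytic:.3f}")
```

Output:

```
memory bin-100 pairs: 735   coherence: 0.789
permutation null: 0.053   analytic: 0.053
```

Memory cells recurring with identical CDRH3s (bin 100) share their light
chain V gene 78.9% of the time — the planted 80% minus the incoherent
keys, which match only at the ~5% chance rate. Breaking the heavy/light
pairing by permutation drops coherence to exactly that background, and the
Monte-Carlo null agrees with its closed form. (Naive cells at this scale
produce almost no identical-CDRH3 recurrences; the 20,000-cell study runs
in the acceptance script measure the naive background too.)

The same analysis from the shell:

```bash
bcrcoherence simulate --seed 1 --out scratch/sim --public-keys 30
bcrcoherence run --config examples/pipeline_config.yaml
```

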