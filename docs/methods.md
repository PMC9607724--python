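# Methods

This package analyzes paired heavy/light antibody repertoires from single
B cells. Its central statistic asks: when two unrelated B cells recur with
the same heavy chain V gene and the same CDRH3 amino acid sequence, how
often do they also use the same light chain V gene? That fraction — the
*light chain coherence* — separates functional (memory) antibodies, where
the heavy chain largely determines the light chain, from naive antibodies,
where light chain pairing looks like chance. Everything else in the
package exists to make that measurement trustworthy: donor allele
inference so germline polymorphism is not mistaken for somatic
hypermutation (SHM), SHM-based naive/memory classification, clonotyping so
clonal expansion does not masquerade as independent recurrence, junction
decomposition to quantify how complex a junction is (and hence how likely
it is to recur by chance), and a generator of synthetic paired repertoires
with exact ground truth.

## Cell model and conventions

A cell is exactly one productive heavy chain (IGH) plus one productive
light chain (IGK/IGL); barcodes with any other configuration are dropped
as unpaired or multiplet and never rescued. The *junction* runs from the
conserved cysteine codon at the V 3' end through the conserved W/F codon
at the J 5' end, inclusive; `cdr3_aa` keeps both conserved residues, so a
printed CDR3 looks like `CARDGGYW`. All intervals are 0-based half-open.
Allele suffixes (`*01`) are stripped at ingest (raw calls are retained);
gene-level comparisons optionally merge duplicated-locus paralogs by
deleting the `D` marker directly before the hyphen (IGKV1D-17 ≡ IGKV1-17).

## Donor allele inference

For each donor and V gene, expressed sequences are piled up after a
de-redundancy step that keeps one cell per (CDRH3 length, CDRL3 length,
partner V, partner J) stratum — a deterministic proxy for one-per-clonotype
that does not require clonotypes (which are computed later, from these
alleles). A position is variant when a non-reference base occurs at least
`min_count = 4` times and makes up at least `min_fraction = 25%` of the
pileup; the last `tail_exclusion = 15` bases are excluded to stay clear of
the junction, so germline variants there are undetectable by design. Cell
footprints over the variant positions that meet the same two thresholds
define alternate alleles; their number per gene is not capped (duplicated
gene copies are real). "The same thresholds apply to footprints" is an
interpretation — the evidence rule for footprints is otherwise
underdetermined — and both knobs are exposed.

Cells are assigned the allele (reference or alternate) minimizing
mismatches over the V region 5' of the junction, ties broken toward the
reference and flagged ambiguous.

## Classification and clonotyping

SHM is counted as substitutions outside the junction on both chains: the
V region against the assigned allele, and FWR4 (everything 3' of the
junction) against the 3' end of the J reference. Indels are not counted;
cells whose V region length disagrees with every allele are flagged, not
classified. A cell is *naive* iff its total count is zero, *memory*
otherwise. These labels ignore class switching and any novel alleles the
inference missed — both documented oversimplifications.

Clonotypes are computed within donors by single-linkage clustering: two
cells link when they share heavy V and J, light V and J, equal junction
nucleotide lengths on both chains, and at least `cdr3_nt_identity = 0.85`
positional identity on each chain's junction. This is an intentionally
simple, fully documented stand-in for production clonotypers; the
threshold is configurable and the linkage result provably equals
connected components of the pairwise similarity graph (tested against an
independent BFS oracle).

Same-donor recurrence analysis additionally requires positive evidence
that two cells in different computed clonotypes really arose from separate
recombinations: different light CDR3 lengths, or framework-4 evidence of
different heavy (or light) J genes — at least three positions where the
two J references differ and each cell matches its own reference, with a
veto when any differing position has both cells supporting the same single
reference.

## The coherence statistic

Eligible pairs share the heavy V gene name and CDRH3 length and are both
memory or both naive. CDRH3 identity is positional (equal length is a
precondition), binned by rounding down to the nearest 10%. Coherence of a
pair set is the fraction whose light V gene names match (V-only by
default; a stricter V+J mode exists). Per-bin standard errors are binomial
over pairs; pairs are not independent (one cell can appear in many pairs),
which is the reason the permutation null exists. Strata (donor pair,
donor, class, dataset pair) produce families of curves; with four donors
the cross-donor stratification yields six donor-pair curves.

Null models:

- **Permutation null.** Light chains are shuffled among retained cells
  (one per clonotype, within class) with heavy chains fixed; coherence is
  recomputed per replicate (default 1,000). The replicate mean has the
  closed-form expectation Σ_g c_g(c_g−1)/(n(n−1)) — the without-replacement
  light-gene match probability — which the implementation reports alongside
  the Monte-Carlo value.
- **Slope F test.** Curve sets are compared by extra sum of squares:
  every curve gets its own intercept in both models; the full model fits
  one slope per set, the reduced model one common slope, and
  F = ((SSR_red − SSR_full)/(k−1)) / (SSR_full/(N − C − k)) for k sets and
  C curves. Passing each curve as its own set reproduces the
  one-slope-per-curve variant. Curves need at least three populated bins.
- **Vh/Vl contingency.** One (heavy V, light V) observation per clonotype;
  the chi-square statistic is compared with `n_mc = 100,000` light-label
  permutations and p = (1 + #{null ≥ observed})/(n_mc + 1).

Gene-free coherence uses the Levenshtein distance between full-length
light chain nucleotide sequences (threshold 20 by default), with and
without restricting to identical-CDRH3 pairs. The distance substrate is
configurable since conventions differ.

Recurrence counting keys cells by (heavy V gene, CDRH3 amino acids); a
cell is recurrent when its key occurs in two or more donors, and junction
summaries (insertion mean, substitution rates, VDDJ rate, CDRH3 length)
are computed over the recurrent cells of a class. The super-donor variant
replaces donor identity with dataset identity to rule out within-dataset
cross-contamination as an explanation of coherence.

## Transitive grouping

Restricted to memory cells in all-memory clonotypes, two cells are
similar when they share a clonotype or share the heavy V gene with CDRH3
identity at or above a threshold (default 90%); groups are the connected
components of this relation (union-find). Lowering the threshold only
merges groups, so partitions nest across thresholds. Group coherence is
reported both pair-level (cross-donor member pairs) and cell-level
(members using the modal light V gene). Entropy profiles are per-position
Shannon entropy in bits over the group's modal-length CDR3s; non-modal
lengths are excluded rather than aligned — embedding a multiple aligner
was deliberately avoided, so groups dominated by one length are summarized
faithfully and ragged groups partially.

## Junction decomposition

Each heavy junction is explained as a recombination product against
candidate references V·J, V·D·J, and V·D1·D2·J over ordered pairs of
distinct D genes (1 + d + d(d−1) candidates). Rather than a free global
alignment, a segment-anchored dynamic program considers exactly the
configurations recombination can produce: a prefix of the V junction
overlap, a contiguous substring of each D, and a suffix of the J overlap,
aligned to disjoint in-order blocks of the junction. Unkept reference
bases are trims (deletions, counted separately), junction bases outside
blocks are insertions, and mismatches inside blocks are substitutions.
The substitution-rate denominator is all matching plus mismatching bases.

Scoring is match +1, mismatch −1, inserted base −0.25, trimmed reference
base −0.5. Two constraints drove these values. First, insertion + deletion
(0.75) stays below the mismatch cost, so a boundary trim next to an
N-insertion is never collapsed into fake substitutions — the failure mode
that makes free affine alignment report near-zero insertions on realistic
junctions. Second, the deletion cost is high enough that a short chance
match cannot be promoted into a spurious second D segment: on labeled
simulations with 2% true VDDJ, this scoring yields zero false VDDJ calls
and zero misses among 1,000 cells. A D is only called when its block has
at least `min_d_support = 4` matches, and ordered D pairs are screened by
a shared 8-mer prefilter (`dd_kmer = 8`, disable with 0). All penalties
are dyadic so float comparisons in the traceback are exact. Ties prefer
fewer D segments, then lexicographic gene names.

Known limitation: an inserted base that happens to equal the adjacent
trimmed reference base is absorbed into the aligned block by *any*
maximum-scoring method; with geometric insertions this removes about 1/3
nt per segment joint, so decomposed insertion counts undershoot the
generative truth by roughly 1–2 nt per junction on average. On trim-free
junctions the decomposition is exact (verified per cell against ground
truth), and the undercount never becomes an overcount.

## Synthetic repertoires

The generator emulates the statistical structure the analysis assumes and
nothing more. Per clonotype it samples V/(D)/J genes from usage weights
proportional to 1/√rank, trims segment ends geometrically (mean 2.5 nt per
end; D segments keep at least 8 nt so topology stays identifiable),
inserts N regions with geometric lengths summing to mean 5 nt (the
scale of real heavy junctions), uses two D segments with probability
0.005, and expands memory clones geometrically (mean 1.5). N lengths are
drawn before any rejection; codon-frame and stop-codon constraints are
satisfied by redrawing trims and base content so the N-length law is
untouched. Memory cells receive substitution-only SHM at 0.01 per base
outside the junction, with at least one mutation forced so generator
labels are exact; junctions are never mutated, so CDR3-keyed recurrences
survive SHM and the classifier test is a closed loop. Segment overlap
lengths were set once so the mean CDRH3 is ≈18 amino acids. The light V
set (25 genes, including the identical-sequence paralog pair
IGKV1-17/IGKV1D-17) under 1/√rank usage gives a chance light-gene match
probability Σf² ≈ 6%.

Public recurrences are planted as K heavy configurations (V gene +
junction, hence CDRH3) copied into several donors. A key is *coherent* —
all copies carry its canonical light V gene — for exactly round(p·K) keys;
incoherent keys draw each copy's light gene from the background usage.
Measured pair-level bin-100 coherence is therefore p + (1−p)·Σf² up to
sampling noise, which is within three percentage points of p because
Σf² ≈ 6%; with p = 0 it equals the analytic background. A per-copy
planting mode exists for users who want copy-level rather than key-level
coherence.

What the generator does **not** model, and hence what passing tests do not
show about real data: selection (coherence is planted, not emergent),
SHM inside junctions, indels, isotype biology beyond a label, biological
gene-usage and trimming distributions (no IGoR/soNNia parity), and
sequencing error. Its background coherence (~6%) is somewhat below the
~10% seen for naive human repertoires. It is a correctness instrument,
not a biological simulator.

## Numerical and design choices

- All randomness flows through `numpy.random.Generator` with explicit
  seeds; identical configs give byte-identical pipeline summaries.
- Pileup representative choice is deterministic (smallest cell id), so
  allele inference needs no seed and is input-order invariant.
- Empty pair sets yield NaN coherence rather than an exception in
  aggregate statistics; `EmptyPairSet` is raised only where proceeding is
  meaningless (e.g. a super-donor comparison with one dataset).
- Monte-Carlo p-values use the add-one rule (1 + hits)/(n + 1), so zero is
  unreachable.
- Study-scale validation runs use 20,000-cell repertoires (4 donors ×
  2,500 naive + 2,500 memory including 240 planted public cells), sizes at
  which the planted-coherence band (±3 pp), the permutation/analytic
  agreement (±3 SEM at 1,000 permutations) and exact classifier recovery
  are all sharp; junction decomposition in descriptive reports samples
  2,000 cells per run.

## Known limitations

- The clonotyper is a documented simplification; on real data its
  assignments will differ from production tools, shifting one-per-
  clonotype statistics slightly.
- Insertion counts are maximum-parsimony estimates with the boundary
  absorption bias described above.
- FWR4-based J discrimination assumes substitution-only differences and
  3'-anchored comparability of J references.
- The per-cell-table column adapter for externally deposited tables is
  configuration shipped with best-effort defaults; confirm it against the
  actual file before relying on it.
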