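"""SHM counting, naive/memory classification, and a simplified clonotyper.

A cell is called computationally *naive* when it carries zero somatic
hypermutations outside the junction regions of both chains relative to its
donor's inferred germline alleles, and *memory* otherwise. Mutations are
counted as substitutions only; cells whose V region length differs from
every candidate allele cannot be scored this way and are flagged instead.

Clonotypes are computed within donors by single-linkage clustering: two
cells join when they share heavy V and J genes, light V and J genes, equal
heavy and light junction lengths, and per-chain junction nucleotide
identity at or above a threshold (default 85%). This is a documented,
deliberately simple stand-in for production clonotypers; the threshold and
required shared genes are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from ._util import DisjointSet, count_mismatches, fraction_identity
from .alleles import AlleleTable, assign_allele
from .errors import BcrCoherenceError
from .repio import CellRecord, GermlineReference


@dataclass(frozen=True)
class MutationProfile:
    """Non-junction substitution counts for one cell, by chain."""

    cell_id: str
    heavy_nonjunction_mutations: int
    light_nonjunction_mutations: int

    @property
    def total(self) -> int:
        return self.heavy_nonjunction_mutations + self.light_nonjunction_mutations


def _chain_mutations(
    cell: CellRecord,
    allele_table: AlleleTable,
    reference: GermlineReference,
    chain: str,
) -> int:
    anno = getattr(cell, chain)
    if anno.junction_start is None or anno.junction_end is None or not anno.seq_nt:
        raise BcrCoherenceError(
            f"cell {cell.cell_id}: {chain} chain lacks sequence/junction coordinates"
        )
    assignment = assign_allele(cell, allele_table, reference, chain=chain)
    prefix = anno.seq_nt[: anno.junction_start]
    v_mut = count_mismatches(prefix, assignment.seq[: len(prefix)])
    # FWR4: everything 3' of the junction, aligned to the 3' end of the J gene
    fwr4 = anno.seq_nt[anno.junction_end:]
    j_ref = reference.get(anno.j_gene)
    ref_fwr4 = j_ref.seq[len(j_ref.seq) - len(fwr4):] if fwr4 else ""
    j_mut = count_mismatches(fwr4, ref_fwr4)
    return v_mut + j_mut


def count_nonjunction_mutations(
    cell: CellRecord, allele_table: AlleleTable, reference: GermlineReference
) -> MutationProfile:
    """Substitutions outside the junction, both chains, vs assigned alleles."""
    return MutationProfile(
        cell_id=cell.cell_id,
        heavy_nonjunction_mutations=_chain_mutations(cell, allele_table, reference, "heavy"),
        light_nonjunction_mutations=_chain_mutations(cell, allele_table, reference, "light"),
    )


def classify_cell(profile: MutationProfile) -> str:
    """``naive`` iff zero non-junction mutations on both chains."""
    return "naive" if profile.total == 0 else "memory"


def classify_cells(
    cells: Sequence[CellRecord],
    allele_table: AlleleTable,
    reference: GermlineReference,
) -> Dict[str, MutationProfile]:
    """Fill ``shm_count`` and ``cell_class`` on every cell, in place."""
    profiles = {}
    for cell in cells:
        profile = count_nonjunction_mutations(cell, allele_table, reference)
        cell.shm_count = profile.total
        cell.cell_class = classify_cell(profile)
        profiles[cell.cell_id] = profile
    return profiles


# ---------------------------------------------------------------------------
# clonotypes
# ---------------------------------------------------------------------------


@dataclass
class ClonotypeAssignment:
    """Partition of cells into computed clonotypes (never spanning donors)."""

    mapping: Dict[str, str]
    cdr3_nt_identity: float = 0.85

    def of(self, cell_id: str) -> str:
        return self.mapping[cell_id]

    @property
    def n_clonotypes(self) -> int:
        return len(set(self.mapping.values()))

    def members(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for cell_id, ct in self.mapping.items():
            out.setdefault(ct, []).append(cell_id)
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            sorted(self.mapping.items()), columns=["cell_id", "clonotype_id"]
        ).to_csv(path, sep="\t", index=False)


def _same_clonotype(a: CellRecord, b: CellRecord, threshold: float) -> bool:
    return (
        fraction_identity(a.heavy.junction_nt, b.heavy.junction_nt) >= threshold
        and fraction_identity(a.light.junction_nt, b.light.junction_nt) >= threshold
    )


def compute_clonotypes(
    cells: Sequence[CellRecord], cdr3_nt_identity: float = 0.85
) -> ClonotypeAssignment:
    """Single-linkage clonotypes within donors; fills ``clonotype_id`` in place.

    Linkage requires shared heavy V/J, shared light V/J, equal junction
    nucleotide lengths on both chains, and per-chain junction identity of at
    least ``cdr3_nt_identity``.
    """
    blocks: Dict[tuple, List[CellRecord]] = {}
    for cell in cells:
        key = (
            cell.donor_id,
            cell.heavy.v_gene,
            cell.heavy.j_gene,
            cell.light.v_gene,
            cell.light.j_gene,
            len(cell.heavy.junction_nt),
            len(cell.light.junction_nt),
        )
        blocks.setdefault(key, []).append(cell)

    dsu = DisjointSet([c.cell_id for c in cells])
    for block in blocks.values():
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                if _same_clonotype(block[i], block[j], cdr3_nt_identity):
                    dsu.union(block[i].cell_id, block[j].cell_id)

    donor_of = {c.cell_id: c.donor_id for c in cells}
    mapping: Dict[str, str] = {}
    counters: Dict[str, int] = {}
    root_label: Dict[str, str] = {}
    for cell in sorted(cells, key=lambda c: c.cell_id):
        root = dsu.find(cell.cell_id)
        if root not in root_label:
            donor = donor_of[root]
            counters[donor] = counters.get(donor, 0) + 1
            root_label[root] = f"{donor}.ct{counters[donor]:05d}"
        mapping[cell.cell_id] = root_label[root]
    for cell in cells:
        cell.clonotype_id = mapping[cell.cell_id]
    return ClonotypeAssignment(mapping=mapping, cdr3_nt_identity=cdr3_nt_identity)


def one_cell_per_clonotype(
    cells: Sequence[CellRecord],
    assignment: ClonotypeAssignment,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[CellRecord]:
    """Uniformly sample one cell per clonotype (deterministic under a seed)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    by_ct: Dict[str, List[CellRecord]] = {}
    for cell in cells:
        by_ct.setdefault(assignment.of(cell.cell_id), []).append(cell)
    kept = []
    for ct in sorted(by_ct):
        members = sorted(by_ct[ct], key=lambda c: c.cell_id)
        kept.append(members[rng.integers(len(members))])
    return kept


# ---------------------------------------------------------------------------
# same-donor independent-recombination conditions
# ---------------------------------------------------------------------------


def _fwr4_supports_distinct_j(
    a: CellRecord, b: CellRecord, reference: GermlineReference, chain: str,
    min_discriminating: int,
) -> bool:
    """FWR4 evidence that two same-donor cells used different J genes.

    True when, over positions where the two cells' J reference FWR4
    sequences differ (3'-anchored comparison), at least ``min_discriminating``
    positions show each cell matching its own reference — and no such
    position shows both cells supporting the same single reference.
    """
    ca, cb = getattr(a, chain), getattr(b, chain)
    if ca.j_gene == cb.j_gene:
        return False
    ref_a = reference.get(ca.j_gene)
    ref_b = reference.get(cb.j_gene)
    obs_a, obs_b = ca.fwr4_nt, cb.fwr4_nt
    fa, fb = ref_a.fwr4_seq, ref_b.fwr4_seq
    n = min(len(obs_a), len(obs_b), len(fa), len(fb))
    if n == 0:
        return False
    # right-align: FWR4 is anchored at the 3' end of the J gene
    obs_a, obs_b, fa, fb = obs_a[-n:], obs_b[-n:], fa[-n:], fb[-n:]
    consistent = 0
    for x, y, ra, rb in zip(obs_a, obs_b, fa, fb):
        if ra == rb:
            continue
        if x == ra and y == rb:
            consistent += 1
        elif x == y and (x == ra or x == rb):
            return False  # both cells support just one of the references
    return consistent >= min_discriminating


def independent_recombination_check(
    cell_a: CellRecord,
    cell_b: CellRecord,
    reference: GermlineReference,
    min_discriminating: int = 3,
) -> bool:
    """Evidence that two same-donor cells arose from separate recombinations.

    At least one of: (1) heavy FWR4 supports different heavy J genes,
    (2) the same for the light chain, (3) the light chain CDR3 lengths
    differ. Symmetric in its arguments.
    """
    if len(cell_a.light.junction_aa) != len(cell_b.light.junction_aa):
        return True
    if _fwr4_supports_distinct_j(cell_a, cell_b, reference, "heavy", min_discriminating):
        return True
    return _fwr4_supports_distinct_j(cell_a, cell_b, reference, "light", min_discriminating)


def swap_class_labels(
    cells: Sequence[CellRecord], fraction: float = 0.10, seed: int = 0
) -> List[CellRecord]:
    """Copy cells with naive/memory labels flipped for round(fraction*n) cells.

    Used to probe how robust coherence estimates are to misclassification.
    """
    rng = np.random.default_rng(seed)
    out = [c.copy() for c in cells]
    n_flip = int(round(fraction * len(out)))
    if n_flip == 0:
        return out
    idx = rng.choice(len(out), size=n_flip, replace=False)
    for i in idx:
        if out[i].cell_class == "naive":
            out[i].cell_class = "memory"
        elif out[i].cell_class == "memory":
            out[i].cell_class = "naive"
    return out
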