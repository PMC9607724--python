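"""Transitive similarity grouping of memory cells (functional grouping).

Two cells are *similar* when they belong to the same computed clonotype,
or share the heavy chain V gene and have CDRH3 amino acid identity at or
above a threshold (equal length required). Cells X and Y land in the same
*transitive group* when a chain of pairwise-similar cells connects them —
the connected components of the similarity graph, computed with
union-find. Groups partition all cells in scope; scope is memory cells
belonging to all-memory clonotypes.

Group-level summaries report light chain coherence two ways: over
cross-donor member pairs (pair-level) and as the fraction of member cells
using the group's modal light V gene (cell-level), plus per-position
Shannon entropy of the CDR3s for logo-style conservation profiles.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import DisjointSet
from .alleles import normalize_gene_name
from .classify import ClonotypeAssignment
from .coherence import cdrh3_identity_bin
from .repio import CellRecord


def memory_scope_cells(
    cells: Sequence[CellRecord], assignment: ClonotypeAssignment
) -> List[CellRecord]:
    """Memory cells that belong to clonotypes consisting entirely of memory cells."""
    class_by_ct: Dict[str, set] = {}
    for cell in cells:
        class_by_ct.setdefault(assignment.of(cell.cell_id), set()).add(cell.cell_class)
    return [
        c
        for c in cells
        if c.cell_class == "memory"
        and class_by_ct[assignment.of(c.cell_id)] == {"memory"}
    ]


def cells_similar(
    a: CellRecord,
    b: CellRecord,
    identity_threshold: float = 90.0,
    assignment: Optional[ClonotypeAssignment] = None,
) -> bool:
    """Same clonotype, or same heavy V gene with CDRH3 identity >= threshold."""
    if assignment is not None and assignment.of(a.cell_id) == assignment.of(b.cell_id):
        return True
    if a.heavy.v_gene != b.heavy.v_gene:
        return False
    if len(a.heavy.cdr3_aa) != len(b.heavy.cdr3_aa):
        return False
    percent, _ = cdrh3_identity_bin(a.heavy.cdr3_aa, b.heavy.cdr3_aa)
    return percent >= identity_threshold


@dataclass
class TransitiveGroup:
    group_id: str
    cell_ids: List[str]
    clonotype_ids: List[str]
    donors: List[str]

    @property
    def size(self) -> int:
        return len(self.cell_ids)


def build_transitive_groups(
    cells: Sequence[CellRecord],
    identity_threshold: float = 90.0,
    assignment: Optional[ClonotypeAssignment] = None,
    restrict_to_memory: bool = True,
) -> List[TransitiveGroup]:
    """Connected components of the similarity relation, via union-find.

    With ``restrict_to_memory`` (and an assignment), scope is memory cells
    in all-memory clonotypes. The result is a partition of the scoped cells,
    invariant to input order; group ids are assigned by size (largest first)
    with the smallest member cell id as tie-break.
    """
    scoped = list(cells)
    if restrict_to_memory and assignment is not None:
        scoped = memory_scope_cells(scoped, assignment)
    dsu = DisjointSet([c.cell_id for c in scoped])

    if assignment is not None:
        by_ct: Dict[str, List[CellRecord]] = {}
        for cell in scoped:
            by_ct.setdefault(assignment.of(cell.cell_id), []).append(cell)
        for members in by_ct.values():
            for a, b in zip(members, members[1:]):
                dsu.union(a.cell_id, b.cell_id)

    blocks: Dict[tuple, List[CellRecord]] = {}
    for cell in scoped:
        blocks.setdefault(
            (cell.heavy.v_gene, len(cell.heavy.cdr3_aa)), []
        ).append(cell)
    for block in blocks.values():
        for a, b in itertools.combinations(block, 2):
            percent, _ = cdrh3_identity_bin(a.heavy.cdr3_aa, b.heavy.cdr3_aa)
            if percent >= identity_threshold:
                dsu.union(a.cell_id, b.cell_id)

    cells_by_id = {c.cell_id: c for c in scoped}
    raw_groups: Dict[str, List[str]] = {}
    for cell in scoped:
        raw_groups.setdefault(dsu.find(cell.cell_id), []).append(cell.cell_id)
    ordered = sorted(
        (sorted(ids) for ids in raw_groups.values()),
        key=lambda ids: (-len(ids), ids[0]),
    )
    groups = []
    for i, ids in enumerate(ordered):
        members = [cells_by_id[x] for x in ids]
        groups.append(
            TransitiveGroup(
                group_id=f"g{i + 1:05d}",
                cell_ids=ids,
                clonotype_ids=sorted(
                    {assignment.of(x) for x in ids} if assignment is not None else set()
                ),
                donors=sorted({m.donor_id for m in members}),
            )
        )
    return groups


@dataclass
class GroupCoherence:
    """Light chain coherence of one transitive group, two accountings."""

    pair_coherence: float
    n_cross_donor_pairs: int
    modal_light_gene: Optional[str]
    n_consistent_cells: int
    n_cells: int

    @property
    def cell_coherence(self) -> float:
        return self.n_consistent_cells / self.n_cells if self.n_cells else float("nan")


def group_coherence(
    group: TransitiveGroup,
    cells_by_id: Mapping[str, CellRecord],
    merge_paralogs: bool = True,
) -> GroupCoherence:
    """Pair-level (cross-donor) and modal-gene cell-level coherence of a group.

    Pair coherence is NaN for single-donor groups (no cross-donor pairs).
    """
    members = [cells_by_id[x] for x in group.cell_ids]
    genes = [normalize_gene_name(m.light.v_gene, merge_paralogs) for m in members]
    modal_gene, modal_n = (None, 0)
    if genes:
        modal_gene, modal_n = Counter(genes).most_common(1)[0]
    hits = total = 0
    for (a, ga), (b, gb) in itertools.combinations(zip(members, genes), 2):
        if a.donor_id == b.donor_id:
            continue
        total += 1
        hits += ga == gb
    return GroupCoherence(
        pair_coherence=hits / total if total else float("nan"),
        n_cross_donor_pairs=total,
        modal_light_gene=modal_gene,
        n_consistent_cells=modal_n,
        n_cells=len(members),
    )


def coherence_vs_size(
    cells: Sequence[CellRecord],
    assignment: ClonotypeAssignment,
    thresholds: Sequence[float] = (100.0, 90.0, 80.0, 70.0, 60.0),
    merge_paralogs: bool = True,
) -> pd.DataFrame:
    """One row per group per identity threshold: size vs coherence.

    Lowering the threshold only merges groups (the partition at a higher
    threshold refines the one at a lower threshold), so the table shows how
    coherence decays as transitivity reaches further.
    """
    cells_by_id = {c.cell_id: c for c in cells}
    rows = []
    for threshold in thresholds:
        for group in build_transitive_groups(cells, threshold, assignment):
            gc = group_coherence(group, cells_by_id, merge_paralogs)
            rows.append(
                {
                    "identity_threshold": threshold,
                    "group_id": group.group_id,
                    "size": group.size,
                    "n_donors": len(group.donors),
                    "pair_coherence": gc.pair_coherence,
                    "cell_coherence": gc.cell_coherence,
                    "modal_light_gene": gc.modal_light_gene,
                }
            )
    return pd.DataFrame(rows)


def positionwise_entropy(sequences: Sequence[str]) -> np.ndarray:
    """Shannon entropy per column, in bits, over equal-length sequences."""
    if not sequences:
        return np.zeros(0)
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("positionwise entropy requires equal-length sequences")
    out = np.zeros(length)
    for i in range(length):
        counts = np.array(list(Counter(s[i] for s in sequences).values()), dtype=float)
        p = counts / counts.sum()
        out[i] = float(-(p * np.log2(p)).sum())
    return np.maximum(out, 0.0)  # avoid -0.0 for fully conserved columns


def group_entropy_profiles(
    group: TransitiveGroup, cells_by_id: Mapping[str, CellRecord]
) -> Dict[str, np.ndarray]:
    """CDRH3/CDRL3 per-position entropy over the group's modal-length sequences.

    Sequences of non-modal length are excluded rather than aligned; this is
    a documented simplification (no multiple alignment is embedded).
    """
    members = [cells_by_id[x] for x in group.cell_ids]
    profiles = {}
    for label, seqs in (
        ("cdrh3", [m.heavy.cdr3_aa for m in members]),
        ("cdrl3", [m.light.cdr3_aa for m in members]),
    ):
        modal_len = Counter(len(s) for s in seqs).most_common(1)[0][0]
        profiles[label] = positionwise_entropy([s for s in seqs if len(s) == modal_len])
    return profiles
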