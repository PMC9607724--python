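"""Gene-name normalization and donor germline allele inference.

Individual donors carry V gene alleles that differ from the reference
assembly. Treating such germline polymorphisms as somatic hypermutation
would misclassify naive cells as memory, so alternate alleles are inferred
per donor from a pileup of expressed V sequences before any mutation
counting.

The pileup heuristic avoids clonal-expansion bias without requiring
clonotypes (which are computed later): among cells using a given V gene,
only one representative is kept per (CDRH3 length, CDRL3 length, partner
chain V, partner chain J) stratum. A position is called variant when a
non-reference base occurs at least ``min_count`` times and makes up at
least ``min_fraction`` of the pileup at that position; the last
``tail_exclusion`` bases of the V gene are excluded to stay clear of the
junction. Each cell's footprint (its bases over the variant positions)
that itself meets the same evidence thresholds defines an alternate
allele; the number of alternates per gene is not capped, since extras can
arise from duplicated gene copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import count_mismatches
from .errors import MalformedName, NoReferenceForGene
from .repio import CellRecord, GermlineReference

_NAME_RE = re.compile(r"^IG[HKL][VDJ]\S*$")
_PARALOG_RE = re.compile(r"(?<=\d)D-")


def normalize_gene_name(name: str, merge_paralogs: bool = False) -> str:
    """Canonical gene name: allele suffix stripped, paralogs optionally merged.

    With ``merge_paralogs`` the duplicated-locus "D" marker directly before
    the hyphenated index is removed, so e.g. ``IGKV1D-17`` and ``IGKV1-17``
    become the same name.
    """
    base = name.split("*", 1)[0].strip()
    if not _NAME_RE.match(base):
        raise MalformedName(f"not an immunoglobulin gene name: {name!r}")
    if merge_paralogs:
        base = _PARALOG_RE.sub("-", base, count=1)
    return base


def select_pileup_cells(
    cells: Sequence[CellRecord], v_gene: str, chain: str = "heavy"
) -> List[CellRecord]:
    """One representative cell per non-redundancy stratum for a V gene pileup.

    Strata are (CDRH3 length, CDRL3 length, partner-chain V, partner-chain J);
    the representative is the lexicographically smallest ``cell_id`` so the
    choice is deterministic.
    """
    partner = "light" if chain == "heavy" else "heavy"
    best: Dict[tuple, CellRecord] = {}
    for cell in cells:
        own = getattr(cell, chain)
        if own.v_gene != v_gene:
            continue
        other = getattr(cell, partner)
        key = (len(cell.heavy.junction_aa), len(cell.light.junction_aa),
               other.v_gene, other.j_gene)
        if key not in best or cell.cell_id < best[key].cell_id:
            best[key] = cell
    return sorted(best.values(), key=lambda c: c.cell_id)


@dataclass(frozen=True)
class AlleleVariant:
    """An inferred alternate allele for one donor's V gene.

    ``positions`` are 0-based coordinates within the V gene (all strictly
    before ``len(V) - tail_exclusion``); ``footprint`` gives the base at
    each position, and ``support_count`` the number of non-redundant cells
    carrying that footprint.
    """

    donor_id: str
    v_gene: str
    positions: Tuple[int, ...]
    footprint: str
    support_count: int

    @property
    def allele_id(self) -> str:
        return "alt:" + ",".join(
            f"{p}{b}" for p, b in zip(self.positions, self.footprint)
        )

    def apply_to(self, ref_seq: str) -> str:
        seq = list(ref_seq)
        for pos, base in zip(self.positions, self.footprint):
            seq[pos] = base
        return "".join(seq)


@dataclass
class AlleleTable:
    """Per-donor, per-V-gene alternate alleles plus the evidence parameters."""

    variants: Dict[Tuple[str, str], List[AlleleVariant]] = field(default_factory=dict)
    min_count: int = 4
    min_fraction: float = 0.25
    tail_exclusion: int = 15

    def variants_for(self, donor_id: str, v_gene: str) -> List[AlleleVariant]:
        return self.variants.get((donor_id, v_gene), [])

    def alleles_for(
        self, donor_id: str, v_gene: str, reference: GermlineReference
    ) -> List[Tuple[str, str]]:
        """(allele_id, sequence) candidates; the reference allele comes first."""
        ref = reference.get(v_gene)
        out = [("ref", ref.seq)]
        for variant in self.variants_for(donor_id, v_gene):
            out.append((variant.allele_id, variant.apply_to(ref.seq)))
        return out

    def n_variants(self) -> int:
        return sum(len(v) for v in self.variants.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "donor_id": v.donor_id,
                "v_gene": v.v_gene,
                "positions": ",".join(map(str, v.positions)),
                "footprint": v.footprint,
                "support_count": v.support_count,
            }
            for vs in self.variants.values()
            for v in vs
        ]
        return pd.DataFrame(
            rows, columns=["donor_id", "v_gene", "positions", "footprint",
                           "support_count"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pileup_variant_positions(
    prefixes: List[str], ref_seq: str, limit: int, min_count: int, min_fraction: float
) -> List[int]:
    """Variant positions among cell V prefixes vs the reference, below ``limit``."""
    positions: List[int] = []
    for pos in range(limit):
        counts: Dict[str, int] = {}
        for prefix in prefixes:
            if pos < len(prefix):
                base = prefix[pos]
                counts[base] = counts.get(base, 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        ref_base = ref_seq[pos]
        for base, n in counts.items():
            if base != ref_base and n >= min_count and n / total >= min_fraction:
                positions.append(pos)
                break
    return positions


def infer_alleles(
    cells: Sequence[CellRecord],
    reference: GermlineReference,
    min_count: int = 4,
    min_fraction: float = 0.25,
    tail_exclusion: int = 15,
    chains: Iterable[str] = ("heavy", "light"),
) -> AlleleTable:
    """Infer per-donor alternate V alleles from expressed-sequence pileups.

    Cells are stratified per donor and per V gene, de-redundified with
    :func:`select_pileup_cells`, and piled up over the V region 5' of the
    junction. The output is independent of input cell order.
    """
    table = AlleleTable(min_count=min_count, min_fraction=min_fraction,
                        tail_exclusion=tail_exclusion)
    by_donor_gene: Dict[Tuple[str, str, str], List[CellRecord]] = {}
    for cell in cells:
        for chain in chains:
            anno = getattr(cell, chain)
            by_donor_gene.setdefault(
                (cell.donor_id, chain, anno.v_gene), []
            ).append(cell)

    for (donor, chain, v_gene), group in sorted(by_donor_gene.items()):
        try:
            ref = reference.get(v_gene)
        except NoReferenceForGene:
            raise
        selected = select_pileup_cells(group, v_gene, chain=chain)
        prefixes = []
        for cell in selected:
            anno = getattr(cell, chain)
            if anno.junction_start is None or not anno.seq_nt:
                continue
            prefixes.append(anno.seq_nt[: anno.junction_start])
        if not prefixes:
            continue
        limit = min(len(ref.seq) - tail_exclusion, max(map(len, prefixes)))
        positions = _pileup_variant_positions(
            prefixes, ref.seq, limit, min_count, min_fraction
        )
        if not positions:
            continue
        ref_footprint = "".join(ref.seq[p] for p in positions)
        footprints: Dict[str, int] = {}
        for prefix in prefixes:
            if any(p >= len(prefix) for p in positions):
                continue
            fp = "".join(prefix[p] for p in positions)
            footprints[fp] = footprints.get(fp, 0) + 1
        total = sum(footprints.values())
        variants = [
            AlleleVariant(donor, v_gene, tuple(positions), fp, n)
            for fp, n in sorted(footprints.items())
            if fp != ref_footprint and n >= min_count and n / total >= min_fraction
        ]
        if variants:
            key = (donor, v_gene)
            table.variants.setdefault(key, []).extend(variants)
    return table


@dataclass(frozen=True)
class AlleleAssignment:
    """Best-matching allele for one chain of one cell."""

    allele_id: str
    seq: str
    mismatches: int
    ambiguous: bool = False


def assign_allele(
    cell: CellRecord,
    allele_table: AlleleTable,
    reference: GermlineReference,
    chain: str = "heavy",
) -> AlleleAssignment:
    """Pick the donor allele minimizing mismatches against the cell's V region.

    Ties are broken toward the reference allele and flagged ``ambiguous``.
    """
    anno = getattr(cell, chain)
    if anno.junction_start is None or not anno.seq_nt:
        raise NoReferenceForGene(
            f"cell {cell.cell_id}: no full-length sequence for the {chain} chain"
        )
    prefix = anno.seq_nt[: anno.junction_start]
    candidates = allele_table.alleles_for(cell.donor_id, anno.v_gene, reference)
    scored = []
    for allele_id, seq in candidates:
        n = count_mismatches(prefix, seq[: len(prefix)])
        scored.append((n, allele_id, seq))
    best_n = min(s[0] for s in scored)
    winners = [s for s in scored if s[0] == best_n]
    # reference first in candidate order, so winners[0] is the tie-break winner
    n, allele_id, seq = winners[0]
    return AlleleAssignment(allele_id, seq, n, ambiguous=len(winners) > 1)
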