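"""Repertoire input/output.

Reads and writes the on-disk formats used around the analysis — germline
FASTA with IMGT-style ``gene*allele`` headers, AIRR Rearrangement TSV,
10x-style filtered contig annotation CSV, and the package's canonical
per-cell TSV interchange format — and assembles per-barcode chain
annotations into :class:`CellRecord` objects (one productive heavy plus one
productive light chain per cell).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .errors import (
    DuplicateGene,
    InconsistentDonor,
    MalformedHeader,
    MissingColumn,
    MissingReference,
    NoReferenceForGene,
)

HEAVY_LOCUS = "IGH"
LIGHT_LOCI = ("IGK", "IGL")

_GENE_RE = re.compile(r"^(IG[HKL])([VDJ])\S*$")


def strip_allele(call: str) -> str:
    """Drop an IMGT ``*NN`` allele suffix from a gene call string."""
    return call.split("*", 1)[0].strip()


def locus_of_gene(name: str) -> str:
    m = _GENE_RE.match(name)
    if not m:
        raise MalformedHeader(f"cannot parse gene name {name!r}")
    return m.group(1)


def segment_of_gene(name: str) -> str:
    """Segment type (V, D or J) inferred from an IG gene symbol."""
    m = _GENE_RE.match(name)
    if not m:
        raise MalformedHeader(f"cannot parse gene name {name!r}")
    return m.group(2)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ChainAnnotation:
    """One rearranged antibody chain of a single cell.

    ``junction_nt``/``junction_aa`` span the conserved cysteine through the
    conserved W/F inclusive; ``cdr3_aa`` follows the same convention (the
    flanking C and W/F are retained), so it equals ``junction_aa``.
    ``junction_start``/``junction_end`` locate the junction within
    ``seq_nt`` (0-based half-open); they are ``None`` when the full-length
    sequence is unavailable (e.g. 10x contig annotation CSV input).
    """

    locus: str
    v_gene: str
    j_gene: str
    d_gene: Optional[str] = None
    v_allele_call: str = ""
    junction_nt: str = ""
    junction_aa: str = ""
    seq_nt: str = ""
    junction_start: Optional[int] = None
    junction_end: Optional[int] = None
    isotype: Optional[str] = None
    productive: bool = True

    @property
    def is_heavy(self) -> bool:
        return self.locus == HEAVY_LOCUS

    @property
    def cdr3_aa(self) -> str:
        """CDR3 amino acids, junction-style (conserved C ... W/F retained)."""
        return self.junction_aa

    @property
    def fwr4_nt(self) -> str:
        """Framework-4 nucleotides: everything 3' of the junction."""
        if self.junction_end is None or not self.seq_nt:
            return ""
        return self.seq_nt[self.junction_end:]


@dataclass
class CellRecord:
    """One B cell: exactly one heavy and one light chain plus metadata."""

    cell_id: str
    donor_id: str
    dataset_id: str
    heavy: ChainAnnotation
    light: ChainAnnotation
    sort_label: str = "unknown"
    shm_count: Optional[int] = None
    cell_class: str = "unset"
    clonotype_id: Optional[str] = None

    def copy(self) -> "CellRecord":
        return replace(self, heavy=replace(self.heavy), light=replace(self.light))


@dataclass
class GermlineGene:
    """One germline segment sequence.

    For V genes ``cys_position`` is the 0-based start of the conserved
    cysteine codon (junction 5' boundary); for J genes ``w_position`` is the
    start of the conserved W/F codon, so the junction ends at
    ``w_position + 3`` and FWR4 begins there.
    """

    gene: str
    allele: str
    locus: str
    segment: str
    seq: str
    cys_position: Optional[int] = None
    w_position: Optional[int] = None

    @property
    def name(self) -> str:
        return f"{self.gene}*{self.allele}"

    @property
    def junction_overlap(self) -> int:
        """Number of bases this segment contributes to an untrimmed junction."""
        if self.segment == "V":
            if self.cys_position is None:
                raise NoReferenceForGene(
                    f"{self.name}: V gene lacks a cys_position annotation"
                )
            return len(self.seq) - self.cys_position
        if self.segment == "J":
            if self.w_position is None:
                raise NoReferenceForGene(
                    f"{self.name}: J gene lacks a w_position annotation"
                )
            return self.w_position + 3
        return len(self.seq)

    @property
    def fwr4_seq(self) -> str:
        if self.segment != "J":
            raise ValueError("FWR4 is defined for J genes only")
        return self.seq[self.junction_overlap:]


class GermlineReference:
    """Collection of germline V/D/J segments keyed by (gene, allele)."""

    def __init__(self, genes: Iterable[GermlineGene] = ()):  # noqa: D401
        self._by_key: Dict[Tuple[str, str], GermlineGene] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GermlineGene) -> None:
        key = (gene.gene, gene.allele)
        if key in self._by_key:
            raise DuplicateGene(f"duplicate reference record {gene.name}")
        self._by_key[key] = gene

    def get(self, gene: str, allele: str = "01") -> GermlineGene:
        try:
            return self._by_key[(gene, allele)]
        except KeyError:
            raise NoReferenceForGene(f"no reference sequence for {gene}*{allele}")

    def has_gene(self, gene: str) -> bool:
        return any(k[0] == gene for k in self._by_key)

    def genes_of(self, segment: str, locus: Optional[str] = None) -> List[GermlineGene]:
        out = [
            g
            for g in self._by_key.values()
            if g.segment == segment and (locus is None or g.locus == locus)
        ]
        return sorted(out, key=lambda g: (g.gene, g.allele))

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(sorted(self._by_key.values(), key=lambda g: (g.gene, g.allele)))

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for g in self:
                extra = ""
                if g.cys_position is not None:
                    extra += f" cys={g.cys_position}"
                if g.w_position is not None:
                    extra += f" w={g.w_position}"
                fh.write(f">{g.name}{extra}\n{g.seq}\n")


# ---------------------------------------------------------------------------
# germline FASTA
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r"(\w+)=(\S+)")


def read_germline_fasta(path) -> GermlineReference:
    """Parse a germline V/D/J FASTA with IMGT-style ``gene*allele`` headers.

    Optional ``cys=N`` / ``w=N`` tokens in the description annotate the
    conserved cysteine (V) and W/F (J) codon starts.
    """
    reference = GermlineReference()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        name = record.id
        if "*" in name:
            gene, allele = name.split("*", 1)
        else:
            gene, allele = name, "01"
        m = _GENE_RE.match(gene)
        if not m:
            raise MalformedHeader(f"unparseable germline header {name!r}")
        annotations = dict(_KV_RE.findall(record.description))
        cys = int(annotations["cys"]) if "cys" in annotations else None
        w = int(annotations["w"]) if "w" in annotations else None
        reference.add(
            GermlineGene(
                gene=gene,
                allele=allele,
                locus=m.group(1),
                segment=m.group(2),
                seq=str(record.seq).upper(),
                cys_position=cys,
                w_position=w,
            )
        )
    if n == 0:
        raise MissingReference(f"no sequences found in {path}")
    return reference


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV
# ---------------------------------------------------------------------------

_AIRR_REQUIRED = [
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "sequence",
    "productive",
]

_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUE_STRINGS


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumn(f"{path}: missing required column(s) {missing}")


def _opt_int(value) -> Optional[int]:
    if value is None or value == "":
        return None
    return int(float(value))


@dataclass
class ChainReadResult:
    """Chains grouped by barcode plus read metadata.

    ``meta`` carries any donor/dataset/sort columns found in the file, per
    barcode; ``skipped`` tallies rows that were dropped and why.
    """

    chains: Dict[str, List[ChainAnnotation]]
    meta: Dict[str, Dict[str, str]] = field(default_factory=dict)
    skipped: Dict[str, int] = field(default_factory=dict)


def read_airr_rearrangements(path) -> ChainReadResult:
    """Read an AIRR Rearrangement TSV into chains keyed by cell barcode.

    Non-productive rows and rows without a junction are skipped and counted
    in ``skipped``. Allele suffixes are stripped into ``v_gene`` etc.; the
    raw call is retained in ``v_allele_call``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require(df, _AIRR_REQUIRED, path)
    result = ChainReadResult(chains={})
    for row in df.itertuples(index=False):
        barcode = row.cell_id
        if not _as_bool(row.productive):
            result.skipped["nonproductive"] = result.skipped.get("nonproductive", 0) + 1
            continue
        if not row.junction or not row.junction_aa:
            result.skipped["no_junction"] = result.skipped.get("no_junction", 0) + 1
            continue
        d_call = getattr(row, "d_call", "")
        chain = ChainAnnotation(
            locus=row.locus,
            v_gene=strip_allele(row.v_call),
            d_gene=strip_allele(d_call) or None if d_call else None,
            j_gene=strip_allele(row.j_call),
            v_allele_call=row.v_call,
            junction_nt=row.junction,
            junction_aa=row.junction_aa,
            seq_nt=row.sequence,
            junction_start=_opt_int(getattr(row, "junction_start", "")),
            junction_end=_opt_int(getattr(row, "junction_end", "")),
            isotype=getattr(row, "c_call", "") or None,
            productive=True,
        )
        if chain.junction_start is None and chain.seq_nt and chain.junction_nt:
            pos = chain.seq_nt.find(chain.junction_nt)
            if pos >= 0:
                chain.junction_start = pos
                chain.junction_end = pos + len(chain.junction_nt)
        result.chains.setdefault(barcode, []).append(chain)
        meta = result.meta.setdefault(barcode, {})
        for key in ("donor_id", "dataset_id", "sort_label"):
            value = getattr(row, key, "")
            if value:
                meta[key] = value
    return result


# ---------------------------------------------------------------------------
# 10x filtered contig annotation CSV
# ---------------------------------------------------------------------------

_TENX_REQUIRED = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
                  "full_length", "productive"]


def read_10x_contigs(path) -> ChainReadResult:
    """Read a 10x ``filtered_contig_annotations.csv``-style file.

    Rows that are not full length, not productive, lack a CDR3 or carry an
    ambiguous chain label (``Multi``) are skipped and tallied. The 10x
    dialect reports no per-region nucleotide sequence, so ``seq_nt`` is
    empty and junction coordinates are unset.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require(df, _TENX_REQUIRED, path)
    result = ChainReadResult(chains={})

    def _skip(reason: str) -> None:
        result.skipped[reason] = result.skipped.get(reason, 0) + 1

    for row in df.itertuples(index=False):
        if row.chain not in (HEAVY_LOCUS, *LIGHT_LOCI):
            _skip("ambiguous_chain")
            continue
        if not _as_bool(row.full_length):
            _skip("not_full_length")
            continue
        if not _as_bool(row.productive):
            _skip("nonproductive")
            continue
        if not row.cdr3:
            _skip("no_junction")
            continue
        d_gene = getattr(row, "d_gene", "")
        result.chains.setdefault(row.barcode, []).append(
            ChainAnnotation(
                locus=row.chain,
                v_gene=strip_allele(row.v_gene),
                d_gene=strip_allele(d_gene) or None if d_gene and d_gene != "None" else None,
                j_gene=strip_allele(row.j_gene),
                v_allele_call=row.v_gene,
                junction_nt=row.cdr3_nt,
                junction_aa=row.cdr3,
                isotype=getattr(row, "c_gene", "") or None,
                productive=True,
            )
        )
    return result


# ---------------------------------------------------------------------------
# cell assembly
# ---------------------------------------------------------------------------


def assemble_cells(
    chains,
    donor_id: str = "unknown",
    dataset_id: str = "unknown",
    sort_label: str = "unknown",
) -> Tuple[List[CellRecord], Dict[str, int]]:
    """Pair chains into cells: one productive heavy + one productive light.

    Barcodes with any other configuration (unpaired, multiplet) are dropped
    and tallied by reason — they are never rescued.

    ``chains`` is either a :class:`ChainReadResult` (whose per-barcode
    metadata, when present, overrides the donor/dataset/sort arguments) or a
    plain mapping of barcode to chain list.
    """
    meta: Mapping[str, Mapping[str, str]] = {}
    if isinstance(chains, ChainReadResult):
        meta = chains.meta
        chains = chains.chains
    cells: List[CellRecord] = []
    dropped: Dict[str, int] = {"unpaired": 0, "multiplet": 0}
    for barcode, annos in chains.items():
        heavies = [c for c in annos if c.is_heavy and c.productive]
        lights = [c for c in annos if not c.is_heavy and c.productive]
        if len(heavies) == 1 and len(lights) == 1:
            m = meta.get(barcode, {})
            cells.append(
                CellRecord(
                    cell_id=barcode,
                    donor_id=m.get("donor_id", donor_id),
                    dataset_id=m.get("dataset_id", dataset_id),
                    sort_label=m.get("sort_label", sort_label),
                    heavy=heavies[0],
                    light=lights[0],
                )
            )
        elif len(heavies) > 1 or len(lights) > 1:
            dropped["multiplet"] += 1
        else:
            dropped["unpaired"] += 1
    return cells, dropped


# ---------------------------------------------------------------------------
# canonical per-cell TSV
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ["cell_id", "donor_id", "dataset_id", "sort_label",
                 "cell_class", "clonotype_id", "shm_count"]
_CHAIN_COLUMNS = ["locus", "v_gene", "d_gene", "j_gene", "v_allele_call",
                  "junction_nt", "junction_aa", "seq_nt",
                  "junction_start", "junction_end", "isotype", "productive"]

#: Default adapter from enclone-style per-cell table headers to this
#: package's canonical per-cell column names. This mapping is configuration:
#: pass your own dict to :func:`read_per_cell_table` if the table at hand
#: uses different headers. Chain 1 is heavy, chain 2 light.
ENCLONE_COLUMN_MAP = {
    "barcode": "cell_id",
    "donors_cell": "donor_id",
    "datasets_cell": "dataset_id",
    "v_name1": "heavy_v_gene",
    "d1_name1": "heavy_d_gene",
    "j_name1": "heavy_j_gene",
    "cdr3_aa1": "heavy_junction_aa",
    "cdr3_dna1": "heavy_junction_nt",
    "const1": "heavy_isotype",
    "v_name2": "light_v_gene",
    "j_name2": "light_j_gene",
    "cdr3_aa2": "light_junction_aa",
    "cdr3_dna2": "light_junction_nt",
    "const2": "light_isotype",
    "dref": "shm_count",
}


def _chain_to_columns(prefix: str, chain: ChainAnnotation) -> Dict[str, object]:
    return {f"{prefix}_{k}": getattr(chain, k) for k in _CHAIN_COLUMNS}


def _chain_from_row(prefix: str, row: Mapping[str, str]) -> ChainAnnotation:
    def col(name, default=""):
        return row.get(f"{prefix}_{name}", default)

    locus = col("locus") or (HEAVY_LOCUS if prefix == "heavy" else "IGK")
    return ChainAnnotation(
        locus=locus,
        v_gene=col("v_gene"),
        d_gene=col("d_gene") or None,
        j_gene=col("j_gene"),
        v_allele_call=col("v_allele_call") or col("v_gene"),
        junction_nt=col("junction_nt"),
        junction_aa=col("junction_aa"),
        seq_nt=col("seq_nt"),
        junction_start=_opt_int(col("junction_start")),
        junction_end=_opt_int(col("junction_end")),
        isotype=col("isotype") or None,
        productive=_as_bool(col("productive", "T")),
    )


def write_per_cell_table(cells: Sequence[CellRecord], path) -> None:
    """Write cells to the canonical one-line-per-cell TSV (lossless)."""
    rows = []
    for cell in cells:
        row: Dict[str, object] = {
            "cell_id": cell.cell_id,
            "donor_id": cell.donor_id,
            "dataset_id": cell.dataset_id,
            "sort_label": cell.sort_label,
            "cell_class": cell.cell_class,
            "clonotype_id": cell.clonotype_id if cell.clonotype_id is not None else "",
            "shm_count": cell.shm_count if cell.shm_count is not None else "",
        }
        row.update(_chain_to_columns("heavy", cell.heavy))
        row.update(_chain_to_columns("light", cell.light))
        rows.append(row)
    columns = (_CELL_COLUMNS
               + [f"heavy_{c}" for c in _CHAIN_COLUMNS]
               + [f"light_{c}" for c in _CHAIN_COLUMNS])
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_per_cell_table(path, column_map: Optional[Mapping[str, str]] = None
                        ) -> List[CellRecord]:
    """Read a per-cell TSV back into :class:`CellRecord` objects.

    ``column_map`` renames foreign headers to canonical ones before parsing
    (see :data:`ENCLONE_COLUMN_MAP` for the shipped adapter for
    enclone-style deposited tables).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require(df, ["cell_id", "donor_id", "heavy_v_gene", "heavy_junction_aa",
                  "light_v_gene", "light_junction_aa"], path)
    donors_seen: Dict[str, str] = {}
    cells: List[CellRecord] = []
    for _, row in df.iterrows():
        cell_id = row["cell_id"]
        donor = row["donor_id"]
        if cell_id in donors_seen and donors_seen[cell_id] != donor:
            raise InconsistentDonor(
                f"cell {cell_id!r} listed under donors "
                f"{donors_seen[cell_id]!r} and {donor!r}"
            )
        donors_seen[cell_id] = donor
        shm = row.get("shm_count", "")
        cells.append(
            CellRecord(
                cell_id=cell_id,
                donor_id=donor,
                dataset_id=row.get("dataset_id", "") or "unknown",
                sort_label=row.get("sort_label", "") or "unknown",
                cell_class=row.get("cell_class", "") or "unset",
                clonotype_id=row.get("clonotype_id", "") or None,
                shm_count=_opt_int(shm),
                heavy=_chain_from_row("heavy", row),
                light=_chain_from_row("light", row),
            )
        )
    return cells
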