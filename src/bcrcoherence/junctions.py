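"""Heavy-chain junction decomposition against VJ / VDJ / VDDJ references.

Every heavy junction (conserved C codon through conserved W codon) is
explained as a recombination product: a 3'-trimmed prefix of the V gene's
junction overlap, zero, one or two trimmed D segments, non-templated (N)
insertions between segments, and a 5'-trimmed prefix-removed J junction
overlap. For each candidate reference concatenation (V·J, V·D·J, or
V·D1·D2·J over ordered pairs of distinct Ds) a segment-anchored dynamic
program finds the highest-scoring decomposition; the best candidate gives
the topology, the chosen D gene(s), the number of inserted bases (junction
bases absent from the reference), deleted bases (trimmed reference bases,
counted separately), and substitutions (mismatches within aligned blocks).

The alignment model is deliberately structural rather than a free global
alignment: kept reference regions are a prefix of V, a contiguous substring
of each D and a suffix of J, which are the only configurations V(D)J
recombination can produce. Deletions are therefore confined to segment
ends and insertions to the joints; a substitution in the middle of a
segment can never be re-expressed as an indel pair. Scoring: match +1,
mismatch -1, inserted base -0.25, trimmed reference base -0.5 (all dyadic,
so float arithmetic is exact and tie comparisons are reliable; insertion
plus deletion stays below the mismatch cost so boundary trims are never
collapsed into fake substitutions, while the relatively expensive deletion
keeps short chance matches from being promoted to spurious D segments).

The substitution rate denominator is the total number of matching plus
mismatching bases across all aligned blocks of the junction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import NoCandidates
from .repio import CellRecord, GermlineReference

NEG = float("-inf")


@dataclass(frozen=True)
class Scoring:
    """Decomposition scoring. Costs are positive numbers (subtracted)."""

    match: float = 1.0
    mismatch: float = -1.0
    insertion: float = 0.25
    deletion: float = 0.5


@dataclass(frozen=True)
class Candidate:
    """One reference concatenation hypothesis for a junction."""

    topology: str  # VJ | VDJ | VDDJ
    v_gene: str
    j_gene: str
    d_genes: Tuple[str, ...]
    v_part: str
    d_parts: Tuple[str, ...]
    j_part: str

    @property
    def seq(self) -> str:
        return self.v_part + "".join(self.d_parts) + self.j_part


@dataclass
class JunctionDecomposition:
    """Best reference explanation of one junction."""

    topology: str
    v_gene: str
    j_gene: str
    d_genes: Tuple[str, ...]
    inserted_bases: int
    deleted_bases: int
    substitutions: int
    aligned_bases: int
    score: float
    d_matches: Tuple[int, ...] = ()

    @property
    def substitution_rate(self) -> float:
        return self.substitutions / self.aligned_bases if self.aligned_bases else 0.0


def candidate_references(
    v_gene: str,
    j_gene: str,
    d_genes: Sequence[str],
    reference: GermlineReference,
) -> List[Candidate]:
    """All concatenation candidates: V·J, V·D·J, and V·D1·D2·J (ordered,
    distinct Ds). Candidate count is 1 + d + d(d-1)."""
    v = reference.get(v_gene)
    j = reference.get(j_gene)
    v_part = v.seq[v.cys_position:] if v.cys_position is not None else v.seq
    j_part = j.seq[: j.junction_overlap]
    out = [Candidate("VJ", v_gene, j_gene, (), v_part, (), j_part)]
    d_seqs = {name: reference.get(name).seq for name in d_genes}
    for name in d_genes:
        out.append(
            Candidate("VDJ", v_gene, j_gene, (name,), v_part, (d_seqs[name],), j_part)
        )
    for d1, d2 in itertools.permutations(d_genes, 2):
        out.append(
            Candidate(
                "VDDJ", v_gene, j_gene, (d1, d2), v_part,
                (d_seqs[d1], d_seqs[d2]), j_part,
            )
        )
    return out


# ---------------------------------------------------------------------------
# segment-anchored DP
# ---------------------------------------------------------------------------


def _insertion_scan(raw: np.ndarray, ins: float) -> np.ndarray:
    """best[t] = max_{e<=t} raw[e] - ins*(t-e)."""
    out = raw.copy()
    for t in range(1, len(out)):
        prev = out[t - 1] - ins
        if prev > out[t]:
            out[t] = prev
    return out


def _v_stage(s: str, v_part: str, sc: Scoring) -> Tuple[np.ndarray, np.ndarray]:
    """Raw and scanned scores for the V prefix stage."""
    m = len(s)
    limit = min(m, len(v_part))
    raw = np.full(m + 1, NEG)
    cum = 0.0
    raw[0] = -sc.deletion * len(v_part)
    for a in range(1, limit + 1):
        cum += sc.match if s[a - 1] == v_part[a - 1] else sc.mismatch
        raw[a] = cum - sc.deletion * (len(v_part) - a)
    return raw, _insertion_scan(raw, sc.insertion)


def _d_stage(
    s: str, d: str, h_prev: np.ndarray, sc: Scoring
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One D segment: returns (A matrix, raw scores, scanned scores).

    A[i, j] is the best score of a block alignment whose last aligned pair
    is (s[i-1], d[j-1]); entry into the block from h_prev pays the deleted
    D-prefix cost, exit pays the deleted D-suffix cost.
    """
    m, q = len(s), len(d)
    A = np.full((m + 1, q + 1), NEG)
    jarr = np.arange(q, dtype=float)
    d_arr = np.frombuffer(d.encode(), dtype=np.uint8)
    s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
    for i in range(1, m + 1):
        pair = np.where(d_arr == s_arr[i - 1], sc.match, sc.mismatch)
        entry = h_prev[i - 1] - sc.deletion * jarr
        A[i, 1:] = pair + np.maximum(A[i - 1, :q], entry)
    raw = h_prev - sc.deletion * q  # D fully deleted
    with np.errstate(invalid="ignore"):
        exit_scores = A[:, 1:] - sc.deletion * (q - np.arange(1, q + 1, dtype=float))
        if q:
            raw = np.maximum(raw, exit_scores.max(axis=1))
    return A, raw, _insertion_scan(raw, sc.insertion)


def _j_scores(s: str, j_part: str, sc: Scoring) -> np.ndarray:
    """score_j[L] for keeping the final L bases of the J junction overlap."""
    m, r = len(s), len(j_part)
    limit = min(m, r)
    out = np.full(limit + 1, NEG)
    out[0] = -sc.deletion * r
    cum = 0.0
    for L in range(1, limit + 1):
        cum += sc.match if s[m - L] == j_part[r - L] else sc.mismatch
        out[L] = cum - sc.deletion * (r - L)
    return out


@dataclass
class _Trace:
    inserted: int = 0
    deleted: int = 0
    substitutions: int = 0
    aligned: int = 0
    d_matches: List[int] = field(default_factory=list)


def _traceback_scan(raw: np.ndarray, scanned: np.ndarray, t: int, ins: float) -> int:
    """Largest e <= t with raw[e] - ins*(t-e) == scanned[t]."""
    target = scanned[t]
    for e in range(t, -1, -1):
        if raw[e] - ins * (t - e) == target:
            return e
    raise AssertionError("insertion scan traceback failed")


def _score_candidate(s: str, cand: Candidate, sc: Scoring) -> Tuple[float, _Trace]:
    """Run the staged DP for one candidate and trace back event counts."""
    m = len(s)
    v_raw, h = _v_stage(s, cand.v_part, sc)
    stages = []  # (A, raw, scanned, d_seq) per D segment
    for d in cand.d_parts:
        A, raw, h = _d_stage(s, d, h, sc)
        stages.append((A, raw, h, d))

    j_sc = _j_scores(s, cand.j_part, sc)
    totals = np.array(
        [h[m - L] + j_sc[L] for L in range(len(j_sc))]
    )
    L_j = int(np.flatnonzero(totals == totals.max())[-1])  # prefer fewer J trims
    score = float(totals[L_j])

    trace = _Trace()
    r = len(cand.j_part)
    trace.deleted += r - L_j
    trace.substitutions += sum(
        s[m - L] != cand.j_part[r - L] for L in range(1, L_j + 1)
    )
    trace.aligned += L_j
    t = m - L_j

    v_scanned = _insertion_scan(v_raw, sc.insertion)
    d_matches_rev: List[int] = []
    for k in range(len(stages) - 1, -1, -1):
        A, raw, scanned, d = stages[k]
        q = len(d)
        prev_scanned = stages[k - 1][2] if k > 0 else v_scanned
        e = _traceback_scan(raw, scanned, t, sc.insertion)
        trace.inserted += t - e
        # was the whole D deleted?
        if raw[e] == prev_scanned[e] - sc.deletion * q:
            trace.deleted += q
            d_matches_rev.append(0)
            t = e
            continue
        exit_vals = A[e, 1:] - sc.deletion * (q - np.arange(1, q + 1, dtype=float))
        j_star = int(np.flatnonzero(exit_vals == raw[e])[-1]) + 1
        trace.deleted += q - j_star
        i, j = e, j_star
        matches_here = 0
        while True:
            pair_match = s[i - 1] == d[j - 1]
            trace.aligned += 1
            if pair_match:
                matches_here += 1
            else:
                trace.substitutions += 1
            entry = prev_scanned[i - 1] - sc.deletion * (j - 1)
            diag = A[i - 1, j - 1] if (i - 1 >= 1 and j - 1 >= 1) else NEG
            base = A[i, j] - (sc.match if pair_match else sc.mismatch)
            if diag == base and diag >= entry:
                i, j = i - 1, j - 1
                continue
            trace.deleted += j - 1
            t = i - 1
            break
        d_matches_rev.append(matches_here)

    # V stage
    e = _traceback_scan(v_raw, v_scanned, t, sc.insertion)
    trace.inserted += t - e
    trace.deleted += len(cand.v_part) - e
    for a in range(e):
        trace.aligned += 1
        if s[a] != cand.v_part[a]:
            trace.substitutions += 1
    trace.d_matches = list(reversed(d_matches_rev))
    return score, trace


def _share_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i: i + k] for i in range(len(a) - k + 1)}
    return any(b[i: i + k] in kmers for i in range(len(b) - k + 1))


def decompose_junction(
    junction_nt: str,
    v_gene: str,
    j_gene: str,
    reference: GermlineReference,
    d_genes: Optional[Sequence[str]] = None,
    scoring: Scoring = Scoring(),
    min_d_support: int = 4,
    dd_kmer: int = 8,
) -> JunctionDecomposition:
    """Best-scoring V(D)(D)J decomposition of one heavy junction.

    A D segment (or a second D) is only called when its aligned block
    contains at least ``min_d_support`` matching bases; otherwise the
    simpler topology wins. To keep the VDDJ search tractable, ordered D
    pairs are only evaluated when both Ds share a ``dd_kmer``-mer with the
    junction (set ``dd_kmer=0`` to disable the prefilter).
    """
    if not junction_nt:
        raise NoCandidates("empty junction")
    if d_genes is None:
        locus = reference.get(v_gene).locus
        d_genes = [g.gene for g in reference.genes_of("D", locus)]
    candidates = candidate_references(v_gene, j_gene, d_genes, reference)
    if dd_kmer:
        hit = {
            name: _share_kmer(junction_nt, reference.get(name).seq, dd_kmer)
            for name in d_genes
        }
        candidates = [
            c for c in candidates
            if c.topology != "VDDJ" or all(hit[d] for d in c.d_genes)
        ]
    if not candidates:
        raise NoCandidates(f"no reference concatenations for {v_gene}/{j_gene}")

    scored = []
    for cand in candidates:
        score, trace = _score_candidate(junction_nt, cand, scoring)
        scored.append((score, cand, trace))
    # max score; ties broken toward fewer D segments, then gene names
    scored.sort(key=lambda x: (-x[0], len(x[1].d_genes), x[1].d_genes))
    for score, cand, trace in scored:
        if all(mm >= min_d_support for mm in trace.d_matches):
            return JunctionDecomposition(
                topology=cand.topology,
                v_gene=v_gene,
                j_gene=j_gene,
                d_genes=cand.d_genes,
                inserted_bases=trace.inserted,
                deleted_bases=trace.deleted,
                substitutions=trace.substitutions,
                aligned_bases=trace.aligned,
                score=score,
                d_matches=tuple(trace.d_matches),
            )
    raise AssertionError("unreachable: the VJ candidate is always eligible")


def decompose_cells(
    cells: Sequence[CellRecord],
    reference: GermlineReference,
    **kwargs,
) -> Dict[str, JunctionDecomposition]:
    """Decompose the heavy junction of every cell (heavy chains only)."""
    return {
        cell.cell_id: decompose_junction(
            cell.heavy.junction_nt, cell.heavy.v_gene, cell.heavy.j_gene,
            reference, **kwargs,
        )
        for cell in cells
    }


def insertion_profile(
    cells: Sequence[CellRecord],
    decompositions: Mapping[str, JunctionDecomposition],
    strata=None,
) -> Dict[str, pd.Series]:
    """Normalized inserted-base-count histogram per stratum.

    ``strata`` maps a cell to a stratum label (default: its naive/memory
    class). Strata with no cells are absent from the result.
    """
    if strata is None:
        strata = lambda c: c.cell_class  # noqa: E731
    counts: Dict[str, Dict[int, int]] = {}
    for cell in cells:
        if cell.cell_id not in decompositions:
            continue
        label = str(strata(cell))
        ins = decompositions[cell.cell_id].inserted_bases
        counts.setdefault(label, {})[ins] = counts.get(label, {}).get(ins, 0) + 1
    out = {}
    for label, hist in counts.items():
        series = pd.Series(hist).sort_index()
        out[label] = series / series.sum()
    return out


_BUCKETS = [0, 1, 2, 3, 4, 5, 6, 7, ">=8"]


def _bucket(n: int):
    return n if n < 8 else ">=8"


def coherence_by_insertion(
    pairs,
    decompositions: Mapping[str, JunctionDecomposition],
    identity_levels: Sequence[int] = (100, 90, 80),
    merge_paralogs: bool = True,
) -> pd.DataFrame:
    """Light chain coherence by junction inserted-base count.

    A pair's bucket requires both cells to have the same inserted-base
    count; pairs whose cells disagree are reported under the ``mixed``
    bucket. Rows cover counts 0..7 and >=8 for each minimum CDRH3 identity
    level.
    """
    from .coherence import pair_is_coherent

    rows = []
    for level in identity_levels:
        tallies: Dict[object, List[int]] = {b: [0, 0] for b in _BUCKETS + ["mixed"]}
        for pair in pairs:
            if pair.identity_percent < level:
                continue
            da = decompositions.get(pair.cell_a.cell_id)
            db = decompositions.get(pair.cell_b.cell_id)
            if da is None or db is None:
                continue
            ba, bb = _bucket(da.inserted_bases), _bucket(db.inserted_bases)
            bucket = ba if ba == bb else "mixed"
            tallies[bucket][0] += 1
            tallies[bucket][1] += pair_is_coherent(pair, merge_paralogs)
        for bucket in _BUCKETS + ["mixed"]:
            n, coh = tallies[bucket]
            rows.append(
                {
                    "min_identity": level,
                    "inserted_bases": bucket,
                    "pair_count": n,
                    "coherence": coh / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)
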