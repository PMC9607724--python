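"""Light chain coherence statistics over recurrent heavy chains.

Two B cells form an *eligible pair* when they share the same heavy chain V
gene name, have equal CDRH3 length, and are both memory or both naive.
Pairs are binned by CDRH3 amino acid percent identity (positional, no
alignment — equal length is a precondition), rounded down to the nearest
10%. The *light chain coherence* of a pair set is the fraction of pairs
whose light chain V gene names (optionally with duplicated-locus paralogs
merged) are identical.

Cross-donor pairs take the two cells from different donors (public
recurrences); same-donor pairs take them from different computed
clonotypes within one donor and additionally require positive evidence of
independent recombination events.

The module also provides the null models used to calibrate the statistic:
a light-chain permutation test (heavy chains fixed, one cell per
clonotype), an extra-sum-of-squares F test comparing regression slopes of
coherence curves, and a Monte-Carlo chi-square test of the Vh/Vl
clonotype contingency table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
from scipy import stats

from .alleles import normalize_gene_name
from .classify import (
    ClonotypeAssignment,
    independent_recombination_check,
    one_cell_per_clonotype,
)
from .errors import EmptyPairSet, LengthMismatch
from .repio import CellRecord, GermlineReference

BINS = tuple(range(0, 101, 10))


def cdrh3_identity_bin(cdr3_a: str, cdr3_b: str) -> Tuple[float, int]:
    """Percent identity of two equal-length CDR3s and its 10%-floor bin."""
    if len(cdr3_a) != len(cdr3_b):
        raise LengthMismatch(
            f"CDRH3 lengths differ: {len(cdr3_a)} vs {len(cdr3_b)}"
        )
    if not cdr3_a:
        return 100.0, 100
    matches = sum(x == y for x, y in zip(cdr3_a, cdr3_b))
    percent = 100.0 * matches / len(cdr3_a)
    return percent, min(int(percent // 10) * 10, 100)


@dataclass(frozen=True)
class CellPair:
    """An unordered eligible pair of cells."""

    cell_a: CellRecord
    cell_b: CellRecord
    scope: str
    identity_percent: float
    identity_bin: int

    @property
    def donor_pair(self) -> Tuple[str, str]:
        return tuple(sorted((self.cell_a.donor_id, self.cell_b.donor_id)))

    @property
    def dataset_pair(self) -> Tuple[str, str]:
        return tuple(sorted((self.cell_a.dataset_id, self.cell_b.dataset_id)))

    @property
    def cell_class(self) -> str:
        return self.cell_a.cell_class


def effective_class(cell: CellRecord, source: str = "computed") -> str:
    """Naive/memory label from the computed classifier or from flow sort."""
    if source == "computed":
        return cell.cell_class
    label = cell.sort_label
    if label == "naive":
        return "naive"
    if label in ("unswitched_memory", "switched_memory", "plasmablast"):
        return "memory"
    return "unknown"


def enumerate_pairs(
    cells: Sequence[CellRecord],
    scope: str = "cross_donor",
    cell_class: str = "memory",
    assignment: Optional[ClonotypeAssignment] = None,
    reference: Optional[GermlineReference] = None,
    class_source: str = "computed",
    donor_key: Optional[Callable[[CellRecord], str]] = None,
) -> List[CellPair]:
    """All and only the eligible pairs for a scope.

    ``scope`` is ``cross_donor`` (different donors) or ``same_donor`` (same
    donor, different computed clonotypes, independent-recombination check
    passed — which requires ``assignment`` and ``reference``).
    ``donor_key`` overrides the donor identity, e.g. to treat whole
    datasets as super-donors.
    """
    if scope not in ("cross_donor", "same_donor"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "same_donor" and (assignment is None or reference is None):
        raise ValueError("same_donor scope requires assignment and reference")
    if donor_key is None:
        donor_key = lambda c: c.donor_id  # noqa: E731

    eligible = [c for c in cells if effective_class(c, class_source) == cell_class]
    groups: Dict[tuple, List[CellRecord]] = {}
    for cell in eligible:
        key = (cell.heavy.v_gene, len(cell.heavy.cdr3_aa))
        groups.setdefault(key, []).append(cell)

    pairs: List[CellPair] = []
    for group in groups.values():
        for a, b in itertools.combinations(group, 2):
            same_donor = donor_key(a) == donor_key(b)
            if scope == "cross_donor":
                if same_donor:
                    continue
            else:
                if not same_donor:
                    continue
                if assignment.of(a.cell_id) == assignment.of(b.cell_id):
                    continue
                if not independent_recombination_check(a, b, reference):
                    continue
            percent, ibin = cdrh3_identity_bin(a.heavy.cdr3_aa, b.heavy.cdr3_aa)
            pairs.append(CellPair(a, b, scope, percent, ibin))
    return pairs


def pair_is_coherent(
    pair: CellPair, merge_paralogs: bool = True, compare: str = "v"
) -> bool:
    """Do the two cells use the same light chain gene name?

    ``compare`` is ``"v"`` (the headline metric) or ``"vj"`` (stricter:
    V and J both match).
    """
    a, b = pair.cell_a.light, pair.cell_b.light
    same_v = normalize_gene_name(a.v_gene, merge_paralogs) == normalize_gene_name(
        b.v_gene, merge_paralogs
    )
    if compare == "v":
        return same_v
    if compare == "vj":
        return same_v and a.j_gene == b.j_gene
    raise ValueError(f"unknown comparison mode {compare!r}")


def light_chain_coherence(
    pairs: Sequence[CellPair], merge_paralogs: bool = True, compare: str = "v"
) -> float:
    """Fraction of pairs with matching light chain genes (NaN if no pairs)."""
    if not pairs:
        return float("nan")
    n = sum(pair_is_coherent(p, merge_paralogs, compare) for p in pairs)
    return n / len(pairs)


@dataclass
class CoherenceCurve:
    """Per-CDRH3-identity-bin pair counts and coherent fractions."""

    label: str
    pair_count: np.ndarray = field(
        default_factory=lambda: np.zeros(len(BINS), dtype=int)
    )
    coherent_count: np.ndarray = field(
        default_factory=lambda: np.zeros(len(BINS), dtype=int)
    )

    @property
    def bins(self) -> Tuple[int, ...]:
        return BINS

    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.pair_count > 0, self.coherent_count / self.pair_count, np.nan
            )

    def standard_error(self) -> np.ndarray:
        """Binomial standard error of the per-bin coherent fraction."""
        f = self.fraction()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(f * (1 - f) / self.pair_count)

    def populated_bins(self) -> List[int]:
        return [b for b, n in zip(BINS, self.pair_count) if n > 0]

    def at_bin(self, identity_bin: int) -> Tuple[int, int]:
        i = BINS.index(identity_bin)
        return int(self.pair_count[i]), int(self.coherent_count[i])


_STRATIFIERS: Dict[str, Callable[[CellPair], object]] = {
    "donor_pair": lambda p: "|".join(p.donor_pair),
    "donor": lambda p: p.cell_a.donor_id,
    "class": lambda p: p.cell_class,
    "dataset_pair": lambda p: "|".join(p.dataset_pair),
}


def coherence_curve(
    pairs: Sequence[CellPair],
    stratify_by: Optional[object] = None,
    merge_paralogs: bool = True,
    compare: str = "v",
) -> Dict[str, CoherenceCurve]:
    """Coherence-by-identity-bin curves, one per stratum.

    ``stratify_by`` is None (single pooled curve), the name of a built-in
    stratifier (``donor_pair``, ``donor``, ``class``, ``dataset_pair``) or a
    callable mapping a pair to a stratum label.
    """
    if stratify_by is None:
        strata = lambda p: "all"  # noqa: E731
    elif callable(stratify_by):
        strata = stratify_by
    else:
        strata = _STRATIFIERS[stratify_by]
    curves: Dict[str, CoherenceCurve] = {}
    index = {b: i for i, b in enumerate(BINS)}
    for pair in pairs:
        label = str(strata(pair))
        curve = curves.setdefault(label, CoherenceCurve(label=label))
        i = index[pair.identity_bin]
        curve.pair_count[i] += 1
        if pair_is_coherent(pair, merge_paralogs, compare):
            curve.coherent_count[i] += 1
    return curves


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def light_gene_match_probability(
    cells: Sequence[CellRecord], merge_paralogs: bool = True, exact: bool = True
) -> float:
    """Probability two distinct cells share a light V gene.

    ``exact=True`` uses the without-replacement form sum c_g(c_g-1)/(n(n-1))
    (the expectation under label permutation); ``exact=False`` returns the
    plug-in sum of squared frequencies.
    """
    genes = [normalize_gene_name(c.light.v_gene, merge_paralogs) for c in cells]
    n = len(genes)
    counts: Dict[str, int] = {}
    for g in genes:
        counts[g] = counts.get(g, 0) + 1
    if exact:
        if n < 2:
            return float("nan")
        return sum(c * (c - 1) for c in counts.values()) / (n * (n - 1))
    return sum((c / n) ** 2 for c in counts.values())


@dataclass
class PermutationNull:
    """Null coherence from permuting light chains with heavy chains fixed."""

    bin_mean: np.ndarray
    bin_sem: np.ndarray
    overall_mean: float
    overall_sem: float
    analytic: float
    n_perm: int
    n_pairs: int


def permute_light_chains(
    cells: Sequence[CellRecord],
    n_perm: int = 1000,
    seed: int = 0,
    one_per_clonotype: bool = True,
    assignment: Optional[ClonotypeAssignment] = None,
    cell_class: str = "memory",
    scope: str = "cross_donor",
    merge_paralogs: bool = True,
    reference: Optional[GermlineReference] = None,
) -> PermutationNull:
    """Permutation null of light chain coherence.

    Light chain annotations are shuffled uniformly among the retained cells
    (one per clonotype when requested, within the chosen class) while heavy
    chains stay fixed; coherence is recomputed per replicate. The analytic
    expectation of the per-replicate mean is the light-gene match
    probability of the retained cells.
    """
    rng = np.random.default_rng(seed)
    retained = [c for c in cells if effective_class(c) == cell_class]
    if one_per_clonotype:
        if assignment is None:
            raise ValueError("one_per_clonotype requires a clonotype assignment")
        retained = one_cell_per_clonotype(retained, assignment, rng=rng)

    pairs = enumerate_pairs(
        retained, scope=scope, cell_class=cell_class,
        assignment=assignment, reference=reference,
    )
    index = {c.cell_id: i for i, c in enumerate(retained)}
    genes = [normalize_gene_name(c.light.v_gene, merge_paralogs) for c in retained]
    codes, _ = _encode(genes)
    idx_a = np.array([index[p.cell_a.cell_id] for p in pairs], dtype=np.intp)
    idx_b = np.array([index[p.cell_b.cell_id] for p in pairs], dtype=np.intp)
    bin_idx = np.array([BINS.index(p.identity_bin) for p in pairs], dtype=np.intp)

    n_cells = len(retained)
    n_bins = len(BINS)
    bin_tot = np.bincount(bin_idx, minlength=n_bins).astype(float)
    per_bin = np.full((n_perm, n_bins), np.nan)
    overall = np.zeros(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(n_cells)
        match = codes[perm[idx_a]] == codes[perm[idx_b]]
        overall[r] = match.mean() if len(match) else np.nan
        hits = np.bincount(bin_idx, weights=match, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_bin[r] = np.where(bin_tot > 0, hits / bin_tot, np.nan)

    analytic = light_gene_match_probability(retained, merge_paralogs, exact=True)
    populated = bin_tot > 0
    bin_mean = np.full(n_bins, np.nan)
    bin_sem = np.full(n_bins, np.nan)
    if len(pairs):
        bin_mean[populated] = np.nanmean(per_bin[:, populated], axis=0)
        bin_sem[populated] = (
            np.nanstd(per_bin[:, populated], axis=0, ddof=1) / np.sqrt(n_perm)
        )
    return PermutationNull(
        bin_mean=bin_mean,
        bin_sem=bin_sem,
        overall_mean=float(np.nanmean(overall)),
        overall_sem=float(np.nanstd(overall, ddof=1) / np.sqrt(n_perm)),
        analytic=analytic,
        n_perm=n_perm,
        n_pairs=len(pairs),
    )


def _encode(labels: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    uniq = sorted(set(labels))
    lut = {u: i for i, u in enumerate(uniq)}
    return np.array([lut[x] for x in labels], dtype=np.intp), uniq


# ---------------------------------------------------------------------------
# slope F test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlopeFTest:
    F: float
    df_num: int
    df_den: int
    p: float


def _curve_points(curve: CoherenceCurve) -> Tuple[np.ndarray, np.ndarray]:
    mask = curve.pair_count > 0
    x = np.array(BINS, dtype=float)[mask]
    y = curve.fraction()[mask]
    return x, y


def compare_curve_slopes(groups: Sequence[Sequence[CoherenceCurve]]) -> SlopeFTest:
    """Extra-sum-of-squares F test of regression slopes between curve groups.

    Both models give every curve its own intercept; the full model fits one
    slope per group, the reduced model one common slope. Each curve must
    contribute at least three populated identity bins.
    """
    xs, ys, curve_ids, group_ids = [], [], [], []
    curve_counter = 0
    for gi, group in enumerate(groups):
        for curve in group:
            x, y = _curve_points(curve)
            if len(x) < 3:
                raise ValueError(
                    f"curve {curve.label!r} has fewer than 3 populated bins"
                )
            xs.append(x)
            ys.append(y)
            curve_ids.append(np.full(len(x), curve_counter))
            group_ids.append(np.full(len(x), gi))
            curve_counter += 1
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    curve_id = np.concatenate(curve_ids).astype(int)
    group_id = np.concatenate(group_ids).astype(int)
    n_curves = curve_counter
    n_groups = len(groups)
    n = len(x)

    intercepts = np.zeros((n, n_curves))
    intercepts[np.arange(n), curve_id] = 1.0

    slope_full = np.zeros((n, n_groups))
    slope_full[np.arange(n), group_id] = x
    design_full = np.hstack([intercepts, slope_full])

    design_red = np.hstack([intercepts, x[:, None]])

    ssr_full = _ssr(design_full, y)
    ssr_red = _ssr(design_red, y)
    df_num = n_groups - 1
    df_den = n - (n_curves + n_groups)
    if df_num <= 0 or df_den <= 0:
        raise ValueError("not enough data for the slope F test")
    num = max(ssr_red - ssr_full, 0.0) / df_num
    den = ssr_full / df_den
    F = num / den if den > 0 else (0.0 if num == 0 else float("inf"))
    p = float(stats.f.sf(F, df_num, df_den))
    return SlopeFTest(F=float(F), df_num=df_num, df_den=df_den, p=p)


def _ssr(design: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def slope_f_test(
    curve_set_a: Sequence[CoherenceCurve], curve_set_b: Sequence[CoherenceCurve]
) -> SlopeFTest:
    """Do two sets of coherence curves share a regression slope?"""
    return compare_curve_slopes([list(curve_set_a), list(curve_set_b)])


# ---------------------------------------------------------------------------
# Vh/Vl contingency Monte Carlo
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    p: float
    n_mc: int
    n_observations: int


def _chi2_stat(vh: np.ndarray, vl: np.ndarray, n_vh: int, n_vl: int) -> float:
    table = np.bincount(vh * n_vl + vl, minlength=n_vh * n_vl).reshape(n_vh, n_vl)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    mask = expected > 0
    return float((((table - expected) ** 2)[mask] / expected[mask]).sum())


def vh_vl_contingency_test(
    vh_labels: Sequence[str],
    vl_labels: Sequence[str],
    n_mc: int = 100000,
    seed: int = 0,
) -> ContingencyResult:
    """Monte-Carlo chi-square test of Vh/Vl independence.

    Each observation is one clonotype's (heavy V, light V) pair; the null
    distribution comes from permuting the light labels, and
    p = (1 + #{null >= observed}) / (n_mc + 1).
    """
    if len(vh_labels) != len(vl_labels):
        raise LengthMismatch("Vh and Vl label lists differ in length")
    rng = np.random.default_rng(seed)
    vh, _ = _encode(list(vh_labels))
    vl, _ = _encode(list(vl_labels))
    n_vh = int(vh.max()) + 1 if len(vh) else 0
    n_vl = int(vl.max()) + 1 if len(vl) else 0
    observed = _chi2_stat(vh, vl, n_vh, n_vl)
    hits = 0
    for _ in range(n_mc):
        null = _chi2_stat(vh, rng.permutation(vl), n_vh, n_vl)
        if null >= observed - 1e-12:
            hits += 1
    return ContingencyResult(
        statistic=observed, p=(1 + hits) / (n_mc + 1), n_mc=n_mc,
        n_observations=len(vh_labels),
    )


def clonotype_vh_vl_labels(
    cells: Sequence[CellRecord],
    assignment: ClonotypeAssignment,
    merge_paralogs: bool = True,
) -> Tuple[List[str], List[str]]:
    """One (Vh, Vl) observation per clonotype (first cell by id)."""
    rep: Dict[str, CellRecord] = {}
    for cell in cells:
        ct = assignment.of(cell.cell_id)
        if ct not in rep or cell.cell_id < rep[ct].cell_id:
            rep[ct] = cell
    vh, vl = [], []
    for ct in sorted(rep):
        cell = rep[ct]
        vh.append(cell.heavy.v_gene)
        vl.append(normalize_gene_name(cell.light.v_gene, merge_paralogs))
    return vh, vl


# ---------------------------------------------------------------------------
# edit-distance coherence
# ---------------------------------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two sequences."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class EditDistanceCoherence:
    fraction: float
    n_pairs: int
    threshold: int


def edit_distance_coherence(
    pairs: Sequence[CellPair],
    threshold: int = 20,
    restrict_to_identical_cdrh3: bool = True,
) -> EditDistanceCoherence:
    """Fraction of pairs with light chain nucleotide edit distance <= threshold.

    With the restriction, only pairs whose CDRH3 amino acid sequences are
    identical are considered — the gene-free version of coherence.
    """
    selected = [
        p
        for p in pairs
        if not restrict_to_identical_cdrh3
        or p.cell_a.heavy.cdr3_aa == p.cell_b.heavy.cdr3_aa
    ]
    if not selected:
        return EditDistanceCoherence(float("nan"), 0, threshold)
    hits = sum(
        edit_distance(p.cell_a.light.seq_nt, p.cell_b.light.seq_nt) <= threshold
        for p in selected
    )
    return EditDistanceCoherence(hits / len(selected), len(selected), threshold)


# ---------------------------------------------------------------------------
# recurrence counting
# ---------------------------------------------------------------------------


@dataclass
class RecurrenceSummary:
    """Cross-donor recurrence counts and junction summaries for one class."""

    cell_class: str
    n_recurrent_cells: int
    n_recurrent_keys: int
    mean_cdrh3_length: float
    mean_insertion_length: Optional[float] = None
    substitution_rate_all: Optional[float] = None
    substitution_rate_no_insertion: Optional[float] = None
    vddj_rate: Optional[float] = None


def count_recurrences(
    cells: Sequence[CellRecord],
    cell_class: str = "naive",
    decompositions: Optional[Mapping[str, object]] = None,
    class_source: str = "computed",
) -> RecurrenceSummary:
    """Cells whose (heavy V gene, CDRH3 aa) key occurs in two or more donors.

    When per-cell junction decompositions are supplied, the summary also
    reports mean inserted-base count, pooled substitution rates (all
    recurrent cells, and those with no insertions), and the VDDJ rate among
    recurrent cells.
    """
    selected = [c for c in cells if effective_class(c, class_source) == cell_class]
    donors_by_key: Dict[tuple, set] = {}
    for cell in selected:
        key = (cell.heavy.v_gene, cell.heavy.cdr3_aa)
        donors_by_key.setdefault(key, set()).add(cell.donor_id)
    recurrent_keys = {k for k, d in donors_by_key.items() if len(d) >= 2}
    recurrent = [
        c for c in selected if (c.heavy.v_gene, c.heavy.cdr3_aa) in recurrent_keys
    ]
    summary = RecurrenceSummary(
        cell_class=cell_class,
        n_recurrent_cells=len(recurrent),
        n_recurrent_keys=len(recurrent_keys),
        mean_cdrh3_length=(
            float(np.mean([len(c.heavy.cdr3_aa) for c in recurrent]))
            if recurrent else float("nan")
        ),
    )
    if decompositions is not None and recurrent:
        decomposed = [
            (c, decompositions[c.cell_id])
            for c in recurrent
            if c.cell_id in decompositions
        ]
        if decomposed:
            ins = [d.inserted_bases for _, d in decomposed]
            summary.mean_insertion_length = float(np.mean(ins))
            subs = sum(d.substitutions for _, d in decomposed)
            aligned = sum(d.aligned_bases for _, d in decomposed)
            summary.substitution_rate_all = subs / aligned if aligned else None
            zero = [d for _, d in decomposed if d.inserted_bases == 0]
            z_subs = sum(d.substitutions for d in zero)
            z_aligned = sum(d.aligned_bases for d in zero)
            summary.substitution_rate_no_insertion = (
                z_subs / z_aligned if z_aligned else None
            )
            summary.vddj_rate = float(
                np.mean([d.topology == "VDDJ" for _, d in decomposed])
            )
    return summary


# ---------------------------------------------------------------------------
# super-donor comparison across datasets
# ---------------------------------------------------------------------------


@dataclass
class SuperDonorCoherence:
    per_pair: Dict[Tuple[str, str], float]
    pooled_bin100: float
    n_pairs_bin100: int


def super_donor_coherence(
    datasets: Mapping[str, Sequence[CellRecord]],
    cell_class: str = "memory",
    merge_paralogs: bool = True,
) -> SuperDonorCoherence:
    """Cross-dataset coherence treating each dataset as a single super-donor.

    This removes any within-dataset contamination channel: pairs are only
    formed between cells of different datasets.
    """
    if len(datasets) < 2:
        raise EmptyPairSet("super-donor comparison needs at least two datasets")
    all_cells: List[CellRecord] = []
    for dataset_id, cells in datasets.items():
        for cell in cells:
            c = cell.copy()
            c.dataset_id = dataset_id
            all_cells.append(c)
    pairs = enumerate_pairs(
        all_cells, scope="cross_donor", cell_class=cell_class,
        donor_key=lambda c: c.dataset_id,
    )
    bin100 = [p for p in pairs if p.identity_bin == 100]
    per_pair: Dict[Tuple[str, str], float] = {}
    for names in itertools.combinations(sorted(datasets), 2):
        subset = [p for p in bin100 if p.dataset_pair == names]
        per_pair[names] = light_chain_coherence(subset, merge_paralogs)
    return SuperDonorCoherence(
        per_pair=per_pair,
        pooled_bin100=light_chain_coherence(bin100, merge_paralogs),
        n_pairs_bin100=len(bin100),
    )
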