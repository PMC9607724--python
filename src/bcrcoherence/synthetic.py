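"""Synthetic paired heavy/light repertoires with ground truth.

The generator emulates the statistical structure the analysis assumes —
categorical V/D/J usage per locus, geometric end-trimming and N-insertion
lengths, a small VDDJ recombination rate, substitution-only somatic
hypermutation outside junctions for memory cells, clonal expansion, and
planted cross-donor public heavy configurations whose light chains are
coherent with a tunable probability — so every pipeline stage can be
tested with no external data. It is not a biologically calibrated
recombination model: junctions are preserved under SHM (so CDR3-keyed
recurrences survive mutation and ground-truth labels stay exact), there is
no selection modeling, and coherence is planted rather than emergent.

Default parameters are the study conditions: four donors, N-insertion
total mean 5 nt, VDDJ rate 0.005, segment overlaps tuned so the mean CDRH3
length is about 18 amino acids, and light V usage proportional to
1/sqrt(rank) over 25 genes (one duplicated-locus paralog pair included),
which puts the background light-gene match probability near 6%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .repio import CellRecord, ChainAnnotation, GermlineGene, GermlineReference

_BASES = np.array(list("ACGT"))


def translate_nt(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


@dataclass
class PublicPlan:
    """Planted cross-donor public heavy configurations.

    ``p_coherent`` is the probability that a public key is *coherent*: all
    of its copies use the key's canonical light V gene (an incoherent key's
    copies draw light genes from the background usage independently).
    Exactly ``round(p_coherent * n_keys)`` keys are made coherent, so the
    planted pair-level coherence is ``p_coherent`` by construction up to
    the background match probability. ``mode="per_copy"`` instead makes
    each individual copy canonical with probability ``p_coherent``.
    """

    n_keys: int = 0
    donors_per_key: int = 4
    copies_per_donor: int = 3
    p_coherent: float = 0.8
    cell_class: str = "memory"
    mode: str = "per_key"


@dataclass
class SimulationConfig:
    """Generator parameters. ``seed`` is mandatory for reproducibility."""

    seed: int
    n_donors: int = 4
    naive_per_donor: int = 2500
    memory_per_donor: int = 2260
    # germline set sizes
    n_v_heavy: int = 20
    n_d_heavy: int = 8
    n_j_heavy: int = 6
    n_v_light: int = 24  # a "D" paralog twin of one gene is added on top
    n_j_light: int = 5
    # segment geometry (nt)
    v_len: int = 300
    d_len: int = 27
    j_len: int = 48
    v_junction_nt: int = 18  # conserved C codon at v_len - v_junction_nt
    j_junction_nt: int = 15  # conserved W codon ends at this offset into J
    # recombination statistics
    trim_mean: float = 2.5  # geometric, per trimmed segment end
    n_insertion_mean: float = 5.0  # total over N regions, heavy chain
    light_n_insertion_mean: float = 2.0
    vddj_rate: float = 0.005
    # somatic hypermutation / clones
    shm_rate: float = 0.01  # per-base substitution rate outside junctions
    memory_clone_mean: float = 1.5  # geometric clone size, memory
    naive_clone_mean: float = 1.0
    public: PublicPlan = field(default_factory=PublicPlan)
    dataset_id: str = "sim"

    def donors(self) -> List[str]:
        return [f"d{i + 1}" for i in range(self.n_donors)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0,1,2,...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0)) - 1)


def _usage_weights(n: int) -> np.ndarray:
    # moderately skewed usage (~1/sqrt(rank)); over 25 light V genes this
    # puts the chance light-gene match probability sum(f^2) near 6%
    w = 1.0 / np.sqrt(np.arange(1, n + 1))
    return w / w.sum()


def simulate_germline_set(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GermlineReference:
    """Random germline V/D/J segments with IMGT-style names.

    Heavy V genes carry a conserved TGT (Cys) codon at the junction
    boundary; J genes a conserved TGG (Trp) codon ending their junction
    overlap. The light V set contains the paralog pair IGKV1-17 /
    IGKV1D-17 with identical sequences.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = GermlineReference()
    cys = config.v_len - config.v_junction_nt
    w_pos = config.j_junction_nt - 3

    def _stop_free(length: int, frames=(0, 1, 2), head: str = "", tail: str = "") -> str:
        # junction-overlap regions are kept free of stop codons in the given
        # reading frames so productive junctions can always be composed
        while True:
            seq = head + _random_seq(rng, length) + tail
            if all("*" not in translate_nt(seq[f:]) for f in frames):
                return seq

    def make_v(name: str) -> GermlineGene:
        seq = _random_seq(rng, cys)
        seq += _stop_free(config.v_junction_nt - 3, frames=(0,), head="TGT")
        locus = name[:3]
        return GermlineGene(name, "01", locus, "V", seq, cys_position=cys)

    def make_j(name: str) -> GermlineGene:
        overlap = _stop_free(w_pos, tail="TGG")
        seq = overlap + _random_seq(rng, config.j_len - len(overlap))
        return GermlineGene(name, "01", name[:3], "J", seq, w_position=w_pos)

    for i in range(config.n_v_heavy):
        ref.add(make_v(f"IGHV{1 + i % 7}-{i + 1}"))
    for i in range(config.n_d_heavy):
        ref.add(
            GermlineGene(
                f"IGHD{1 + i % 6}-{i + 1}", "01", "IGH", "D",
                _stop_free(config.d_len),
            )
        )
    for i in range(config.n_j_heavy):
        ref.add(make_j(f"IGHJ{i + 1}"))
    light_v_names = [f"IGKV1-{i + 1}" for i in range(config.n_v_light)]
    for name in light_v_names:
        ref.add(make_v(name))
    if "IGKV1-17" in light_v_names:
        twin_of = "IGKV1-17"
    else:
        twin_of = light_v_names[-1]
    twin_name = twin_of.replace("IGKV1-", "IGKV1D-")
    twin_seq = ref.get(twin_of).seq
    ref.add(GermlineGene(twin_name, "01", "IGK", "V", twin_seq, cys_position=cys))
    for i in range(config.n_j_light):
        ref.add(make_j(f"IGKJ{i + 1}"))
    return ref


@dataclass
class _Genes:
    """Usage-weighted gene name pools per locus/segment."""

    heavy_v: List[str]
    heavy_d: List[str]
    heavy_j: List[str]
    light_v: List[str]
    light_j: List[str]
    w_heavy_v: np.ndarray
    w_heavy_d: np.ndarray
    w_heavy_j: np.ndarray
    w_light_v: np.ndarray
    w_light_j: np.ndarray

    @classmethod
    def from_reference(cls, ref: GermlineReference) -> "_Genes":
        hv = [g.gene for g in ref.genes_of("V", "IGH")]
        hd = [g.gene for g in ref.genes_of("D", "IGH")]
        hj = [g.gene for g in ref.genes_of("J", "IGH")]
        lv = [g.gene for g in ref.genes_of("V", "IGK")]
        lj = [g.gene for g in ref.genes_of("J", "IGK")]
        return cls(
            hv, hd, hj, lv, lj,
            _usage_weights(len(hv)), _usage_weights(len(hd)),
            _usage_weights(len(hj)), _usage_weights(len(lv)),
            _usage_weights(len(lj)),
        )


@dataclass
class _JunctionDraw:
    junction: str
    n_inserted: int
    d_genes: Tuple[str, ...]
    topology: str


def _draw_junction(
    rng: np.random.Generator,
    ref: GermlineReference,
    v_gene: str,
    j_gene: str,
    d_genes: Tuple[str, ...],
    insertion_mean: float,
    trim_mean: float,
    d_keep_min: int = 8,
    max_tries: int = 2000,
) -> _JunctionDraw:
    """Compose one junction: trimmed V tail + N + trimmed D(s) + N + trimmed J head.

    Trims and N lengths are rejection-sampled until the junction is a codon
    multiple whose translation has no stop codon, which keeps the N-length
    distribution on its configured geometric law.
    """
    v = ref.get(v_gene)
    j = ref.get(j_gene)
    v_part = v.seq[v.cys_position:]
    j_part = j.seq[: j.junction_overlap]
    n_regions = len(d_genes) + 1
    per_region = insertion_mean / n_regions
    # N lengths are drawn once, before any rejection, so their distribution
    # stays on the configured geometric law; trims and base content are
    # redrawn to satisfy the codon-frame and no-stop constraints. Only when
    # trims cannot fix the frame (e.g. trimming disabled) are N lengths
    # redrawn, which conditions their sum on the frame residue — a shift of
    # well under 0.1 nt in the mean.
    n_lens = [_geometric0(rng, per_region) for _ in range(n_regions)]
    for attempt in range(max_tries):
        if attempt and attempt % 30 == 0:
            n_lens = [_geometric0(rng, per_region) for _ in range(n_regions)]
        t_v = min(_geometric0(rng, trim_mean), len(v_part) - 3)
        t_j = min(_geometric0(rng, trim_mean), len(j_part) - 3)
        kept_v = v_part[: len(v_part) - t_v]
        kept_j = j_part[t_j:]

        kept_ds: List[str] = []
        for name in d_genes:
            d_seq = ref.get(name).seq
            budget = len(d_seq) - d_keep_min
            t5 = min(_geometric0(rng, trim_mean), budget)
            t3 = min(_geometric0(rng, trim_mean), budget - t5)
            kept_ds.append(d_seq[t5: len(d_seq) - t3])

        core_len = len(kept_v) + sum(map(len, kept_ds)) + len(kept_j) + sum(n_lens)
        if core_len % 3:
            continue
        for _content in range(20):
            pieces = [kept_v]
            for kd, nl in zip(kept_ds, n_lens[:-1]):
                pieces.append(_random_seq(rng, nl))
                pieces.append(kd)
            pieces.append(_random_seq(rng, n_lens[-1]))
            pieces.append(kept_j)
            junction = "".join(pieces)
            if "*" not in translate_nt(junction):
                return _JunctionDraw(
                    junction=junction,
                    n_inserted=sum(n_lens),
                    d_genes=d_genes,
                    topology="V" + "D" * len(d_genes) + "J",
                )
    raise RuntimeError("could not draw a stop-free junction")


def _make_chain(
    ref: GermlineReference, v_gene: str, j_gene: str, draw: _JunctionDraw, locus: str
) -> ChainAnnotation:
    v = ref.get(v_gene)
    j = ref.get(j_gene)
    seq = v.seq[: v.cys_position] + draw.junction + j.seq[j.junction_overlap:]
    return ChainAnnotation(
        locus=locus,
        v_gene=v_gene,
        d_gene=draw.d_genes[0] if draw.d_genes else None,
        j_gene=j_gene,
        v_allele_call=f"{v_gene}*01",
        junction_nt=draw.junction,
        junction_aa=translate_nt(draw.junction),
        seq_nt=seq,
        junction_start=v.cys_position,
        junction_end=v.cys_position + len(draw.junction),
        productive=True,
    )


def _apply_shm(
    rng: np.random.Generator, cell: CellRecord, rate: float, min_total: int = 1
) -> int:
    """Mutate bases outside both junctions; returns the substitution count."""
    sites: List[Tuple[str, int]] = []
    for chain_name in ("heavy", "light"):
        anno = getattr(cell, chain_name)
        sites.extend((chain_name, i) for i in range(anno.junction_start))
        sites.extend((chain_name, i) for i in range(anno.junction_end, len(anno.seq_nt)))
    n = max(min_total, rng.poisson(rate * len(sites)))
    n = min(n, len(sites))
    chosen = rng.choice(len(sites), size=n, replace=False)
    seqs = {name: list(getattr(cell, name).seq_nt) for name in ("heavy", "light")}
    for idx in chosen:
        chain_name, pos = sites[idx]
        old = seqs[chain_name][pos]
        alternatives = [b for b in "ACGT" if b != old]
        seqs[chain_name][pos] = alternatives[rng.integers(3)]
    for name in ("heavy", "light"):
        getattr(cell, name).seq_nt = "".join(seqs[name])
    return n


@dataclass
class SimulatedRepertoire:
    cells: List[CellRecord]
    truth: pd.DataFrame
    reference: GermlineReference
    config: SimulationConfig


def _truth_row(cell: CellRecord, true_class: str, clone: str, draw: _JunctionDraw,
               shm: int, public_key: str = "", planted_coherent: bool = False) -> dict:
    return {
        "cell_id": cell.cell_id,
        "donor_id": cell.donor_id,
        "true_class": true_class,
        "true_clonotype": clone,
        "heavy_v": cell.heavy.v_gene,
        "heavy_j": cell.heavy.j_gene,
        "d_genes": "+".join(draw.d_genes),
        "topology": draw.topology,
        "n_inserted": draw.n_inserted,
        "light_v": cell.light.v_gene,
        "light_j": cell.light.j_gene,
        "shm_count": shm,
        "public_key": public_key,
        "planted_coherent": planted_coherent,
    }


def simulate_repertoire(config: SimulationConfig) -> SimulatedRepertoire:
    """Full paired repertoire plus ground truth under a single seed."""
    rng = np.random.default_rng(config.seed)
    ref = simulate_germline_set(config, rng)
    genes = _Genes.from_reference(ref)
    cells: List[CellRecord] = []
    truth_rows: List[dict] = []
    counter = 0

    def draw_heavy() -> Tuple[str, str, _JunctionDraw]:
        v = genes.heavy_v[rng.choice(len(genes.heavy_v), p=genes.w_heavy_v)]
        jg = genes.heavy_j[rng.choice(len(genes.heavy_j), p=genes.w_heavy_j)]
        if rng.random() < config.vddj_rate and len(genes.heavy_d) >= 2:
            d_idx = rng.choice(len(genes.heavy_d), size=2, replace=False,
                               p=genes.w_heavy_d)
            ds = tuple(genes.heavy_d[i] for i in d_idx)
        else:
            ds = (genes.heavy_d[rng.choice(len(genes.heavy_d), p=genes.w_heavy_d)],)
        draw = _draw_junction(rng, ref, v, jg, ds, config.n_insertion_mean,
                              config.trim_mean)
        return v, jg, draw

    def draw_light(v_gene: Optional[str] = None) -> Tuple[str, str, _JunctionDraw]:
        if v_gene is None:
            v_gene = genes.light_v[rng.choice(len(genes.light_v), p=genes.w_light_v)]
        jg = genes.light_j[rng.choice(len(genes.light_j), p=genes.w_light_j)]
        draw = _draw_junction(rng, ref, v_gene, jg, (),
                              config.light_n_insertion_mean, config.trim_mean)
        return v_gene, jg, draw

    for donor in config.donors():
        for cls, per_donor, clone_mean in (
            ("naive", config.naive_per_donor, config.naive_clone_mean),
            ("memory", config.memory_per_donor, config.memory_clone_mean),
        ):
            made = 0
            clone_idx = 0
            while made < per_donor:
                clone_idx += 1
                clone_id = f"{donor}.{cls}.{clone_idx}"
                hv, hj, hdraw = draw_heavy()
                lv, lj, ldraw = draw_light()
                size = 1 + _geometric0(rng, clone_mean - 1.0)
                size = min(size, per_donor - made)
                for _ in range(size):
                    counter += 1
                    cell = CellRecord(
                        cell_id=f"{donor}_c{counter:07d}",
                        donor_id=donor,
                        dataset_id=config.dataset_id,
                        sort_label="naive" if cls == "naive" else "switched_memory",
                        heavy=_make_chain(ref, hv, hj, hdraw, "IGH"),
                        light=_make_chain(ref, lv, lj, ldraw, "IGK"),
                    )
                    shm = 0
                    if cls == "memory":
                        shm = _apply_shm(rng, cell, config.shm_rate)
                    cells.append(cell)
                    truth_rows.append(_truth_row(cell, cls, clone_id, hdraw, shm))
                    made += 1

    if config.public.n_keys > 0:
        planted, planted_truth = plant_public_recurrences(
            config, ref, genes, rng, start_counter=counter
        )
        cells.extend(planted)
        truth_rows.extend(planted_truth)

    truth = pd.DataFrame(truth_rows)
    return SimulatedRepertoire(cells=cells, truth=truth, reference=ref, config=config)


def plant_public_recurrences(
    config: SimulationConfig,
    ref: GermlineReference,
    genes: Optional[_Genes] = None,
    rng: Optional[np.random.Generator] = None,
    start_counter: int = 0,
) -> Tuple[List[CellRecord], List[dict]]:
    """Create the planted public cells described by ``config.public``.

    Each key is one heavy configuration (V gene + junction, hence CDRH3)
    copied into ``donors_per_key`` donors, ``copies_per_donor`` cells each.
    Coherent keys give every copy the key's canonical light V gene;
    incoherent keys draw each copy's light V from the background usage.
    """
    plan = config.public
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if genes is None:
        genes = _Genes.from_reference(ref)
    donors = config.donors()
    n_coherent = int(round(plan.p_coherent * plan.n_keys))
    coherent_flags = np.zeros(plan.n_keys, dtype=bool)
    coherent_flags[rng.permutation(plan.n_keys)[:n_coherent]] = True

    cells: List[CellRecord] = []
    rows: List[dict] = []
    counter = start_counter
    for k in range(plan.n_keys):
        hv = genes.heavy_v[rng.choice(len(genes.heavy_v), p=genes.w_heavy_v)]
        hj = genes.heavy_j[rng.choice(len(genes.heavy_j), p=genes.w_heavy_j)]
        ds = (genes.heavy_d[rng.choice(len(genes.heavy_d), p=genes.w_heavy_d)],)
        hdraw = _draw_junction(rng, ref, hv, hj, ds, config.n_insertion_mean,
                               config.trim_mean)
        canonical_light = genes.light_v[
            rng.choice(len(genes.light_v), p=genes.w_light_v)
        ]
        key_label = f"pub{k + 1:04d}"
        if plan.donors_per_key >= len(donors):
            key_donors = list(donors)
        else:
            key_donors = [donors[i] for i in rng.choice(
                len(donors), size=plan.donors_per_key, replace=False)]
        for donor in key_donors:
            for _ in range(plan.copies_per_donor):
                counter += 1
                if plan.mode == "per_copy":
                    use_canonical = rng.random() < plan.p_coherent
                else:
                    use_canonical = bool(coherent_flags[k])
                lv = canonical_light if use_canonical else None
                lv, lj, ldraw = draw_light_for(genes, rng, ref, config, lv)
                cell = CellRecord(
                    cell_id=f"{donor}_c{counter:07d}",
                    donor_id=donor,
                    dataset_id=config.dataset_id,
                    sort_label=("naive" if plan.cell_class == "naive"
                                else "switched_memory"),
                    heavy=_make_chain(ref, hv, hj, hdraw, "IGH"),
                    light=_make_chain(ref, lv, lj, ldraw, "IGK"),
                )
                shm = 0
                if plan.cell_class == "memory":
                    shm = _apply_shm(rng, cell, config.shm_rate)
                cells.append(cell)
                rows.append(
                    _truth_row(cell, plan.cell_class, f"{donor}.{key_label}.{counter}",
                               hdraw, shm, public_key=key_label,
                               planted_coherent=bool(use_canonical))
                )
    return cells, rows


def draw_light_for(
    genes: _Genes,
    rng: np.random.Generator,
    ref: GermlineReference,
    config: SimulationConfig,
    v_gene: Optional[str],
) -> Tuple[str, str, _JunctionDraw]:
    if v_gene is None:
        v_gene = genes.light_v[rng.choice(len(genes.light_v), p=genes.w_light_v)]
    jg = genes.light_j[rng.choice(len(genes.light_j), p=genes.w_light_j)]
    draw = _draw_junction(rng, ref, v_gene, jg, (), config.light_n_insertion_mean,
                          config.trim_mean)
    return v_gene, jg, draw


# ---------------------------------------------------------------------------
# AIRR emission & allele-inference fixtures
# ---------------------------------------------------------------------------

_AIRR_COLUMNS = [
    "cell_id", "donor_id", "dataset_id", "sort_label", "locus", "v_call",
    "d_call", "j_call", "junction", "junction_aa", "sequence",
    "junction_start", "junction_end", "productive", "c_call",
]


def emit_airr(cells: Sequence[CellRecord], path) -> None:
    """Write cells as an AIRR Rearrangement TSV (two rows per cell).

    The file round-trips through ``repio.read_airr_rearrangements`` +
    ``repio.assemble_cells``.
    """
    rows = []
    for cell in cells:
        for anno in (cell.heavy, cell.light):
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "donor_id": cell.donor_id,
                    "dataset_id": cell.dataset_id,
                    "sort_label": cell.sort_label,
                    "locus": anno.locus,
                    "v_call": anno.v_allele_call or anno.v_gene,
                    "d_call": anno.d_gene or "",
                    "j_call": anno.j_gene,
                    "junction": anno.junction_nt,
                    "junction_aa": anno.junction_aa,
                    "sequence": anno.seq_nt,
                    "junction_start": anno.junction_start,
                    "junction_end": anno.junction_end,
                    "productive": "T" if anno.productive else "F",
                    "c_call": anno.isotype or "",
                }
            )
    pd.DataFrame(rows, columns=_AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def make_pileup_cells(
    reference: GermlineReference,
    v_gene: str,
    donor_id: str,
    n_cells: int,
    n_carriers: int,
    variant_positions: Sequence[int],
    variant_bases: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> List[CellRecord]:
    """Fixture cells for allele-inference tests: a planted germline variant.

    The first ``n_carriers`` cells carry the variant footprint on the heavy
    V gene; every cell occupies its own non-redundancy stratum (distinct
    light junction lengths / partner genes), so none is collapsed by the
    pileup selection heuristic.
    """
    rng = np.random.default_rng(seed)
    v = reference.get(v_gene)
    light_vs = [g.gene for g in reference.genes_of("V", "IGK")]
    light_js = [g.gene for g in reference.genes_of("J", "IGK")]
    if variant_bases is None:
        variant_bases = [
            "ACGT"[("ACGT".index(v.seq[p]) + 1) % 4] for p in variant_positions
        ]
    heavy_js = [g.gene for g in reference.genes_of("J", "IGH")]
    cells = []
    for i in range(n_cells):
        hj = heavy_js[i % len(heavy_js)]
        hdraw = _draw_junction(rng, reference, v_gene, hj, (), 2.0, 0.0)
        lv = light_vs[0]
        lj = light_js[0]
        # distinct CDRL3 length per cell guarantees one stratum per cell
        lref_v, lref_j = reference.get(lv), reference.get(lj)
        pad = _random_seq(rng, 3 * i)
        l_junction = (lref_v.seq[lref_v.cys_position:] + pad
                      + lref_j.seq[: lref_j.junction_overlap])
        ldraw = _JunctionDraw(l_junction, 3 * i, (), "VJ")
        heavy = _make_chain(reference, v_gene, hj, hdraw, "IGH")
        light = _make_chain(reference, lv, lj, ldraw, "IGK")
        if i < n_carriers:
            seq = list(heavy.seq_nt)
            for pos, base in zip(variant_positions, variant_bases):
                seq[pos] = base
            heavy.seq_nt = "".join(seq)
        cells.append(
            CellRecord(
                cell_id=f"{donor_id}_fx{i:04d}",
                donor_id=donor_id,
                dataset_id="fixture",
                heavy=heavy,
                light=light,
            )
        )
    return cells
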