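"""V(D)(D)J junction decomposition."""

import numpy as np
import pytest

from bcrcoherence.coherence import enumerate_pairs
from bcrcoherence.junctions import (
    candidate_references,
    coherence_by_insertion,
    decompose_cells,
    decompose_junction,
    insertion_profile,
)
from bcrcoherence.synthetic import (
    PublicPlan,
    SimulationConfig,
    simulate_germline_set,
    simulate_repertoire,
)
from tests.conftest import make_cell


@pytest.fixture(scope="module")
def junction_reference():
    config = SimulationConfig(seed=23, n_v_heavy=8, n_d_heavy=5, n_j_heavy=4,
                              n_v_light=4, n_j_light=2)
    return simulate_germline_set(config, np.random.default_rng(23))


def _parts(ref, v="IGHV1-1", d="IGHD1-1", j="IGHJ1"):
    vg, jg = ref.get(v), ref.get(j)
    return (vg.seq[vg.cys_position:], ref.get(d).seq, jg.seq[: jg.junction_overlap])


def _fresh_bases(rng, n, forbid_left="", forbid_right=""):
    """Random run whose first/last bases differ from the flanking ref bases."""
    out = [rng.choice(list("ACGT")) for _ in range(n)]
    if n and forbid_left:
        out[0] = next(b for b in "ACGT" if b != forbid_left)
    if n and forbid_right:
        out[-1] = next(b for b in "ACGT" if b != forbid_right)
    return "".join(out)


class TestCandidates:
    @pytest.mark.parametrize("n_d,expected", [(0, 1), (1, 2), (2, 5)])
    def test_candidate_counts(self, junction_reference, n_d, expected):
        d_names = [g.gene for g in junction_reference.genes_of("D", "IGH")][:n_d]
        cands = candidate_references("IGHV1-1", "IGHJ1", d_names, junction_reference)
        assert len(cands) == expected
        topologies = sorted({c.topology for c in cands})
        if n_d == 2:
            assert topologies == ["VDDJ", "VDJ", "VJ"]


class TestDecompose:
    def test_identity_case_vdj(self, junction_reference):
        v_part, d_seq, j_part = _parts(junction_reference)
        result = decompose_junction(
            v_part + d_seq + j_part, "IGHV1-1", "IGHJ1", junction_reference
        )
        assert result.topology == "VDJ"
        assert result.d_genes == ("IGHD1-1",)
        assert (result.inserted_bases, result.deleted_bases,
                result.substitutions) == (0, 0, 0)
        assert result.aligned_bases == len(v_part) + len(d_seq) + len(j_part)

    def test_identity_case_vj(self, junction_reference):
        v_part, _, j_part = _parts(junction_reference)
        result = decompose_junction(
            v_part + j_part, "IGHV1-1", "IGHJ1", junction_reference
        )
        assert result.topology == "VJ"
        assert (result.inserted_bases, result.substitutions) == (0, 0)

    def test_identity_case_random_references(self):
        # fresh random reference sets; exact concatenations decompose cleanly
        config = SimulationConfig(seed=31, n_v_heavy=5, n_d_heavy=4, n_j_heavy=3,
                                  n_v_light=4, n_j_light=2)
        ref = simulate_germline_set(config, np.random.default_rng(31))
        checked = 0
        for v in [g.gene for g in ref.genes_of("V", "IGH")]:
            for d in [g.gene for g in ref.genes_of("D", "IGH")]:
                for j in [g.gene for g in ref.genes_of("J", "IGH")]:
                    vp, ds, jp = _parts(ref, v, d, j)
                    r = decompose_junction(vp + ds + jp, v, j, ref)
                    assert (r.inserted_bases, r.deleted_bases,
                            r.substitutions) == (0, 0, 0)
                    checked += 1
        assert checked == 60

    @pytest.mark.parametrize("k", [0, 1, 3, 5, 8, 12])
    def test_planted_insertions_reported_exactly(self, junction_reference, k):
        rng = np.random.default_rng(100 + k)
        v_part, d_seq, j_part = _parts(junction_reference)
        ins = _fresh_bases(rng, k, v_part[-1], d_seq[0])
        result = decompose_junction(
            v_part + ins + d_seq + j_part, "IGHV1-1", "IGHJ1", junction_reference
        )
        assert result.inserted_bases == k
        assert result.substitutions == 0

    def test_adding_k_bases_increases_insertions_by_k(self, junction_reference):
        rng = np.random.default_rng(7)
        v_part, d_seq, j_part = _parts(junction_reference)
        base = decompose_junction(
            v_part + d_seq + j_part, "IGHV1-1", "IGHJ1", junction_reference
        )
        for k in (2, 4, 6):
            ins = _fresh_bases(rng, k, d_seq[-1], j_part[0])
            grown = decompose_junction(
                v_part + d_seq + ins + j_part, "IGHV1-1", "IGHJ1",
                junction_reference,
            )
            assert grown.inserted_bases == base.inserted_bases + k

    def test_planted_substitutions_and_rate(self, junction_reference):
        # interior substitutions are reported as substitutions, never indels
        v_part, d_seq, j_part = _parts(junction_reference)
        d_mut = list(d_seq)
        for pos in (5, 9, 13):
            d_mut[pos] = next(b for b in "ACGT" if b != d_seq[pos])
        junction = v_part + "".join(d_mut) + j_part
        result = decompose_junction(junction, "IGHV1-1", "IGHJ1", junction_reference)
        assert result.substitutions == 3
        assert result.inserted_bases == 0
        assert result.aligned_bases == len(junction)
        assert result.substitution_rate == pytest.approx(3 / len(junction))

    def test_eight_insertions_seven_substitutions_rate_7_of_46(self):
        # 46 aligned reference bases (15 V + 19 D + 12 J), 8 inserted in two
        # runs, 7 interior substitutions -> rate 7/46
        config = SimulationConfig(seed=41, n_v_heavy=3, n_d_heavy=3, n_j_heavy=2,
                                  n_v_light=3, n_j_light=2,
                                  v_junction_nt=15, d_len=19, j_junction_nt=12)
        ref = simulate_germline_set(config, np.random.default_rng(41))
        rng = np.random.default_rng(42)
        v_part, d_seq, j_part = _parts(ref)
        assert len(v_part) + len(d_seq) + len(j_part) == 46

        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = next(b for b in "ACGT" if b != seq[p])
            return "".join(out)

        v_mut = mutate(v_part, (5, 9))
        d_mut = mutate(d_seq, (5, 9, 13))
        j_mut = mutate(j_part, (4, 7))
        ins1 = _fresh_bases(rng, 5, v_mut[-1], d_mut[0])
        ins2 = _fresh_bases(rng, 3, d_mut[-1], j_mut[0])
        junction = v_mut + ins1 + d_mut + ins2 + j_mut
        result = decompose_junction(junction, "IGHV1-1", "IGHJ1", ref)
        assert result.topology == "VDJ"
        assert result.inserted_bases == 8
        assert result.substitutions == 7
        assert result.aligned_bases == 46
        assert result.substitution_rate == pytest.approx(7 / 46)

    def test_planted_vddj_recovered_in_order(self, junction_reference):
        rng = np.random.default_rng(9)
        v_part, d1, j_part = _parts(junction_reference)
        d2 = junction_reference.get("IGHD2-2").seq
        ins1 = _fresh_bases(rng, 2, v_part[-1], d1[0])
        ins2 = _fresh_bases(rng, 2, d1[-1], d2[0])
        ins3 = _fresh_bases(rng, 2, d2[-1], j_part[0])
        junction = v_part + ins1 + d1 + ins2 + d2 + ins3 + j_part
        result = decompose_junction(junction, "IGHV1-1", "IGHJ1", junction_reference)
        assert result.topology == "VDDJ"
        assert result.d_genes == ("IGHD1-1", "IGHD2-2")
        assert result.inserted_bases == 6

    def test_topology_recovery_rate_on_simulations(self):
        config = SimulationConfig(seed=53, n_donors=1, naive_per_donor=200,
                                  memory_per_donor=0, vddj_rate=0.05,
                                  public=PublicPlan(n_keys=0))
        sim = simulate_repertoire(config)
        truth = sim.truth.set_index("cell_id")
        decomps = decompose_cells(sim.cells, sim.reference)
        agree = np.mean(
            [decomps[c.cell_id].topology == truth.loc[c.cell_id, "topology"]
             for c in sim.cells]
        )
        assert agree >= 0.95


class TestInsertionRecovery:
    def test_trim_free_simulation_recovers_counts_exactly(self):
        # without end-trimming the decomposition is unambiguous: planted
        # insertion counts are recovered per cell
        config = SimulationConfig(seed=61, n_donors=1, naive_per_donor=400,
                                  memory_per_donor=0, trim_mean=0.0,
                                  public=PublicPlan(n_keys=0))
        sim = simulate_repertoire(config)
        truth = sim.truth.set_index("cell_id")["n_inserted"]
        decomps = decompose_cells(sim.cells, sim.reference)
        est = np.array([decomps[c.cell_id].inserted_bases for c in sim.cells])
        true = truth[[c.cell_id for c in sim.cells]].to_numpy()
        assert (est == true).mean() >= 0.98
        assert abs(est.mean() - true.mean()) <= 0.15

    def test_default_simulation_bias_is_bounded_undercount(self):
        # with trimming, chance matches at segment boundaries absorb about
        # one inserted base per joint; the decomposed mean undershoots the
        # generated mean by a bounded, documented amount and never overshoots
        config = SimulationConfig(seed=67, n_donors=1, naive_per_donor=300,
                                  memory_per_donor=0,
                                  public=PublicPlan(n_keys=0))
        sim = simulate_repertoire(config)
        truth = sim.truth.set_index("cell_id")["n_inserted"]
        decomps = decompose_cells(sim.cells, sim.reference)
        est = np.array([decomps[c.cell_id].inserted_bases for c in sim.cells])
        true = truth[[c.cell_id for c in sim.cells]].to_numpy()
        assert (est <= true + 2).all()  # never systematic overshoot
        bias = true.mean() - est.mean()
        assert 0.0 <= bias <= 3.0


def test_insertion_profile_point_mass_and_strata(junction_reference):
    v_part, d_seq, j_part = _parts(junction_reference)
    cells = []
    for i in range(4):
        c = make_cell(f"c{i}", donor="d1",
                      cell_class="memory" if i % 2 else "naive")
        c.heavy.v_gene, c.heavy.j_gene = "IGHV1-1", "IGHJ1"
        c.heavy.junction_nt = v_part + d_seq + j_part
        cells.append(c)
    decomps = decompose_cells(cells, junction_reference)
    profile = insertion_profile(cells, decomps)
    assert set(profile) == {"naive", "memory"}
    for series in profile.values():
        assert series.index.tolist() == [0]
        assert series.iloc[0] == 1.0


def test_coherence_by_insertion_hand_count(junction_reference):
    v_part, d_seq, j_part = _parts(junction_reference)
    junction = v_part + d_seq + j_part
    cells = []
    lights = ["IGKV1-1", "IGKV1-1", "IGKV1-1", "IGKV1-2"]
    for i, lv in enumerate(lights):
        c = make_cell(f"c{i}", donor=f"d{i + 1}", light_v=lv, cell_class="memory")
        c.heavy.v_gene, c.heavy.j_gene = "IGHV1-1", "IGHJ1"
        c.heavy.junction_nt = junction
        cells.append(c)
    pairs = enumerate_pairs(cells, "cross_donor", "memory")
    decomps = decompose_cells(cells, junction_reference)
    table = coherence_by_insertion(pairs, decomps, identity_levels=(100,))
    row = table[(table["inserted_bases"] == 0) & (table["min_identity"] == 100)]
    assert row["pair_count"].iloc[0] == 6
    # 3 coherent pairs among the IGKV1-1 trio out of 6 total
    assert row["coherence"].iloc[0] == pytest.approx(0.5)
    over8 = table[table["inserted_bases"] == ">=8"]
    assert (over8["pair_count"] == 0).all()
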