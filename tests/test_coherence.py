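"""Pair enumeration, coherence curves, and the statistical null models."""

import itertools

import numpy as np
import pytest

from bcrcoherence import errors
from bcrcoherence.classify import compute_clonotypes
from bcrcoherence.coherence import (
    BINS,
    CoherenceCurve,
    cdrh3_identity_bin,
    clonotype_vh_vl_labels,
    coherence_curve,
    compare_curve_slopes,
    count_recurrences,
    edit_distance,
    edit_distance_coherence,
    enumerate_pairs,
    light_chain_coherence,
    light_gene_match_probability,
    permute_light_chains,
    slope_f_test,
    super_donor_coherence,
    vh_vl_contingency_test,
)
from tests.conftest import make_cell


class TestIdentityBin:
    @pytest.mark.parametrize(
        "a,b,percent,bin_",
        [
            ("CARDYW", "CARDYW", 100.0, 100),
            ("CARDYWXYZ", "CARDYWXYA", 100 * 8 / 9, 80),
            ("CW", "CA", 50.0, 50),
        ],
    )
    def test_examples(self, a, b, percent, bin_):
        p, b_ = cdrh3_identity_bin(a, b)
        assert p == pytest.approx(percent)
        assert b_ == bin_

    def test_length_mismatch_rejected(self):
        with pytest.raises(errors.LengthMismatch):
            cdrh3_identity_bin("CARDYWXYZ", "CARDYWXYZAB")

    def test_bin_is_floor_to_ten(self):
        # 9 of 11 = 81.8 -> bin 80; 10 of 11 = 90.9 -> bin 90
        a = "CAAAAAAAAAW"
        b9 = "CAAAAAAAATF"
        b10 = "CAAAAAAAAAF"
        assert cdrh3_identity_bin(a, b9)[1] == 80
        assert cdrh3_identity_bin(a, b10)[1] == 90


class TestEnumeratePairs:
    def test_cross_donor_pair_conditions(self):
        a = make_cell("a", donor="d1", light_v="IGKV1-5")
        b = make_cell("b", donor="d2", light_v="IGKV1-5")
        pairs = enumerate_pairs([a, b], "cross_donor", "memory")
        assert len(pairs) == 1
        assert pairs[0].identity_bin == 100

    def test_same_donor_scope_excludes_cross_donor_cells(self, tiny_reference):
        a = make_cell("a", donor="d1")
        b = make_cell("b", donor="d2")
        assignment = compute_clonotypes([a, b])
        pairs = enumerate_pairs(
            [a, b], "same_donor", "memory",
            assignment=assignment, reference=tiny_reference,
        )
        assert pairs == []

    def test_mixed_class_pairs_excluded(self):
        a = make_cell("a", donor="d1", cell_class="naive")
        b = make_cell("b", donor="d2", cell_class="memory")
        assert enumerate_pairs([a, b], "cross_donor", "memory") == []
        assert enumerate_pairs([a, b], "cross_donor", "naive") == []

    def test_different_heavy_v_or_length_excluded(self):
        a = make_cell("a", donor="d1", heavy_v="IGHV1-1")
        b = make_cell("b", donor="d2", heavy_v="IGHV1-2")
        c = make_cell("c", donor="d2", cdrh3_aa="CARDYYW")
        assert enumerate_pairs([a, b, c], "cross_donor", "memory") == []


class TestCoherence:
    def test_simple_fraction(self):
        cells = [
            make_cell(f"a{i}", donor="d1", light_v="IGKV1-5") for i in range(2)
        ] + [
            make_cell("b0", donor="d2", light_v="IGKV1-5"),
            make_cell("b1", donor="d2", light_v="IGKV1-9"),
        ]
        pairs = enumerate_pairs(cells, "cross_donor", "memory")
        assert len(pairs) == 4
        assert light_chain_coherence(pairs) == pytest.approx(0.5)

    def test_paralog_merging_direction(self):
        a = make_cell("a", donor="d1", light_v="IGKV1-17")
        b = make_cell("b", donor="d2", light_v="IGKV1D-17")
        (pair,) = enumerate_pairs([a, b], "cross_donor", "memory")
        assert light_chain_coherence([pair], merge_paralogs=True) == 1.0
        assert light_chain_coherence([pair], merge_paralogs=False) == 0.0

    def test_merging_never_decreases_coherence(self, small_sim):
        cells = [c.copy() for c in small_sim.cells]
        truth = small_sim.truth.set_index("cell_id")["true_class"]
        for c in cells:
            c.cell_class = truth[c.cell_id]
        pairs = enumerate_pairs(cells, "cross_donor", "memory")
        merged = light_chain_coherence(pairs, merge_paralogs=True)
        unmerged = light_chain_coherence(pairs, merge_paralogs=False)
        assert merged >= unmerged

    def test_empty_pair_set_is_nan(self):
        assert np.isnan(light_chain_coherence([]))

    def test_invariant_under_cell_reordering(self, small_sim):
        cells = [c.copy() for c in small_sim.cells[:500]]
        truth = small_sim.truth.set_index("cell_id")["true_class"]
        for c in cells:
            c.cell_class = truth[c.cell_id]
        forward = light_chain_coherence(enumerate_pairs(cells, "cross_donor", "memory"))
        backward = light_chain_coherence(
            enumerate_pairs(list(reversed(cells)), "cross_donor", "memory")
        )
        assert forward == backward


class TestCurves:
    def test_four_donors_yield_six_donor_pair_curves(self, small_sim):
        cells = [c.copy() for c in small_sim.cells]
        truth = small_sim.truth.set_index("cell_id")["true_class"]
        for c in cells:
            c.cell_class = truth[c.cell_id]
        pairs = enumerate_pairs(cells, "cross_donor", "memory")
        curves = coherence_curve(pairs, stratify_by="donor_pair")
        assert len(curves) == 6

    def test_curve_equals_brute_force_recount(self, small_sim):
        cells = [c.copy() for c in small_sim.cells[:600]]
        truth = small_sim.truth.set_index("cell_id")["true_class"]
        for c in cells:
            c.cell_class = truth[c.cell_id]
        pairs = enumerate_pairs(cells, "cross_donor", "memory")
        curve = coherence_curve(pairs)["all"]
        # independent recount: brute force over all cell pairs
        from bcrcoherence.alleles import normalize_gene_name

        expected_n = {b: 0 for b in BINS}
        expected_c = {b: 0 for b in BINS}
        memory = [c for c in cells if c.cell_class == "memory"]
        for a, b in itertools.combinations(memory, 2):
            if a.donor_id == b.donor_id:
                continue
            if a.heavy.v_gene != b.heavy.v_gene:
                continue
            if len(a.heavy.cdr3_aa) != len(b.heavy.cdr3_aa):
                continue
            matches = sum(x == y for x, y in zip(a.heavy.cdr3_aa, b.heavy.cdr3_aa))
            pct = 100 * matches / len(a.heavy.cdr3_aa)
            bin_ = min(int(pct // 10) * 10, 100)
            expected_n[bin_] += 1
            expected_c[bin_] += normalize_gene_name(
                a.light.v_gene, True
            ) == normalize_gene_name(b.light.v_gene, True)
        assert curve.pair_count.tolist() == [expected_n[b] for b in BINS]
        assert curve.coherent_count.tolist() == [expected_c[b] for b in BINS]

    def test_single_bin_population(self):
        a = make_cell("a", donor="d1")
        b = make_cell("b", donor="d2")
        curve = coherence_curve(enumerate_pairs([a, b], "cross_donor", "memory"))["all"]
        assert curve.pair_count[BINS.index(100)] == 1
        assert curve.pair_count.sum() == 1


class TestPermutationNull:
    def test_null_mean_matches_analytic_match_probability(self, small_sim):
        cells = [c.copy() for c in small_sim.cells]
        truth = small_sim.truth.set_index("cell_id")["true_class"]
        for c in cells:
            c.cell_class = truth[c.cell_id]
        assignment = compute_clonotypes(cells)
        null = permute_light_chains(
            cells, n_perm=300, seed=9, assignment=assignment
        )
        assert null.n_pairs > 100
        assert abs(null.overall_mean - null.analytic) <= 3 * null.overall_sem

    def test_seeded_reproducibility(self, small_sim):
        cells = [c.copy() for c in small_sim.cells[:400]]
        for c in cells:
            c.cell_class = "memory"
        assignment = compute_clonotypes(cells)
        a = permute_light_chains(cells, n_perm=50, seed=3, assignment=assignment)
        b = permute_light_chains(cells, n_perm=50, seed=3, assignment=assignment)
        assert a.overall_mean == b.overall_mean
        assert np.array_equal(a.bin_mean, b.bin_mean, equal_nan=True)

    def test_single_light_gene_gives_unit_coherence(self):
        cells = [
            make_cell(f"c{i}", donor=f"d{1 + i % 2}", light_v="IGKV1-5")
            for i in range(8)
        ]
        assignment = compute_clonotypes(cells)
        null = permute_light_chains(
            cells, n_perm=20, seed=0, assignment=assignment,
            one_per_clonotype=False,
        )
        assert null.overall_mean == 1.0
        assert null.analytic == 1.0


class TestSlopeFTest:
    @staticmethod
    def _curve(label, fractions, n=100):
        curve = CoherenceCurve(label=label)
        for b, f in fractions.items():
            i = BINS.index(b)
            curve.pair_count[i] = n
            curve.coherent_count[i] = int(round(f * n))
        return curve

    def test_duplicated_set_gives_f_near_zero(self):
        curves = [
            self._curve("x", {0: 0.1, 50: 0.4, 100: 0.9}),
            self._curve("y", {0: 0.2, 50: 0.4, 100: 0.6}),
        ]
        result = slope_f_test(curves, curves)
        assert result.F == pytest.approx(0.0, abs=1e-9)
        assert result.p == pytest.approx(1.0)

    def test_hand_computed_toy_fixture(self):
        # group A: slope 0.004 over bins 0/50/100; group B: slope 0.008
        a = self._curve("a", {0: 0.10, 50: 0.30, 100: 0.50})
        b = self._curve("b", {0: 0.10, 50: 0.50, 100: 0.90})
        result = slope_f_test([a], [b])
        # closed form: with one curve per group and exact linear points the
        # full model fits perfectly (SSR_full = 0 -> F = inf) so perturb one
        assert result.F > 1e6  # exact lines: reduced model cannot match

        b2 = self._curve("b2", {0: 0.10, 50: 0.52, 100: 0.90})
        result2 = slope_f_test([a], [b2])
        # hand computation: per-curve intercept+slope leaves SSR_full equal
        # to the b2 residual (OLS on 3 points); reduced shares one slope
        x = np.array([0.0, 50.0, 100.0])
        yb = np.array([0.10, 0.52, 0.90])
        slope_b = np.polyfit(x, yb, 1)[0]
        ssr_full = float(np.sum((yb - np.poly1d(np.polyfit(x, yb, 1))(x)) ** 2))
        ya = np.array([0.10, 0.30, 0.50])
        pooled = np.concatenate([ya, yb])
        # reduced model: common slope, separate intercepts
        slope_common = (
            np.sum((x - 50) * (ya - ya.mean())) + np.sum((x - 50) * (yb - yb.mean()))
        ) / (2 * np.sum((x - 50) ** 2))
        ssr_red = float(
            np.sum((ya - ya.mean() - slope_common * (x - 50)) ** 2)
            + np.sum((yb - yb.mean() - slope_common * (x - 50)) ** 2)
        )
        expected_f = (ssr_red - ssr_full) / 1 / (ssr_full / (6 - 4))
        assert result2.F == pytest.approx(expected_f, rel=1e-6)
        assert result2.df_num == 1
        assert result2.df_den == 2

    def test_null_calibration(self):
        # homogeneous process: per-curve binomial noise around one line
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            sets = []
            for _group in range(2):
                curves = []
                for c in range(3):
                    curve = CoherenceCurve(label=f"c{c}")
                    for i, b in enumerate(BINS):
                        n = 200
                        p = 0.1 + 0.007 * b
                        curve.pair_count[i] = n
                        curve.coherent_count[i] = rng.binomial(n, p)
                    curves.append(curve)
                sets.append(curves)
            if compare_curve_slopes(sets).p < 0.05:
                rejections += 1
        # ~5% expected; allow generous Monte Carlo slack
        assert rejections / n_rep < 0.12

    def test_requires_three_populated_bins(self):
        thin = self._curve("thin", {0: 0.1, 100: 0.9})
        with pytest.raises(ValueError):
            slope_f_test([thin], [thin])


class TestContingency:
    def test_perfectly_associated_table_minimal_p(self):
        vh = ["A"] * 20 + ["B"] * 20
        vl = ["x"] * 20 + ["y"] * 20
        result = vh_vl_contingency_test(vh, vl, n_mc=999, seed=0)
        assert result.p == pytest.approx(1 / 1000)

    def test_independent_table_usually_nonsignificant(self):
        rng = np.random.default_rng(12)
        nonsig = 0
        for rep in range(40):
            vh = rng.choice(list("ABCD"), size=200)
            vl = rng.choice(list("wxyz"), size=200)
            res = vh_vl_contingency_test(list(vh), list(vl), n_mc=199, seed=rep)
            nonsig += res.p > 0.05
        assert nonsig >= 0.9 * 40 - 3  # >=90% within Monte Carlo slack

    def test_default_replicates(self):
        import inspect

        sig = inspect.signature(vh_vl_contingency_test)
        assert sig.parameters["n_mc"].default == 100000

    def test_clonotype_labels_one_per_clonotype(self, small_sim):
        cells = [c.copy() for c in small_sim.cells[:200]]
        for c in cells:
            c.cell_class = "memory"
        assignment = compute_clonotypes(cells)
        vh, vl = clonotype_vh_vl_labels(cells, assignment)
        assert len(vh) == assignment.n_clonotypes


class TestEditDistance:
    def test_identical_sequences_distance_zero(self):
        assert edit_distance("ACGTACGT", "ACGTACGT") == 0

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)

        def dp(a, b):
            prev = list(range(len(b) + 1))
            for i, x in enumerate(a, 1):
                cur = [i] + [0] * len(b)
                for j, y in enumerate(b, 1):
                    cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                                 prev[j - 1] + (x != y))
                prev = cur
            return prev[-1]

        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 50)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 50)))
            assert edit_distance(a, b) == dp(a, b)

    def test_edit_distance_coherence_threshold_and_restriction(self):
        a = make_cell("a", donor="d1")
        b = make_cell("b", donor="d2")
        a.light.seq_nt = "ACGT" * 30
        b.light.seq_nt = "ACGT" * 30
        c = make_cell("c", donor="d3", cdrh3_aa="CARDYF")
        c.light.seq_nt = "TTTT" * 30
        pairs = enumerate_pairs([a, b, c], "cross_donor", "memory")
        restricted = edit_distance_coherence(pairs, threshold=20)
        assert restricted.n_pairs == 1  # only the identical-CDRH3 pair
        assert restricted.fraction == 1.0
        unrestricted = edit_distance_coherence(
            pairs, threshold=20, restrict_to_identical_cdrh3=False
        )
        assert unrestricted.n_pairs == 3
        assert unrestricted.fraction == pytest.approx(1 / 3)


class TestRecurrences:
    def test_toy_counts(self):
        cells = [
            make_cell("a", donor="d1", cell_class="naive"),
            make_cell("b", donor="d2", cell_class="naive"),
            make_cell("c", donor="d2", cell_class="naive"),
            make_cell("d", donor="d1", cell_class="naive", cdrh3_aa="CARDYF"),
        ]
        summary = count_recurrences(cells, "naive")
        assert summary.n_recurrent_cells == 3
        assert summary.n_recurrent_keys == 1
        assert summary.mean_cdrh3_length == pytest.approx(6.0)

    def test_no_cross_donor_sharing(self):
        cells = [
            make_cell("a", donor="d1", cell_class="naive", cdrh3_aa="CARDYW"),
            make_cell("b", donor="d1", cell_class="naive", cdrh3_aa="CARDYW"),
        ]
        assert count_recurrences(cells, "naive").n_recurrent_cells == 0

    def test_key_uses_heavy_v_gene(self):
        cells = [
            make_cell("a", donor="d1", heavy_v="IGHV1-1", cell_class="naive"),
            make_cell("b", donor="d2", heavy_v="IGHV1-2", cell_class="naive"),
        ]
        assert count_recurrences(cells, "naive").n_recurrent_cells == 0


class TestSuperDonor:
    def test_relabeled_copies_reproduce_internal_coherence(self, small_sim):
        cells = [c.copy() for c in small_sim.cells]
        truth = small_sim.truth.set_index("cell_id")["true_class"]
        for c in cells:
            c.cell_class = truth[c.cell_id]
        # split donors into two pseudo-datasets
        ds_a = [c for c in cells if c.donor_id in ("d1", "d2")]
        ds_b = [c.copy() for c in cells if c.donor_id in ("d3", "d4")]
        for i, c in enumerate(ds_b):
            c.cell_id = f"B{i}"
        result = super_donor_coherence({"A": ds_a, "B": ds_b})
        pairs = enumerate_pairs(cells, "cross_donor", "memory")
        bin100_ab = [
            p for p in pairs
            if p.identity_bin == 100
            and {p.cell_a.donor_id, p.cell_b.donor_id} & {"d1", "d2"}
            and {p.cell_a.donor_id, p.cell_b.donor_id} & {"d3", "d4"}
        ]
        expected = light_chain_coherence(bin100_ab)
        assert result.pooled_bin100 == pytest.approx(expected)

    def test_single_dataset_rejected(self):
        with pytest.raises(errors.EmptyPairSet):
            super_donor_coherence({"only": []})

    def test_three_datasets_three_pairwise_comparisons(self):
        datasets = {
            "A": [make_cell("a", donor="d1")],
            "B": [make_cell("b", donor="d2")],
            "C": [make_cell("c", donor="d3")],
        }
        result = super_donor_coherence(datasets)
        assert set(result.per_pair) == {("A", "B"), ("A", "C"), ("B", "C")}
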