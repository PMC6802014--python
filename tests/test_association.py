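"""Coding schemes, permutation chi-square tests and the nested battery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from wolcall import calligrapha
from wolcall.association import (
    SCHEMES,
    CodingScheme,
    bonferroni,
    crosstab,
    encode,
    pearson_chi2,
    permutation_test,
    run_battery,
    wg_association,
)
from wolcall.coinfection import InfectionState, SpecimenRecord
from wolcall.mlst import LOCUS_NAMES
from wolcall.network import NestedCladeHierarchy

ST_GROUPS = {st_.st_id: st_.group for st_ in calligrapha.sequence_types()}


def record(infection, haplotype="H1", wg="", taxon="t"):
    rec = SpecimenRecord("S", taxon, "", haplotype, wg_genotype=wg, observations={})
    rec.infection = infection
    return rec


class TestEncode:
    def test_infection_level_categories(self):
        records = [
            record(InfectionState("uninfected")),
            record(InfectionState("single", sts=("wCallB2",))),
            record(InfectionState("double", sts=("wCallA1", "wCallC1"))),
        ]
        labels, _ = encode(records, "infection_level")
        assert labels == ["uninfected", "single", "double"]

    def test_group_combination_label(self):
        records = [record(InfectionState("double", sts=("wCallA1", "wCallC1")))]
        labels, _ = encode(records, "group", st_groups=ST_GROUPS)
        assert labels == ["A+C"]

    def test_genotype_label_and_uninfected_exclusion(self):
        records = [
            record(InfectionState("single", sts=("wCallB2",))),
            record(InfectionState("uninfected")),
        ]
        labels, excluded = encode(records, "genotype")
        assert labels == ["wCallB2", None]
        assert len(excluded) == 1

    def test_ambiguous_kept_for_level_dropped_for_genotype(self):
        amb = record(InfectionState("ambiguous", candidates=(("wCallB1", "wCallC1"),)))
        assert encode([amb], "infection_level")[0] == ["double"]
        assert encode([amb], "genotype")[0] == [None]

    def test_schemes_are_total_with_uninfected(self):
        records = [
            record(InfectionState("uninfected")),
            record(InfectionState("double", sts=("wCallA1", "wCallB1"))),
        ]
        for name, include_uninfected in SCHEMES.items():
            labels, excluded = encode(records, name, st_groups=ST_GROUPS)
            covered = sum(1 for l in labels if l is not None) + len(excluded)
            assert covered == len(records), name


class TestPearsonChi2:
    def test_independent_table_is_zero(self):
        assert pearson_chi2(np.array([[5, 5], [5, 5]])) == 0.0

    def test_diagonal_table(self):
        assert pearson_chi2(np.array([[10, 0], [0, 10]])) == pytest.approx(20.0)

    def test_degenerate_one_row(self):
        assert pearson_chi2(np.array([[3, 4, 5]])) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 30, size=(3, 4))
        ours = pearson_chi2(table)
        ref = chi2_contingency(table, correction=False).statistic
        assert ours == pytest.approx(ref, rel=1e-12)


class TestPermutationTest:
    def test_perfect_association_minimal_p(self):
        labels = ["x"] * 10 + ["y"] * 10
        res = permutation_test(labels, labels, n_perm=999, seed=1)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value <= 0.005

    def test_constant_vector_degenerate(self):
        res = permutation_test(["x", "y"] * 5, ["z"] * 10, n_perm=99, seed=0)
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_full_enumeration_small_n(self):
        a = ["x", "x", "x", "y", "y", "y", "y"]
        b = ["u", "u", "u", "v", "v", "v", "u"]
        obs = pearson_chi2(crosstab(a, b))
        hits = total = 0
        for perm in itertools.permutations(b):
            total += 1
            hits += pearson_chi2(crosstab(a, list(perm))) >= obs - 1e-12
        exact = hits / total
        res = permutation_test(a, b, n_perm=49_999, seed=11)
        se = math.sqrt(exact * (1 - exact) / 49_999)
        assert abs(res.p_value - exact) < 3 * se + 2 / 49_999

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(42)
        a = rng.integers(0, 3, 60).astype(str)
        b = rng.integers(0, 2, 60).astype(str)
        r1 = permutation_test(a, b, n_perm=999, seed=5)
        r2 = permutation_test(a, b, n_perm=999, seed=5)
        assert r1 == r2

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_invariance_to_category_relabeling_and_vector_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 40).astype(str)
        b = rng.integers(0, 2, 40).astype(str)
        base = permutation_test(a, b, n_perm=199, seed=7)
        relabeled = np.array([{"0": "zebra", "1": "ant", "2": "moth"}[x] for x in a])
        res2 = permutation_test(relabeled, b, n_perm=199, seed=7)
        assert res2.statistic == pytest.approx(base.statistic)
        assert res2.p_value == base.p_value
        # swapping the vectors keeps the statistic (chi-square is symmetric)
        swapped = permutation_test(b, a, n_perm=199, seed=7)
        assert swapped.statistic == pytest.approx(base.statistic)

    def test_significance_tiers(self):
        labels = ["x"] * 30 + ["y"] * 30
        res = permutation_test(labels, labels, n_perm=9999, seed=0)
        assert res.significance == "***"


def two_clade_hierarchy():
    return NestedCladeHierarchy(
        levels=[
            {"0-1": frozenset({"H1"}), "0-2": frozenset({"H2"}),
             "0-3": frozenset({"H3"}), "0-4": frozenset({"H4"})},
            {"1-1": frozenset({"H1", "H2"}), "1-2": frozenset({"H3", "H4"})},
            {"2-1": frozenset({"H1", "H2", "H3", "H4"})},
        ]
    )


class TestRunBattery:
    def test_planted_association_detected(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(120):
            hap = f"H{1 + rng.integers(0, 4)}"
            exclusive = hap in ("H1", "H2")
            inf = (
                InfectionState("single", sts=("wCallB1",))
                if exclusive
                else InfectionState("single", sts=("wCallC2",))
            )
            records.append(record(inf, haplotype=hap))
        report = run_battery(
            records, two_clade_hierarchy(), schemes=("genotype",), n_perm=999,
            seed=3, st_groups=ST_GROUPS,
        )
        total = [r for r in report.results if r.clade_label == "Total"]
        assert total and total[0].p_value <= 0.001

    def test_degenerate_cells_skipped_with_reason(self):
        records = [
            record(InfectionState("single", sts=("wCallB1",)), haplotype="H1")
            for _ in range(10)
        ]
        report = run_battery(
            records, two_clade_hierarchy(), schemes=("genotype",), n_perm=99, seed=0,
            st_groups=ST_GROUPS,
        )
        assert not report.results
        assert all(reason.startswith("degenerate") or reason == "no observations"
                   for _, _, reason in report.skipped)

    def test_unknown_haplotype_rejected(self):
        records = [record(InfectionState("uninfected"), haplotype="H99")]
        with pytest.raises(ValueError, match="H99"):
            run_battery(records, two_clade_hierarchy(), n_perm=9, seed=0)

    def test_report_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        records = [
            record(
                InfectionState("single", sts=(rng.choice(["wCallB1", "wCallC2"]),)),
                haplotype=f"H{1 + rng.integers(0, 4)}",
            )
            for _ in range(60)
        ]
        r1 = run_battery(records, two_clade_hierarchy(), schemes=("genotype",),
                         n_perm=499, seed=9, st_groups=ST_GROUPS)
        r2 = run_battery(records, two_clade_hierarchy(), schemes=("genotype",),
                         n_perm=499, seed=9, st_groups=ST_GROUPS)
        assert r1.results == r2.results and r1.skipped == r2.skipped


class TestWgAssociation:
    def _records(self, associated: bool, n=100, seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            hap = f"H{1 + rng.integers(0, 4)}"
            infected = hap in ("H1", "H2")
            inf = (
                InfectionState("single", sts=("wCallB1",))
                if infected
                else InfectionState("uninfected")
            )
            if associated:
                wg = "w1/w1" if infected else "w2/w2"
            else:
                wg = rng.choice(["w1/w1", "w1/w2", "w2/w2"])
            records.append(record(inf, haplotype=hap, wg=wg))
        return records

    def test_planted_wg_association_significant(self):
        results = wg_association(
            self._records(True), n_perm=999, seed=4, run_all=True
        )
        assert results and min(r.p_value for r in results) <= 0.001

    def test_no_wg_genotypes_empty(self):
        records = [record(InfectionState("uninfected"), wg="") for _ in range(5)]
        assert wg_association(records, n_perm=9, seed=0, run_all=True) == []

    def test_only_significant_clades_tested_by_default(self):
        records = self._records(True, seed=2)
        battery = run_battery(
            records, two_clade_hierarchy(), schemes=("infection_level",),
            n_perm=999, seed=1, st_groups=ST_GROUPS,
        )
        significant = {
            r.clade_label for r in battery.results if r.p_value <= 0.05
        }
        wg = wg_association(records, battery, two_clade_hierarchy(), n_perm=99, seed=0)
        assert {r.clade_label for r in wg} <= significant


class TestBonferroni:
    def test_adjustment_caps_at_one(self):
        labels = ["x"] * 6 + ["y"] * 6
        res = [permutation_test(labels, labels, n_perm=99, seed=s) for s in range(3)]
        adjusted = bonferroni(res)
        assert all(0 < p <= 1 for p in adjusted.values())
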