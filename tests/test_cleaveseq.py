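"""Cleavage fractions, normalization, bootstrap CIs, tests and hit calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavedrive import cleaveseq as cs
from cleavedrive.cleaveseq import (
    PrefixCounts,
    SwitchResult,
    bonferroni_threshold,
    bootstrap_ci,
    call_hits,
    cleavage_fraction,
    fold_change_table,
    proportion_test,
    reference_scale,
    replicate_test,
    switching_test,
)


class TestReferenceScale:
    def test_fifteen_references_at_18pM(self):
        # 15 spike-ins at 18 pM = 270 pM total over 2700 reads
        assert reference_scale(2700, 15, 18.0) == pytest.approx(0.1)

    def test_single_reference_unit_case(self):
        assert reference_scale(1, 1, 1.0) == 1.0

    def test_zero_reference_reads_is_an_error(self):
        with pytest.raises(ValueError):
            reference_scale(0, 15, 18.0)


class TestCleavageFraction:
    def test_no_cleaved_reads_gives_zero(self):
        assert cleavage_fraction(0, 100, 50, 200) == 0.0

    def test_equal_normalized_ratios_give_half(self):
        assert cleavage_fraction(50, 100, 100, 200) == pytest.approx(0.5)

    def test_hand_computed_example(self):
        # (300/100) / (100/200 + 300/100) = 3 / 3.5 = 6/7
        assert cleavage_fraction(300, 100, 100, 200) == pytest.approx(6 / 7)

    def test_both_sample_counts_zero_is_missing(self):
        assert math.isnan(cleavage_fraction(0, 100, 0, 200))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            cleavage_fraction(10, 0, 10, 100)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        rz=st.integers(0, 10**6),
        rw=st.integers(0, 10**6),
        zref=st.integers(1, 10**6),
        wref=st.integers(1, 10**6),
        scale=st.integers(2, 50),
    )
    def test_bounds_and_rescaling_invariance(self, rz, rw, zref, wref, scale):
        if rz + rw == 0:
            return
        c = cleavage_fraction(rz, zref, rw, wref)
        assert 0.0 <= c <= 1.0
        c2 = cleavage_fraction(rz * scale, zref * scale, rw * scale, wref * scale)
        assert c2 == pytest.approx(c)

    def test_monotone_in_cleaved_count(self):
        cs_ = [cleavage_fraction(z, 100, 50, 100) for z in (10, 20, 40, 80)]
        assert cs_ == sorted(cs_)


class TestFoldChangeTable:
    def test_single_sequence_forced_to_one(self):
        _, f = fold_change_table({1: 0.8}, {1: 0.4})
        assert f[1] == pytest.approx(1.0)

    def test_even_n_median_convention(self):
        # rho = {1.0, 4.0} -> even-N median 2.5 -> k = 0.4 -> f = {0.4, 1.6}
        norm, f = fold_change_table({1: 0.8, 2: 0.8}, {1: 0.8, 2: 0.2})
        assert norm.k == pytest.approx(0.4)
        assert f[1] == pytest.approx(0.4)
        assert f[2] == pytest.approx(1.6)

    def test_identical_ratios_all_one(self):
        c_minus = {i: 0.6 for i in range(5)}
        c_plus = {i: 0.2 for i in range(5)}
        _, f = fold_change_table(c_minus, c_plus)
        assert all(v == pytest.approx(1.0) for v in f.values())

    def test_median_of_qualifying_f_is_one(self, rng):
        c_minus = {i: rng.uniform(0.2, 0.8) for i in range(31)}
        c_plus = {i: rng.uniform(0.2, 0.8) for i in range(31)}
        _, f = fold_change_table(c_minus, c_plus)
        assert np.median(list(f.values())) == pytest.approx(1.0)

    def test_fully_cleaved_reference_condition_is_missing(self):
        _, f = fold_change_table({1: 1.0, 2: 0.5}, {1: 0.5, 2: 0.5})
        assert math.isnan(f[1])
        assert f[2] == pytest.approx(1.0)

    def test_min_reads_filtering_changes_normalization(self):
        c_minus = {1: 0.8, 2: 0.8}
        c_plus = {1: 0.8, 2: 0.2}  # rho 1 and 4
        norm, _ = fold_change_table(
            c_minus, c_plus, reads_minus={1: 100, 2: 10}, reads_plus={1: 100, 2: 100},
            min_reads=30,
        )
        # only sequence 1 qualifies -> k = 1
        assert norm.k == pytest.approx(1.0)
        assert norm.n_sequences_used == 1

    def test_no_qualifying_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            fold_change_table({1: 1.0}, {1: 0.5})


class TestBootstrapCI:
    def test_symmetric_counts_bracket_half(self):
        counts = PrefixCounts(500, 500, 50_000, 50_000)
        ci = bootstrap_ci(counts, B=1000, seed=1)["c"]
        assert ci[0] < 0.5 < ci[1]
        assert abs((0.5 - ci[0]) - (ci[1] - 0.5)) < 0.01

    def test_interval_collapses_at_high_depth(self):
        wide = bootstrap_ci(PrefixCounts(70, 30, 10**6, 10**6), B=1000, seed=2)["c"]
        narrow = bootstrap_ci(
            PrefixCounts(700_000, 300_000, 10**6, 10**6), B=1000, seed=2
        )["c"]
        assert (narrow[1] - narrow[0]) < (wide[1] - wide[0]) / 10

    def test_reproducible_under_seed(self):
        counts = PrefixCounts(80, 120, 1000, 1000)
        a = bootstrap_ci(counts, B=500, seed=7)
        b = bootstrap_ci(counts, B=500, seed=7)
        assert a == b

    def test_zero_total_reads_is_an_error(self):
        with pytest.raises(ValueError):
            bootstrap_ci(PrefixCounts(0, 0, 100, 100))

    def test_fold_change_interval_brackets_truth(self):
        minus = PrefixCounts(700, 300, 10_000, 10_000)  # c = 0.7
        plus = PrefixCounts(100, 900, 10_000, 10_000)  # c = 0.1, rho = 3
        out = bootstrap_ci(minus, B=1000, seed=3, counts_plus=plus)
        lo, hi = out["f"]
        assert lo < 3.0 < hi


class TestProportionTests:
    def test_identical_tables_not_significant(self):
        assert proportion_test(90, 10, 90, 10) == pytest.approx(1.0)

    def test_opposite_proportions_extremely_significant(self):
        assert proportion_test(90, 10, 10, 90) < 1e-15

    def test_agrees_with_exact_oracle(self):
        from scipy.stats import fisher_exact

        expected = fisher_exact([[30, 70], [50, 50]], "two-sided").pvalue
        assert proportion_test(30, 70, 50, 50) == pytest.approx(expected)

    def test_p_decreases_with_depth_at_fixed_proportions(self):
        ps = [
            switching_test((60 * s, 40 * s), (40 * s, 60 * s))
            for s in (1, 10, 100)
        ]
        assert ps[0] > ps[1] > ps[2]

    def test_switching_below_min_reads_untested(self):
        assert switching_test((10, 10), (10, 10), min_reads=30) is None


class TestReplicateTest:
    def test_identical_replicates_have_no_outliers(self):
        counts = {i: (200 + i, 300) for i in range(20)}
        pvals, outliers = replicate_test(counts, counts)
        assert outliers == set()
        assert all(p == pytest.approx(1.0) for p in pvals.values())

    def test_bonferroni_threshold_matches_published_scale(self):
        # 0.1 / 12025 ~= 8e-6 at one significant figure
        thr = bonferroni_threshold(0.1, 12_025)
        assert thr == pytest.approx(8.32e-6, rel=0.01)
        assert float(f"{thr:.0e}") == 8e-6

    def test_discordant_sequence_flagged(self):
        counts1 = {i: (500, 500) for i in range(10)}
        counts2 = dict(counts1)
        counts1[0] = (90, 910)
        counts2[0] = (910, 90)
        _, outliers = replicate_test(counts1, counts2)
        assert outliers == {0}

    def test_min_reads_excludes_shallow_sequences(self):
        counts1 = {1: (10, 10), 2: (500, 500)}
        counts2 = {1: (10, 10), 2: (480, 520)}
        pvals, _ = replicate_test(counts1, counts2, min_reads=100)
        assert set(pvals) == {2}

    def test_no_shared_accessions_is_an_error(self):
        with pytest.raises(ValueError):
            replicate_test({1: (100, 100)}, {2: (100, 100)})


class TestHitCalling:
    def make(self, acc, f, p):
        return SwitchResult(acc, f, f * 0.9, f * 1.1, p)

    def test_rule_conjunction(self):
        results = {
            1: self.make(1, 2.5, 1e-9),  # hit
            2: self.make(2, 1.9, 1e-9),  # fold too low
            3: self.make(3, 2.5, 1e-3),  # not significant at 1/N = 1e-4
        }
        called = call_hits(results, N=10_000)
        assert [called[i].is_hit for i in (1, 2, 3)] == [True, False, False]

    def test_flagged_sequences_never_hits(self):
        results = {1: self.make(1, 3.0, 1e-12)}
        called = call_hits(results, N=100, flagged={1})
        assert not called[1].is_hit

    def test_bonferroni_edge_cases(self):
        assert bonferroni_threshold(1.0, 1) == 1.0
        assert bonferroni_threshold(1.0, 4328) == pytest.approx(2.31e-4, rel=0.01)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.1, 0)


class TestQuantifyRun:
    def test_planted_switcher_is_the_unique_hit(self):
        from cleavedrive.synthgen import generate_count_run, random_truth

        truth = random_truth(
            n_sequences=50, n_switchers=1, rho=3.0, depth=400_000, seed=5
        )
        table = generate_count_run(truth)
        df = cs.quantify_run(table, "minus", "plus", B=200, seed=9)
        hits = set(df.loc[df["is_hit"], "core_seq"])
        switcher = truth.truth_frame().iloc[0]["core_seq"]
        assert hits == {switcher}

    def test_normalization_median_is_one(self):
        from cleavedrive.synthgen import generate_count_run, random_truth

        truth = random_truth(n_sequences=40, n_switchers=0, depth=200_000, seed=6)
        table = generate_count_run(truth)
        df = cs.quantify_run(table, "minus", "plus", B=200, seed=10)
        assert np.nanmedian(df["f"]) == pytest.approx(1.0, abs=1e-9)


class TestReferenceScaleFromTable:
    def test_scale_from_generated_run(self):
        from cleavedrive.cleaveseq import reference_scale_from_table
        from cleavedrive.synthgen import generate_count_run, random_truth

        truth = random_truth(3, depth=30_000, seed=12)
        table = generate_count_run(truth)
        refs = table.references
        sub = refs[(refs["prefix"] == "Z") & (refs["condition"] == "minus")]
        expected = 18.0 * sub["core_seq"].nunique() / sub["count"].sum()
        scale = reference_scale_from_table(table, "Z", "minus")
        assert scale == pytest.approx(expected)
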