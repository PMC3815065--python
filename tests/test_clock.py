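"""Clock calibration, modal differences, resampling ESS, Poisson CIs and
spectrum utilities."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from hapclock import clock
from hapclock.types import MISSING, HapclockError, PairwiseAlignment


class TestAlignmentDifferences:
    def test_identical_ungapped_sequences(self):
        aln = PairwiseAlignment("A" * 100, "A" * 100)
        assert clock.count_alignment_differences(aln) == (0, 100)

    def test_gap_masking_excludes_a_four_nt_halo(self):
        # 16 columns, gap at column 8, mismatch at column 16:
        # columns 4-12 are masked, leaving 7 columns and 1 difference
        a = "AAAAAAA-AAAAAAAA"
        b = "AAAAAAAAAAAAAAAC"
        assert clock.count_alignment_differences(PairwiseAlignment(a, b)) == (1, 7)

    def test_mismatch_inside_the_mask_is_not_counted(self):
        a = "AAAAAAA-AAAAAAAA"
        b = "AAAAAAAAACAAAAAA"  # mismatch at column 10, inside the halo
        assert clock.count_alignment_differences(PairwiseAlignment(a, b)) == (0, 7)

    def test_radius_zero_excludes_only_gap_columns(self):
        a = "AC-GT"
        b = "ACCGA"
        assert clock.count_alignment_differences(
            PairwiseAlignment(a, b), gap_mask_radius=0
        ) == (1, 4)


class TestCalibration:
    def test_published_alignment_summary_reproduces_the_printed_rate(self):
        cal = clock.calibrate_rate(1227, 125_531, 6e6)
        assert float(f"{cal.rate:.2g}") == 8.1e-10
        assert cal.rate == pytest.approx(8.1449e-10, rel=1e-4)

    def test_zero_differences_give_zero_rate(self):
        assert clock.calibrate_rate(0, 1000).rate == 0.0

    def test_forced_arithmetic(self):
        assert clock.calibrate_rate(12, 1000, 6e6).rate == pytest.approx(1e-9)

    def test_rate_scales_inversely_with_divergence_time(self):
        r1 = clock.calibrate_rate(100, 1000, 1e6).rate
        r2 = clock.calibrate_rate(100, 1000, 2e6).rate
        assert r1 == pytest.approx(2 * r2)


class TestModalAndDifferences:
    def test_identical_chromosomes_are_their_own_mode(self):
        rows = np.array([[0, 1, 1]] * 4)
        assert clock.modal_haplotype(rows).tolist() == [0, 1, 1]

    def test_per_site_majority(self):
        rows = np.array([[0, 0], [0, 1], [0, 1]])
        assert clock.modal_haplotype(rows).tolist() == [0, 1]

    def test_ties_resolve_to_the_ancestral_allele(self):
        rows = np.array([[0, 1], [1, 0]])
        assert clock.modal_haplotype(rows).tolist() == [0, 0]
        assert clock.modal_haplotype(rows, tie="derived").tolist() == [1, 1]

    def test_diff_from_modal_counts_and_mean(self):
        rows = np.array([[0, 0], [0, 1], [1, 1]])
        counts, total, mean = clock.diff_from_modal(rows, np.array([0, 0]))
        assert counts.tolist() == [0, 1, 2]
        assert (total, mean) == (3, 1.0)

    def test_missing_calls_do_not_contribute(self):
        rows = np.array([[MISSING, 1], [0, 1]])
        counts, total, _ = clock.diff_from_modal(rows, np.array([0, 0]))
        assert counts.tolist() == [1, 1]

    def test_permuting_chromosomes_permutes_counts_only(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(10, 6))
        modal = clock.modal_haplotype(rows)
        perm = rng.permutation(10)
        c1, t1, m1 = clock.diff_from_modal(rows, modal)
        c2, t2, m2 = clock.diff_from_modal(rows[perm], modal)
        assert sorted(c1) == sorted(c2) and (t1, m1) == (t2, m2)


class TestAgeEstimate:
    def test_zero_mean_difference_dates_to_the_present(self):
        assert clock.estimate_age(0.0, 8.1e-10, 127_419) == 0.0

    def test_estimate_is_invariant_to_duplicating_every_chromosome(self):
        """Nonindependent sampling robustness: copying every lineage leaves
        the point estimate unchanged."""
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        doubled = np.vstack([rows, rows])
        rate, length = 8.145e-10, 127_419
        modal = clock.modal_haplotype(rows)
        _, _, mean1 = clock.diff_from_modal(rows, modal)
        _, _, mean2 = clock.diff_from_modal(doubled, clock.modal_haplotype(doubled))
        assert clock.estimate_age(mean1, rate, length) == pytest.approx(
            clock.estimate_age(mean2, rate, length)
        )


class TestEffectiveSampleSize:
    def test_single_class_always_duplicates_on_the_second_draw(self):
        assert clock.effective_sample_size(["h"] * 50, replicates=100, seed=0) == 1

    def test_two_classes_match_exact_enumeration(self):
        """With two equal classes the count before repeat is 1 or 2 with
        probability 1/2 each (exact enumeration), so the median is 1 or 2."""
        # exact distribution: P(1) = 1/2 (second draw repeats the first),
        # P(2) = 1/2 (third draw must repeat one of the two seen)
        med = clock.effective_sample_size(["a", "b"], replicates=4_001, seed=1)
        assert med in (1, 2)
        # empirical distribution from an independent brute-force process
        rnd = random.Random(42)
        counts = []
        for _ in range(20_000):
            seen, n = set(), 0
            while True:
                x = rnd.choice(["a", "b"])
                if x in seen:
                    break
                seen.add(x)
                n += 1
            counts.append(n)
        assert abs(counts.count(1) / len(counts) - 0.5) < 0.02
        assert abs(counts.count(2) / len(counts) - 0.5) < 0.02

    @pytest.mark.parametrize("n_classes", [10, 100])
    def test_uniform_classes_match_a_birthday_process_oracle(self, n_classes):
        classes = [f"h{i}" for i in range(n_classes)]
        med = clock.effective_sample_size(classes, replicates=4_000, seed=5)
        rnd = random.Random(99)
        oracle = []
        for _ in range(4_001):
            seen, n = set(), 0
            while True:
                x = rnd.randrange(n_classes)
                if x in seen:
                    break
                seen.add(x)
                n += 1
            oracle.append(n)
        oracle.sort()
        assert abs(med - oracle[len(oracle) // 2]) <= 1

    def test_empty_multiset_is_an_error(self):
        with pytest.raises(HapclockError):
            clock.effective_sample_size([], seed=0)


class TestPoissonInterval:
    def test_k_ten_matches_the_chi_square_oracle(self):
        low, high = clock.poisson_interval(10)
        assert low == pytest.approx(stats.chi2.ppf(0.025, 20) / 2)
        assert high == pytest.approx(stats.chi2.ppf(0.975, 22) / 2)
        assert (low, high) == (pytest.approx(4.795, abs=5e-4), pytest.approx(18.39, abs=5e-3))

    def test_interval_width_vanishes_for_large_counts(self):
        for k, age in [(10, 8000.0), (10_000, 8000.0)]:
            low, high = clock.age_confidence_interval(k, age)
            assert low < age < high
        lo_small, hi_small = clock.age_confidence_interval(10, 8000.0)
        lo_big, hi_big = clock.age_confidence_interval(10_000, 8000.0)
        assert (hi_big - lo_big) / 8000.0 < (hi_small - lo_small) / 8000.0
        assert (hi_big - lo_big) / 8000.0 < 0.05

    def test_scaled_intervals_are_nested_when_the_count_doubles(self):
        age = 5000.0
        for k in (3, 7.5, 20, 80):
            lo1, hi1 = clock.age_confidence_interval(k, age)
            lo2, hi2 = clock.age_confidence_interval(2 * k, age)
            assert lo1 <= lo2 <= age <= hi2 <= hi1

    def test_zero_count_gives_a_degenerate_interval(self):
        lo, hi = clock.age_confidence_interval(0, 0.0)
        assert lo == 0.0 and math.isinf(hi)


class TestUndercountCorrection:
    def test_perfect_power_means_no_correction(self):
        assert clock.undercount_correction({1: 10, 2: 4}, {1: 1.0, 2: 1.0}) == 1.0

    def test_hand_arithmetic(self):
        factor = clock.undercount_correction({1: 10, 2: 5}, {1: 0.5, 2: 1.0})
        assert factor == pytest.approx(25 / 15)

    def test_factor_decreases_as_power_improves(self):
        spectrum = {1: 20, 2: 10, 3: 5}
        worse = clock.undercount_correction(spectrum, {1: 0.4, 2: 0.8, 3: 0.9})
        better = clock.undercount_correction(spectrum, {1: 0.6, 2: 0.8, 3: 0.9})
        assert worse > better >= 1.0

    def test_missing_or_invalid_power_is_an_error(self):
        with pytest.raises(HapclockError, match="no detection power"):
            clock.undercount_correction({1: 5, 2: 1}, {1: 0.5})
        with pytest.raises(HapclockError, match="outside"):
            clock.undercount_correction({1: 5}, {1: 0.0})


class TestSubstitutionSpectrum:
    def test_printed_statistic_has_upper_tail_probability_half(self):
        assert round(clock.chi_square_upper_tail(4.42, 5), 2) == 0.49

    def test_identical_proportions_give_zero_statistic(self):
        a = {"ts": 30, "tv": 10, "cpg": 20}
        b = {"ts": 60, "tv": 20, "cpg": 40}
        chi2, df, p = clock.substitution_spectrum_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_by_two_equal_table(self):
        chi2, df, _ = clock.substitution_spectrum_test(
            {"a": 10, "b": 10}, {"a": 10, "b": 10}
        )
        assert chi2 == 0.0 and df == 1

    def test_empty_classes_are_pooled_out(self):
        chi2, df, _ = clock.substitution_spectrum_test(
            {"a": 10, "b": 0, "c": 5}, {"a": 8, "b": 0, "c": 9}
        )
        assert df == 1  # class b dropped


class TestDatingPipeline:
    def test_date_from_totals_carries_the_correction_through(self):
        rate = clock.calibrate_rate(1227, 125_531).rate
        est = clock.date_from_totals(
            1013, 822, rate, 127_419, ess=19, correction_factor=1.58
        )
        assert est.corrected_age == pytest.approx(est.age * 1.58)
        assert est.corrected_ci[0] == pytest.approx(est.ci[0] * 1.58)
        assert est.eff_count == pytest.approx(19 * 822 / 1013)

    def test_date_carriers_runs_end_to_end(self):
        rng = np.random.default_rng(11)
        rows = (rng.random((40, 25)) < 0.05).astype(np.int8)
        est = clock.date_carriers(rows, 8.145e-10, 127_419, replicates=200, seed=7)
        assert est.n_chrom == 40
        assert est.ci[0] <= est.age <= est.ci[1]
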