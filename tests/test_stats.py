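import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from cpgpipe.panel import Individual, TumorDiagnosis, load_tumor_vocabulary
from cpgpipe.simulate import SimulationConfig, generate_cohort
from cpgpipe.stats import (
    CombinationRecord,
    ReferencePopulationCounts,
    combination_distribution,
    coverage_summary,
    detection_rates,
    enumerate_combinations,
    pearson_chi2,
    registry_comparison,
    round_percent,
    sex_adjusted_frequency,
    yield_projection,
)


def _ind(categories, iid="P0001", ages=None):
    ages = ages or [40.0] * len(categories)
    return Individual(
        individual_id=iid, family_id=iid, sex="female",
        tumors=tuple(TumorDiagnosis(c, a) for c, a in zip(categories, ages)),
    )


class TestCombinations:
    def test_two_discordant_tumors_one_pair(self):
        assert len(enumerate_combinations(_ind(["breast", "colorectal"]))) == 1

    def test_three_discordant_tumors_three_pairs(self):
        recs = enumerate_combinations(_ind(["breast", "ovary", "endometrium"]))
        assert len(recs) == 3

    def test_concordant_pair_contributes_nothing(self):
        assert enumerate_combinations(_ind(["breast", "breast"])) == []

    def test_pair_order_normalized(self):
        rec = CombinationRecord(pair=("ovary", "breast"), individual_id="x")
        assert rec.pair == ("breast", "ovary")

    def test_same_category_pair_rejected(self):
        with pytest.raises(ValueError):
            CombinationRecord(pair=("breast", "breast"), individual_id="x")

    def test_total_combinations_identity(self):
        """Total combinations equal the sum of C(k_i, 2) over distinct
        category counts, on a generated cohort."""
        cohort = generate_cohort(SimulationConfig(seed=5, n_probands=200))
        dist = combination_distribution(cohort)
        expected = sum(
            len(ind.tumor_categories) * (len(ind.tumor_categories) - 1) // 2
            for ind in cohort
        )
        assert dist["combinations"] == expected
        assert sum(dist["type_counts"].values()) == expected

    def test_frequency_of_frequency_fixture(self):
        # structure: 206 types once, 53 twice, 68 three+ -> 327 types
        cohort = []
        idx = 0
        pairs = [(f"a{i}", f"b{i}") for i in range(327)]
        for i, pair in enumerate(pairs):
            reps = 1 if i < 206 else 2 if i < 259 else 3
            for _ in range(reps):
                cohort.append(_ind(list(pair), iid=f"P{idx:05d}"))
                idx += 1
        dist = combination_distribution(cohort)
        bd = dist["type_frequency_breakdown"]
        assert dist["n_types"] == 327
        assert (bd["once"], bd["twice"], bd["three_or_more"]) == (206, 53, 68)
        assert (bd["once_pct"], bd["twice_pct"], bd["three_or_more_pct"]) == (
            63.0, 16.2, 20.8
        )

    def test_single_individual_single_type(self):
        dist = combination_distribution([_ind(["breast", "colorectal"])])
        assert dist["n_types"] == 1
        assert dist["share_of_combinations"][("breast", "colorectal")] == 100.0


class TestPearsonChi2:
    def test_identical_proportions_zero(self):
        assert pearson_chi2([[10, 90], [10, 90]]).statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 5]])

    @given(st.lists(st.integers(1, 500), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_matches_observed_expected_formulation(self, cells):
        """The closed-form 2x2 statistic equals brute-force sum((O-E)^2/E)."""
        table = np.array(cells, dtype=float).reshape(2, 2)
        res = pearson_chi2(table)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows @ cols / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(brute, rel=1e-10)

    @given(st.lists(st.integers(1, 500), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_uncorrected(self, cells):
        table = np.array(cells, dtype=float).reshape(2, 2)
        res = pearson_chi2(table)
        ref = chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_invariant_under_row_and_column_swaps(self):
        t = [[52, 388], [298, 8694]]
        base = pearson_chi2(t).statistic
        assert pearson_chi2([t[1], t[0]]).statistic == pytest.approx(base)
        assert pearson_chi2(
            [[388, 52], [8694, 298]]
        ).statistic == pytest.approx(base)
        transpose = [[52, 298], [388, 8694]]
        assert pearson_chi2(transpose).statistic == pytest.approx(base)


class TestRegistryComparison:
    def _vocab(self):
        return load_tumor_vocabulary()

    def test_enriched_type_flagged(self):
        # MPT cohort: breast-ovary 5x enriched relative to the registry
        cohort = [
            _ind(["breast", "ovary"], iid=f"P{i:04d}") for i in range(50)
        ] + [
            _ind(["breast", "colorectal"], iid=f"Q{i:04d}") for i in range(50)
        ]
        registry = {("breast", "ovary"): 10, ("breast", "colorectal"): 50,
                    ("colorectal", "kidney"): 40}
        results = registry_comparison(cohort, registry, self._vocab())
        flagged = {r["pair"] for r in results if r["significant"]}
        assert ("breast", "ovary") in flagged

    def test_identical_cohorts_nothing_flagged(self):
        cohort = [
            _ind(["breast", "ovary"], iid=f"P{i:04d}") for i in range(30)
        ] + [
            _ind(["breast", "colorectal"], iid=f"Q{i:04d}") for i in range(30)
        ]
        registry = {("breast", "ovary"): 30, ("breast", "colorectal"): 30}
        results = registry_comparison(cohort, registry, self._vocab())
        assert not any(r["significant"] for r in results)

    def test_rare_type_not_tested(self):
        cohort = [
            _ind(["breast", "ovary"], iid=f"P{i:04d}") for i in range(200)
        ] + [_ind(["kidney", "thyroid"], iid="PRARE")]
        registry = {("breast", "ovary"): 100}
        results = registry_comparison(cohort, registry, self._vocab())
        tested = {r["pair"] for r in results}
        assert ("kidney", "thyroid") not in tested

    def test_restriction_by_age_and_malignancy(self):
        # benign tumors and diagnoses at/after 60 are dropped before pairing
        cohort = [
            _ind(["breast", "pheochromocytoma"], iid="P1"),   # benign partner
            _ind(["breast", "colorectal"], iid="P2", ages=[45, 62]),  # late dx
            _ind(["breast", "colorectal"], iid="P3", ages=[45, 50]),
            _ind(["breast", "cns"], iid="P4", ages=[30, 40]),  # CNS kept
        ]
        registry = {("breast", "colorectal"): 5, ("breast", "cns"): 5}
        results = registry_comparison(cohort, registry, self._vocab())
        assert {r["pair"] for r in results} == {("breast", "colorectal"),
                                                ("breast", "cns")}
        assert results[0]["mpt_total"] == 2

    def test_empty_after_restriction_errors(self):
        cohort = [_ind(["breast", "colorectal"], iid="P1", ages=[65, 70])]
        with pytest.raises(ValueError, match="empty"):
            registry_comparison(cohort, {("breast", "ovary"): 5},
                                self._vocab())


class TestSexAdjustment:
    def test_equal_frequencies_invariant(self):
        ref = ReferencePopulationCounts(1000, 1000, 50, 50)
        for p in (0.2, 0.5, 0.77):
            assert sex_adjusted_frequency(ref, p) == pytest.approx(0.05)

    def test_hand_arithmetic(self):
        # f_m=0.10, f_f=0.02, n_f=1000, 50% female -> (0.10+0.02)/2
        ref = ReferencePopulationCounts(5000, 1000, 500, 20)
        assert sex_adjusted_frequency(ref, 0.5) == pytest.approx(0.06)

    def test_adjusted_male_count(self):
        # keeping 6,929 females at 77% female implies ~2,069.7 males
        n_female, p = 6929, 0.77
        assert n_female * (1 - p) / p == pytest.approx(2069.7, abs=0.05)

    def test_bounded_by_sex_frequencies(self):
        ref = ReferencePopulationCounts(4000, 3000, 300, 30)
        for p in (0.1, 0.35, 0.77, 0.9):
            adj = sex_adjusted_frequency(ref, p)
            assert min(ref.freq_male, ref.freq_female) <= adj
            assert adj <= max(ref.freq_male, ref.freq_female)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sex_adjusted_frequency(ReferencePopulationCounts(0, 10, 0, 1), 0.5)
        with pytest.raises(ValueError):
            sex_adjusted_frequency(
                ReferencePopulationCounts(10, 10, 1, 1), 0.0
            )


class TestYieldAndRates:
    def test_boundary_identities(self):
        assert yield_projection(0.0, 0.3) == 0.3
        assert yield_projection(1.0, 0.3) == 1.0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, prior, inc, inc2):
        y = yield_projection(prior, inc)
        assert 0 <= y <= 1
        assert yield_projection(prior, max(inc, inc2)) >= y

    def test_detection_rate_table(self):
        table = detection_rates({"plp": 67}, 440)
        assert table["plp"]["percent"] == 15.2
        assert table["plp"]["numerator"] == 67

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            detection_rates({"x": 1}, 0)

    def test_round_half_up(self):
        assert round_percent(0.1625) == 16.3
        assert round_percent(0.0) == 0.0


class TestCoverage:
    def test_uniform_depth(self):
        assert coverage_summary([35] * 100) == (35.0, 1.0)

    def test_threshold_inclusive(self):
        mean, frac = coverage_summary([5, 15], threshold=10)
        assert (mean, frac) == (10.0, 0.5)
        assert coverage_summary([10], threshold=10)[1] == 1.0

    def test_against_naive_loop(self):
        rng = np.random.default_rng(4)
        depths = rng.integers(0, 60, size=500)
        mean, frac = coverage_summary(depths, threshold=10)
        naive_mean = sum(depths) / len(depths)
        naive_frac = sum(1 for d in depths if d >= 10) / len(depths)
        assert mean == pytest.approx(naive_mean)
        assert frac == pytest.approx(naive_frac)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coverage_summary([])
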