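import random

import pytest

from cpgpipe.panel import Panel
from cpgpipe.snv import (
    SnvFilterConfig,
    derive_cadd_threshold,
    exclusion_rules,
    frequency_filter,
    noncoding_lookup,
    quality_filter,
    retention_rules,
    run_snv_pipeline,
    variant_allele_fraction,
)
from cpgpipe.variants import ClinvarAssertion, Outcome, Stage

from conftest import make_variant


class TestVaf:
    @pytest.mark.parametrize(
        "alt,dp,expected",
        [(7, 22, 7 / 22), (9, 29, 9 / 29), (10, 20, 0.5)],
    )
    def test_fraction(self, alt, dp, expected):
        assert variant_allele_fraction(alt, dp) == pytest.approx(expected)

    def test_reported_percent_rounding(self):
        # marginally sub-threshold calls print as 32% and 31%
        assert round(variant_allele_fraction(7, 22) * 100) == 32
        assert round(variant_allele_fraction(9, 29) * 100) == 31

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            variant_allele_fraction(0, 0)


class TestQualityFilter:
    def test_all_boundaries_inclusive(self):
        v = make_variant(gq=30.0, dp=10, alt_depth=5)
        assert quality_filter(v).outcome is Outcome.PASS

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            (dict(gq=29.0), "low_gq"),
            (dict(dp=9, alt_depth=5), "low_dp"),
            (dict(dp=2, alt_depth=1), "low_dp"),
            (dict(dp=22, alt_depth=7, gq=60.0), "low_vaf"),  # 31.8% < 33%
            (dict(dp=29, alt_depth=9), "low_vaf"),
            (dict(filter_status="LowQual"), "not_pass"),
        ],
    )
    def test_single_criterion_failures(self, overrides, reason):
        v = make_variant(**overrides)
        d = quality_filter(v)
        assert d.outcome is Outcome.FAIL
        assert reason in d.reason_codes

    def test_vaf_boundary_exact_rational(self):
        # 33/100 exactly passes; one read fewer fails
        assert quality_filter(make_variant(dp=100, alt_depth=33)).outcome is Outcome.PASS
        assert quality_filter(make_variant(dp=100, alt_depth=32)).outcome is Outcome.FAIL

    def test_missing_fields(self):
        d = quality_filter(make_variant(gq=None, dp=None, alt_depth=None))
        assert d.reason_codes == ("missing_quality_field",)

    def test_all_reasons_listed(self):
        d = quality_filter(make_variant(gq=10.0, dp=9, alt_depth=1,
                                        filter_status="q10"))
        assert set(d.reason_codes) == {"low_gq", "low_dp", "low_vaf", "not_pass"}


class TestFrequencyFilter:
    def test_above_threshold_fails(self):
        d = frequency_filter(make_variant(af_exac=0.02))
        assert d.outcome is Outcome.FAIL
        assert d.reason_codes == ("af_exac_above_threshold",)

    def test_exactly_threshold_passes(self):
        assert frequency_filter(make_variant(af_exac=0.01)).outcome is Outcome.PASS
        assert frequency_filter(make_variant(af_exac=0.010001)).outcome is Outcome.FAIL

    def test_absent_treated_as_zero(self):
        absent = frequency_filter(make_variant(af_exac=None, af_1kg=None))
        explicit = frequency_filter(make_variant(af_exac=0.0, af_1kg=0.0))
        assert absent.outcome == explicit.outcome == Outcome.PASS

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            make_variant(af_1kg=-0.1)


class TestRetention:
    def test_truncating(self):
        d = retention_rules(make_variant(so_consequence="stop_gained"))
        assert d.outcome is Outcome.RETAINED
        assert "truncating_consequence" in d.reason_codes

    def test_cadd_route(self):
        v = make_variant(so_consequence="missense_variant",
                         truncation_fraction=None, cadd_phred=35.0)
        d = retention_rules(v)
        assert d.reason_codes == ("cadd_above_threshold",)

    def test_cadd_boundary(self):
        lo = make_variant(so_consequence="missense_variant",
                          truncation_fraction=None, cadd_phred=33.99)
        hi = make_variant(so_consequence="missense_variant",
                          truncation_fraction=None, cadd_phred=34.0)
        assert retention_rules(lo).outcome is Outcome.FAIL
        assert retention_rules(hi).outcome is Outcome.RETAINED

    def test_clinvar_two_star(self):
        v = make_variant(so_consequence="missense_variant",
                         truncation_fraction=None,
                         clinvar_assertion=ClinvarAssertion.PATHOGENIC,
                         clinvar_stars=2)
        assert retention_rules(v).reason_codes == ("clinvar_plp_two_star",)

    def test_clinvar_one_star_not_enough(self):
        v = make_variant(so_consequence="missense_variant",
                         truncation_fraction=None,
                         clinvar_assertion=ClinvarAssertion.PATHOGENIC,
                         clinvar_stars=1, cadd_phred=20.0)
        assert retention_rules(v).outcome is Outcome.FAIL

    def test_nothing_fires(self):
        v = make_variant(so_consequence="missense_variant",
                         truncation_fraction=None, cadd_phred=20.0)
        assert retention_rules(v).outcome is Outcome.FAIL


class TestCaddThreshold:
    def test_odd_median(self):
        assert derive_cadd_threshold([30, 34, 40]) == 34

    def test_even_median_midpoint(self):
        assert derive_cadd_threshold([30, 38]) == 34

    def test_against_sort_oracle(self):
        rng = random.Random(7)
        scores = [rng.uniform(20, 50) for _ in range(101)]
        assert derive_cadd_threshold(scores) == sorted(scores)[50]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            derive_cadd_threshold([])


class TestNoncodingLookup:
    def test_exact_match_retained(self, panel):
        entry = ("chr1", 10_050, "C", "T")
        p = Panel(genes=panel.genes, noncoding_pathogenic_positions=(entry,))
        assert noncoding_lookup(make_variant(), p).outcome is Outcome.RETAINED

    def test_allele_mismatch(self, panel):
        p = Panel(genes=panel.genes,
                  noncoding_pathogenic_positions=(("chr1", 10_050, "C", "G"),))
        assert noncoding_lookup(make_variant(), p).outcome is Outcome.FAIL

    def test_empty_list(self, panel):
        assert noncoding_lookup(make_variant(), panel).outcome is Outcome.FAIL


class TestExclusion:
    def _run(self, v, gene, reasons=("truncating_consequence",), dose=1):
        return exclusion_rules(v, gene, reasons, dose)

    def test_truncating_in_proto_oncogene(self, panel):
        v = make_variant(gene_symbol="RET")
        d = self._run(v, panel["RET"])
        assert d.outcome is Outcome.EXCLUDED
        assert "truncating_in_proto_oncogene" in d.reason_codes

    def test_truncation_fraction_boundary(self, panel):
        low = make_variant(truncation_fraction=0.049)
        ok = make_variant(truncation_fraction=0.05)
        assert self._run(low, panel["BRCA1"]).outcome is Outcome.EXCLUDED
        assert self._run(ok, panel["BRCA1"]).outcome is Outcome.PASS

    def test_missing_truncation_fraction_skips_criterion(self, panel):
        v = make_variant(truncation_fraction=None)
        assert self._run(v, panel["BRCA1"]).outcome is Outcome.PASS

    def test_recessive_single_variant_excluded(self, panel):
        v = make_variant(gene_symbol="MUTYH")
        d = self._run(v, panel["MUTYH"], dose=1)
        assert "recessive_gene_single_variant" in d.reason_codes

    def test_recessive_homozygous_not_excluded(self, panel):
        v = make_variant(gene_symbol="NTHL1", zygosity="hom")
        assert self._run(v, panel["NTHL1"], dose=2).outcome is Outcome.PASS

    def test_truncating_with_benign_clinvar(self, panel):
        v = make_variant(clinvar_assertion=ClinvarAssertion.BENIGN,
                         clinvar_stars=2)
        d = self._run(v, panel["BRCA1"])
        assert "truncating_with_benign_uncertain_clinvar" in d.reason_codes

    def test_insilico_refuted_by_two_star_uncertain(self, panel):
        v = make_variant(so_consequence="missense_variant",
                         truncation_fraction=None, hgmd_dm=True,
                         clinvar_assertion=ClinvarAssertion.UNCERTAIN,
                         clinvar_stars=2)
        d = self._run(v, panel["BRCA1"], reasons=("hgmd_dm",))
        assert d.reason_codes == ("insilico_retained_with_clinvar_refutation",)

    def test_insilico_one_star_multiple_submissions(self, panel):
        v = make_variant(so_consequence="missense_variant",
                         truncation_fraction=None, cadd_phred=40.0,
                         clinvar_assertion=ClinvarAssertion.UNCERTAIN,
                         clinvar_stars=1, clinvar_submission_count=3)
        d = self._run(v, panel["BRCA1"], reasons=("cadd_above_threshold",))
        assert d.outcome is Outcome.EXCLUDED

    def test_conflicting_counts_as_uncertain(self, panel):
        v = make_variant(clinvar_assertion=ClinvarAssertion.CONFLICTING,
                         clinvar_stars=2)
        d = self._run(v, panel["BRCA1"])
        assert "truncating_with_benign_uncertain_clinvar" in d.reason_codes


class TestPipeline:
    def test_empty_input(self, panel):
        res = run_snv_pipeline([], panel)
        assert res.retained == []
        assert res.audit["input"] == 0

    def test_conservation(self, panel):
        variants = [
            make_variant(position=10_050 + i, individual_id=f"P{i:04d}",
                         gq=float(20 + i))
            for i in range(20)
        ]
        res = run_snv_pipeline(variants, panel)
        assert res.audit["input"] == sum(
            res.audit[k] for k in ("quality_fail", "frequency_fail",
                                   "not_retained", "excluded",
                                   "retained_for_assessment")
        )

    def test_order_invariance(self, panel):
        variants = [
            make_variant(position=10_050 + i, gq=float(25 + i),
                         individual_id=f"P{i % 3:04d}")
            for i in range(15)
        ]
        res1 = run_snv_pipeline(variants, panel)
        shuffled = list(variants)
        random.Random(3).shuffle(shuffled)
        res2 = run_snv_pipeline(shuffled, panel)
        assert res1.retained == res2.retained
        assert res1.dispositions == res2.dispositions

    def test_duplicate_records_deduplicated_with_warning(self, panel):
        v = make_variant()
        with pytest.warns(UserWarning, match="duplicate"):
            res = run_snv_pipeline([v, v], panel)
        assert res.audit["input"] == 1
        assert len(res.duplicates) == 1

    def test_unknown_gene_quarantined(self, panel):
        v = make_variant(gene_symbol="NOT_A_GENE")
        res = run_snv_pipeline([v], panel)
        assert res.audit["input"] == 0
        assert len(res.quarantined) == 1

    def test_compound_het_in_recessive_gene_retained(self, panel):
        gene = panel["MUTYH"]
        contig, s, _ = gene.exons[0]
        pair = [
            make_variant(contig=contig, position=s + 5, gene_symbol="MUTYH"),
            make_variant(contig=contig, position=s + 50, gene_symbol="MUTYH"),
        ]
        res = run_snv_pipeline(pair, panel)
        assert len(res.retained) == 2
        # remove one: the survivor is now excluded by the recessive rule
        res_single = run_snv_pipeline(pair[:1], panel)
        assert res_single.retained == []
        assert res_single.audit["excluded"] == 1
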