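"""Boundary behaviour of every quality/depth/VAF/control prefilter."""

import pytest

from ptascrub import variants as V
from ptascrub.config import PipelineConfig
from ptascrub.prefilter import apply_prefilters
from ptascrub.variants import Genotype, SampleCall
from tests.conftest import make_variant


def run_one(variant, coverage_class="30x", controls=("BULK",), **cfg_over):
    cfg = PipelineConfig(coverage_class=coverage_class).replace(**cfg_over)
    if controls and "BULK" in controls and "BULK" not in variant.samples:
        variant.samples["BULK"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
    apply_prefilters([variant], "S1", control_samples=list(controls), config=cfg)
    return variant.filter_flags


class TestQualityThresholds:
    def test_qual_100_inclusive(self):
        assert V.FAIL_QUAL in run_one(make_variant(qual=99.0))
        assert V.FAIL_QUAL not in run_one(make_variant(qual=100.0))

    def test_mq_55_strict(self):
        assert V.FAIL_MQ in run_one(make_variant(mq=55.0))
        assert V.FAIL_MQ not in run_one(make_variant(mq=55.01))

    def test_preexisting_filter_verdict_honored(self):
        v = make_variant()
        v.input_filters = ("SNP_StrandBias",)
        assert V.FAIL_QUAL in run_one(v)


class TestDepthAndVaf:
    def test_depth_by_coverage_class(self):
        v = make_variant(ref_depth=5, alt_depth=4)  # total 9
        assert V.FAIL_DEPTH in run_one(v, "30x")
        v2 = make_variant(ref_depth=5, alt_depth=4)
        assert V.FAIL_DEPTH not in run_one(v2, "15x")

    def test_control_depth_also_counts(self):
        v = make_variant(ref_depth=20, alt_depth=10)
        v.samples["BULK"] = SampleCall(5, 0, 99, Genotype.HOM_REF)  # depth 5 < 10
        assert V.FAIL_DEPTH in run_one(v, "30x")

    def test_snv_vaf_15x_boundary(self):
        assert V.FAIL_VAF in run_one(make_variant(ref_depth=81, alt_depth=19), "15x")
        assert V.FAIL_VAF not in run_one(make_variant(ref_depth=80, alt_depth=20), "15x")

    def test_snv_vaf_30x_boundary(self):
        assert V.FAIL_VAF in run_one(make_variant(ref_depth=71, alt_depth=29), "30x")
        assert V.FAIL_VAF not in run_one(make_variant(ref_depth=70, alt_depth=30), "30x")

    def test_indel_vaf_quarter(self):
        bad = make_variant(ref="A", alt="AT", ref_depth=76, alt_depth=24)
        assert V.FAIL_VAF in run_one(bad)
        good = make_variant(ref="A", alt="AT", ref_depth=75, alt_depth=25)
        assert V.FAIL_VAF not in run_one(good)


class TestGenotypeQuality:
    def test_het_snv_gq_99(self):
        assert V.FAIL_GQ in run_one(make_variant(gq=98))
        assert V.FAIL_GQ not in run_one(make_variant(gq=99))

    def test_hom_alt_snv_gq_10(self):
        v = make_variant(gq=10, genotype=Genotype.HOM_ALT, ref_depth=0, alt_depth=30)
        assert V.FAIL_GQ not in run_one(v)
        v2 = make_variant(gq=9, genotype=Genotype.HOM_ALT, ref_depth=0, alt_depth=30)
        assert V.FAIL_GQ in run_one(v2)

    def test_indel_gq_in_both_samples(self):
        v = make_variant(ref="A", alt="AT", gq=99)
        v.samples["BULK"] = SampleCall(25, 0, 98, Genotype.HOM_REF)
        assert V.FAIL_GQ in run_one(v)


class TestControlAndPon:
    def test_any_alt_read_in_control_is_evidence(self):
        v = make_variant()
        v.samples["BULK"] = SampleCall(24, 1, 99, Genotype.HOM_REF)
        assert V.FAIL_CONTROL_EVIDENCE in run_one(v)

    def test_non_ref_genotype_is_evidence_even_without_reads(self):
        v = make_variant()
        v.samples["BULK"] = SampleCall(None, None, 99, Genotype.HET)
        assert V.FAIL_CONTROL_EVIDENCE in run_one(v)

    def test_pon_match_is_exact_on_key(self):
        v = make_variant(chrom="chr1", pos=100, ref="A", alt="T")
        v.samples["BULK"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
        cfg = PipelineConfig()
        apply_prefilters([v], "S1", control_samples=["BULK"],
                         pon_sites={("1", 100, "A", "T")}, config=cfg)
        assert V.FAIL_PON in v.filter_flags
        v2 = make_variant(chrom="chr1", pos=100, ref="A", alt="G")
        v2.samples["BULK"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
        apply_prefilters([v2], "S1", control_samples=["BULK"],
                         pon_sites={("1", 100, "A", "T")}, config=cfg)
        assert V.FAIL_PON not in v2.filter_flags

    def test_private_variant_mode_rejects_shared_calls(self):
        shared = make_variant()
        shared.samples["S2"] = SampleCall(15, 8, 99, Genotype.HET)
        shared.samples["S3"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
        apply_prefilters([shared], "S1", control_samples=[],
                         private_mode_samples=["S1", "S2", "S3"])
        assert V.FAIL_CONTROL_EVIDENCE in shared.filter_flags

        private = make_variant()
        private.samples["S2"] = SampleCall(20, 0, 99, Genotype.HOM_REF)
        private.samples["S3"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
        apply_prefilters([private], "S1", control_samples=[],
                         private_mode_samples=["S1", "S2", "S3"])
        assert V.FAIL_CONTROL_EVIDENCE not in private.filter_flags

    def test_no_control_and_no_private_mode_is_an_error(self):
        with pytest.raises(ValueError, match="configuration"):
            apply_prefilters([make_variant()], "S1", control_samples=[])


class TestFilterProperties:
    def test_flags_are_cumulative_not_first_hit(self):
        v = make_variant(qual=50, mq=40, ref_depth=3, alt_depth=1, gq=5)
        flags = run_one(v)
        assert {V.FAIL_QUAL, V.FAIL_MQ, V.FAIL_DEPTH, V.FAIL_VAF, V.FAIL_GQ} <= flags

    def test_idempotent_on_pass_output(self):
        variants = [make_variant(pos=p) for p in (100, 200, 300)]
        for v in variants:
            v.samples["BULK"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
        cfg = PipelineConfig()
        apply_prefilters(variants, "S1", control_samples=["BULK"], config=cfg)
        passing = [v for v in variants if v.is_pass]
        before = [set(v.filter_flags) for v in passing]
        apply_prefilters(passing, "S1", control_samples=["BULK"], config=cfg)
        assert [set(v.filter_flags) for v in passing] == before

    def test_raising_thresholds_never_increases_pass_count(self, rng):
        params = [
            dict(
                pos=100 + i,
                qual=float(rng.uniform(50, 300)),
                mq=float(rng.uniform(40, 70)),
                ref_depth=int(rng.integers(0, 30)),
                alt_depth=int(rng.integers(1, 30)),
                gq=int(rng.integers(50, 100)),
            )
            for i in range(60)
        ]

        def batch():
            out = []
            for kw in params:
                v = make_variant(**kw)
                v.samples["BULK"] = SampleCall(25, 0, 99, Genotype.HOM_REF)
                out.append(v)
            return out

        base = batch()
        apply_prefilters(base, "S1", control_samples=["BULK"], config=PipelineConfig())
        n_base = sum(v.is_pass for v in base)
        stricter = batch()
        cfg = PipelineConfig().replace(min_qual=150.0, min_mq=60.0, min_vaf_snv_30x=0.4)
        apply_prefilters(stricter, "S1", control_samples=["BULK"], config=cfg)
        assert sum(v.is_pass for v in stricter) <= n_base
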