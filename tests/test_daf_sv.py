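"""DAF profiles, VAF modes, CN state calls, breakend filtering, integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ptascrub.config import PipelineConfig
from ptascrub.coverage import CoverageSegment
from ptascrub.daf import daf, daf_profile, vaf_modes
from ptascrub.svcalls import (
    Breakend,
    BreakendCall,
    build_breakend_pon,
    call_cn_segments,
    filter_breakends,
    integrate_svs,
    pair_breakends,
    parse_bnd_alt,
)


class TestDaf:
    @pytest.mark.parametrize("vaf,expected", [(0.5, 0.0), (1.0, 0.5), (0.0, 0.5), (0.3, 0.2)])
    def test_definition(self, vaf, expected):
        assert daf(vaf) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_bounds(self, vafs):
        d = daf(vafs)
        assert np.all((d >= 0) & (d <= 0.5))

    def test_shrinking_vafs_toward_half_never_raises_daf(self, rng):
        vafs = rng.uniform(0, 1, 200)
        for lam in (1.0, 0.7, 0.4, 0.0):
            shrunk = 0.5 + lam * (vafs - 0.5)
            assert daf(shrunk).mean() <= daf(vafs).mean() + 1e-12


class TestVafModes:
    def test_diploid_hets_single_mode_near_half(self, rng):
        vafs = rng.binomial(30, 0.5, 500) / 30
        modes = vaf_modes(vafs)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(0.5, abs=0.05)

    def test_trisomic_hets_two_modes_near_thirds(self, rng):
        p = np.where(rng.random(500) < 0.5, 1 / 3, 2 / 3)
        vafs = rng.binomial(30, p) / 30
        modes = vaf_modes(vafs)
        assert len(modes) == 2
        assert abs(modes[0] - 1 / 3) <= 0.12
        assert abs(modes[1] - 2 / 3) <= 0.12

    def test_degenerate_identical_vafs(self):
        assert vaf_modes(np.full(50, 0.4)) == [0.4]

    def test_too_few_hets_undetermined(self):
        assert vaf_modes(np.full(5, 0.5)) == []


def _hets_df(rng, length=2_000_000, state="neutral", chrom="1"):
    pos = np.sort(rng.choice(np.arange(1, length), 1500, replace=False))
    if state == "neutral":
        p = np.full(len(pos), 0.5)
    elif state == "gain":
        p = np.where(rng.random(len(pos)) < 0.5, 1 / 3, 2 / 3)
    else:  # loss-like / LOH
        p = np.where(rng.random(len(pos)) < 0.5, 0.02, 0.98)
    vaf = rng.binomial(30, p) / 30
    return pd.DataFrame({"chrom": chrom, "pos": pos, "vaf": vaf})


class TestStateCalls:
    def _cov_seg(self, direction, mean_cn, candidate=True):
        return CoverageSegment("1", 0, 2_000_000, mean_cn=mean_cn, n_bins=2000,
                               sample_p=0.001 if candidate else 0.5,
                               pon_p=0.01 if candidate else 0.5,
                               direction=direction, is_candidate=candidate)

    def test_loss_needs_coverage_and_daf(self, rng):
        prof = daf_profile(_hets_df(rng, state="loss"))
        calls = call_cn_segments([self._cov_seg(-1, 1.0)], prof)
        assert calls[0].state == "loss"
        assert calls[0].evidence == {"coverage", "daf"}

    def test_gain_needs_modes_and_elevated_daf(self, rng):
        hets = pd.concat([
            _hets_df(rng, state="gain"),
            _hets_df(rng, state="neutral").assign(pos=lambda d: d.pos + 2_000_000),
        ])
        prof = daf_profile(hets)
        calls = call_cn_segments([self._cov_seg(+1, 3.0)], prof)
        gain = [c for c in calls if c.start == 0][0]
        assert gain.state == "gain"
        assert len(gain.vaf_mode_list) >= 2

    def test_coverage_loss_without_daf_support_not_called(self, rng):
        prof = daf_profile(_hets_df(rng, state="neutral"))
        calls = call_cn_segments([self._cov_seg(-1, 1.0)], prof)
        assert calls[0].state != "loss"

    def test_cnloh_high_daf_without_coverage_change(self, rng):
        hets = pd.concat([
            _hets_df(rng, state="loss"),  # LOH-looking VAFs
            _hets_df(rng, state="neutral").assign(pos=lambda d: d.pos + 2_000_000),
        ])
        prof = daf_profile(hets)
        neutral_cov = self._cov_seg(0, 2.0, candidate=False)
        neutral_cov.end = 4_000_000
        calls = call_cn_segments([neutral_cov], prof)
        states = {c.state for c in calls}
        assert "cnLOH" in states
        cnloh = [c for c in calls if c.state == "cnLOH"][0]
        assert cnloh.end <= 2_100_000  # confined to the high-DAF region


class TestBreakends:
    @pytest.mark.parametrize(
        "alt,expected",
        [
            ("A[2:321[", ("2", 321, "+")),
            ("A]2:321]", ("2", 321, "+")),
            ("]2:321]A", ("2", 321, "-")),
            ("[2:321[A", ("2", 321, "-")),
        ],
    )
    def test_alt_parsing(self, alt, expected):
        assert parse_bnd_alt(alt) == expected

    def _pair(self, chrom_a, pos_a, o_a, chrom_b, pos_b, o_b):
        alt_a = f"A[{chrom_b}:{pos_b}[" if o_a == "+" else f"]{chrom_b}:{pos_b}]A"
        return [
            Breakend("bnd1", chrom_a, pos_a, "bnd2", chrom_b, pos_b, o_a),
            Breakend("bnd2", chrom_b, pos_b, "bnd1", chrom_a, pos_a, o_b),
        ]

    @pytest.mark.parametrize(
        "o_a,o_b,expected",
        [("+", "-", "DEL"), ("-", "+", "DUP"), ("+", "+", "INV"), ("-", "-", "INV")],
    )
    def test_intrachromosomal_classification(self, o_a, o_b, expected):
        calls = pair_breakends(self._pair("1", 1000, o_a, "1", 51_000, o_b))
        assert len(calls) == 1
        assert calls[0].sv_class == expected
        assert calls[0].size == 50_000

    def test_interchromosomal_is_ctx(self):
        calls = pair_breakends(self._pair("1", 1000, "+", "2", 9000, "-"))
        assert calls[0].sv_class == "CTX"

    def test_missing_mate_flagged_not_fatal(self):
        lone = Breakend("b1", "1", 1000, "absent", "2", 500, "+")
        calls = pair_breakends([lone])
        assert calls[0].mate_missing
        filter_breakends(calls)
        assert "MATE_MISSING" in calls[0].filter_flags


class TestBreakendFilters:
    def _call(self, sv_class, size=50_000, daf_val=0.45, cn=None, junctions=2):
        cn = cn if cn is not None else (3.0 if sv_class == "DUP" else 1.0)
        call = BreakendCall("1", 1_000_000, "1", 1_000_000 + size, sv_class, size,
                            junction_count=junctions)
        call.local_daf = daf_val
        call.local_cn = cn
        return call

    def _run(self, call, cnvs=None, **cfg_over):
        cfg = PipelineConfig().replace(**cfg_over) if cfg_over else PipelineConfig()
        # local stats are pre-set; pass no profile so they are kept
        filter_breakends([call], cnv_segments=cnvs, config=cfg)
        return call

    def test_dup_daf_boundary(self):
        assert "LOW_DAF" in self._run(self._call("DUP", daf_val=0.17)).filter_flags
        assert self._run(self._call("DUP", daf_val=0.18)).is_pass

    def test_dup_ratio_boundary(self):
        assert "LOW_RATIO" in self._run(self._call("DUP", cn=2.4)).filter_flags
        assert self._run(self._call("DUP", cn=2.5)).is_pass

    def test_del_daf_boundary(self):
        assert "LOW_DAF" in self._run(self._call("DEL", daf_val=0.39)).filter_flags
        assert self._run(self._call("DEL", daf_val=0.40)).is_pass

    def test_del_ratio_boundary(self):
        assert "HIGH_RATIO" in self._run(self._call("DEL", cn=1.6)).filter_flags
        assert self._run(self._call("DEL", cn=1.5)).is_pass

    def test_inversion_size_and_junctions(self):
        assert "TOO_SMALL" in self._run(self._call("INV", size=800)).filter_flags
        assert self._run(self._call("INV", size=1000)).is_pass
        assert "SINGLE_JUNCTION" in self._run(
            self._call("INV", junctions=1)
        ).filter_flags

    def test_single_junction_translocation_rescued_near_cnv(self):
        from ptascrub.svcalls import Segment

        ctx = BreakendCall("1", 1_050_000, "2", 9_000_000, "CTX", None, junction_count=1)
        lost = Segment("1", 1_100_000, 2_000_000, state="loss")
        assert self._run(ctx, cnvs=[lost]).is_pass  # 50 kb from a called CNV
        ctx2 = BreakendCall("1", 1_050_000, "2", 9_000_000, "CTX", None, junction_count=1)
        far = Segment("1", 5_000_000, 6_000_000, state="loss")
        assert "SINGLE_JUNCTION" in self._run(ctx2, cnvs=[far]).filter_flags

    def test_high_coverage_excluded_only_at_15x(self):
        from tests.test_coverage import grid_df
        from ptascrub.coverage import CoveragePON, normalize_coverage

        counts = np.full(3000, 50.0)
        counts[1000] = 140.0
        pon = CoveragePON.build([grid_df(np.full(3000, 50.0))] * 2)
        profile = normalize_coverage(grid_df(counts), pon)
        for cls, expect_flag in (("15x", True), ("30x", False)):
            call = BreakendCall("1", 1_000_500, "1", 1_040_000, "DEL", 39_500)
            call.local_daf, call.local_cn = 0.45, 1.0
            cfg = PipelineConfig(coverage_class=cls)
            filter_breakends([call], profile=profile, config=cfg)
            assert ("HIGH_COVERAGE" in call.filter_flags) is expect_flag

    def test_filtering_is_idempotent(self):
        call = self._call("DUP", daf_val=0.1, cn=1.0)
        self._run(call)
        flags = set(call.filter_flags)
        self._run(call)
        assert call.filter_flags == flags


class TestIntegration:
    def test_cnv_emitted_without_breakend_support(self):
        from ptascrub.svcalls import Segment

        loss = Segment("1", 0, 1_000_000, state="loss", evidence={"coverage", "daf"})
        final = integrate_svs([loss], [])
        assert len(final) == 1
        assert final[0]["type"] == "loss"
        assert "breakend" not in final[0]["evidence"]

    def test_balanced_sv_from_breakends_only(self):
        inv = BreakendCall("1", 10_000, "1", 60_000, "INV", 50_000, junction_count=2)
        inv.evidence = {"breakend"}
        final = integrate_svs([], [inv])
        assert final[0]["type"] == "INV"

    def test_duplicate_representation_merged(self):
        from ptascrub.svcalls import Segment

        loss = Segment("1", 100_000, 900_000, state="loss", evidence={"coverage", "daf"})
        matching_del = BreakendCall("1", 100_500, "1", 899_000, "DEL", 798_500)
        matching_del.evidence = {"breakend"}
        final = integrate_svs([loss], [matching_del])
        assert len(final) == 1
        assert final[0]["evidence"] == {"coverage", "daf", "breakend"}

    def test_breakend_pon_requires_two_individuals(self):
        pon = build_breakend_pon({
            "I1": [("1", 10_000), ("1", 50_000)],
            "I2": [("1", 10_500)],
        })
        assert len(pon.overlapping("1", 9_999, 10_001)) > 0   # recurrent
        assert len(pon.overlapping("1", 49_000, 51_000)) == 0  # single individual
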