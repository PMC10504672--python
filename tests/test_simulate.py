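"""The synthetic-data generator: declared marginals and determinism."""

import numpy as np
import pytest

from ptascrub.simulate import (
    simulate_candidates,
    simulate_coverage_daf,
    simulate_phased_hets,
    simulate_reference,
    write_bin_counts,
    write_phased_vcf,
)


class TestPhasedHets:
    def test_balanced_profile_marginals(self):
        series, records, _ = simulate_phased_hets(
            region_length=10_000, het_density=1 / 1000, mean_depth=30, seed=1
        )
        assert 3 <= len(series) <= 25  # ~10 expected at Poisson spacing
        big_series, _, _ = simulate_phased_hets(
            region_length=2_000_000, het_density=1 / 1000, mean_depth=30, seed=1
        )
        mean_baf = big_series.oriented_baf.mean()
        se = 0.5 / np.sqrt(len(big_series) * 30)
        assert abs(mean_baf - 0.5) < 3 * max(se, 0.01)

    def test_imbalanced_profile_shifts_oriented_baf(self):
        series, _, _ = simulate_phased_hets(
            region_length=500_000, het_density=1 / 1000, mean_depth=40,
            imbalance_profile=lambda pos: np.full(len(np.atleast_1d(pos)), 0.8),
            seed=2,
        )
        assert abs(series.oriented_baf.mean() - 0.8) < 0.03

    def test_same_seed_byte_identical_output(self, tmp_path):
        for name in ("a.vcf", "b.vcf"):
            _, records, _ = simulate_phased_hets(100_000, 1 / 1000, 30, seed=9)
            write_phased_vcf(records, tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_round_trip_through_vcf_reader(self, tmp_path):
        from ptascrub.io import read_phased_hets

        _, records, _ = simulate_phased_hets(200_000, 1 / 1000, 30, seed=3)
        path = tmp_path / "phased.vcf"
        write_phased_vcf(records, path)
        back = read_phased_hets(path, "SIM")
        kept = [r for r in records if r["alt_depth"] + r["ref_depth"] > 0
                and 0 < r["alt_depth"] < r["alt_depth"] + r["ref_depth"]]
        assert len(back) == len(kept)
        assert [(r["pos"], r["hap"]) for r in back] == [(r["pos"], r["hap"]) for r in kept]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_phased_hets(1000, 0.0, 30)
        with pytest.raises(ValueError):
            simulate_phased_hets(1000, 0.001, 0.5)


class TestCandidates:
    def test_all_artifact_labels(self):
        _, _, truth = simulate_candidates(0, 50, seed=0)
        assert (truth.labels == "artifact").all()

    def test_depth_and_vaf_threshold_separates_at_high_separation(self):
        variants, _, truth = simulate_candidates(100, 100, 1.0, seed=1)
        vafs = np.array([v.call("SIM").vaf for v in variants])
        labels = truth.labels == "true_somatic"
        best = max(np.mean((vafs >= t) == labels) for t in np.linspace(0, 1, 101))
        assert best > 0.8

    def test_zero_separation_is_chance_level(self):
        variants, _, truth = simulate_candidates(300, 300, 0.0, seed=2)
        vafs = np.array([v.call("SIM").vaf for v in variants])
        labels = truth.labels == "true_somatic"
        best = max(
            max(np.mean((vafs >= t) == labels), np.mean((vafs < t) == labels))
            for t in np.linspace(0, 1, 101)
        )
        assert best < 0.60  # indistinguishable up to sampling noise

    def test_true_somatic_vaf_marginal(self):
        variants, _, truth = simulate_candidates(400, 0, 1.0, seed=3)
        vafs = np.array([v.call("SIM").vaf for v in variants])
        se = 0.5 / np.sqrt(len(vafs) * 30)
        assert abs(vafs.mean() - 0.5) < 4 * max(se, 0.005)

    def test_determinism(self):
        a = simulate_candidates(50, 50, 1.0, seed=4)
        b = simulate_candidates(50, 50, 1.0, seed=4)
        assert [(v.pos, v.ref, v.alt) for v in a[0]] == [(v.pos, v.ref, v.alt) for v in b[0]]
        assert all(x.context == y.context for x, y in zip(a[1], b[1]))

    def test_truth_never_leaks_into_variant_records(self):
        variants, _, truth = simulate_candidates(50, 50, 1.0, seed=5)
        for v in variants:
            assert "label" not in v.info
            assert v.filter_flags == set()


class TestCoverageDaf:
    SEGS = [(0, 2_000_000, "neutral"), (2_000_000, 3_000_000, "gain"),
            (3_000_000, 4_000_000, "cnLOH"), (4_000_000, 5_000_000, "neutral")]

    def test_neutral_profile_normalizes_to_unit_ratio(self):
        from ptascrub.coverage import CoveragePON, normalize_coverage

        data = simulate_coverage_daf([(0, 5_000_000, "neutral")], seed=1)
        pon = CoveragePON.build(data["pon_tables"])
        profile = normalize_coverage(data["sample_counts"], pon)
        coarse = profile.coarse_bins()
        assert np.allclose(coarse["median_cn"], 2.0, atol=0.2)
        assert abs(coarse["median_cn"].mean() - 2.0) < 0.05

    def test_cn3_segment_vafs_cluster_at_thirds(self):
        data = simulate_coverage_daf(self.SEGS, seed=2)
        hets = data["hets"]
        gain = hets[(hets["pos"] > 2_000_000) & (hets["pos"] <= 3_000_000)]
        low = (gain["vaf"] - 1 / 3).abs() < 0.15
        high = (gain["vaf"] - 2 / 3).abs() < 0.15
        assert (low | high).mean() > 0.9
        assert 0.3 < low.mean() < 0.7

    def test_cnloh_has_unit_coverage_but_high_daf(self):
        data = simulate_coverage_daf(self.SEGS, seed=3)
        counts = data["sample_counts"]
        loh = counts[(counts["start"] >= 3_000_000) & (counts["end"] <= 4_000_000)]
        neutral = counts[counts["end"] <= 2_000_000]
        assert abs(loh["count"].mean() / neutral["count"].mean() - 1.0) < 0.05
        hets = data["hets"]
        loh_hets = hets[(hets["pos"] > 3_000_000) & (hets["pos"] <= 4_000_000)]
        assert (loh_hets["vaf"] - 0.5).abs().mean() > 0.45

    def test_tiling_validation(self):
        with pytest.raises(ValueError, match="tile"):
            simulate_coverage_daf([(0, 1000_000, "neutral"), (2_000_000, 3_000_000, "loss")])

    def test_deterministic_files(self, tmp_path):
        for name in ("a.tsv", "b.tsv"):
            data = simulate_coverage_daf(self.SEGS, seed=4)
            write_bin_counts(data["sample_counts"], tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestReference:
    def test_fasta_round_trip(self, tmp_path):
        from ptascrub.annotations import FastaReference
        from ptascrub.simulate import write_fasta

        ref = simulate_reference(5000, seed=1)
        write_fasta(ref, tmp_path / "ref.fa")
        back = FastaReference(tmp_path / "ref.fa")
        assert back.fetch("1", 100, 150) == ref.fetch("1", 100, 150)
        assert back.length("1") == 5000
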