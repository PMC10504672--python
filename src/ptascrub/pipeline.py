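"""End-to-end orchestration of the filtering stages.

The library modules are independently usable; this module wires them into
the three workflows a user runs: base-substitution classification, indel
filtering, and structural-variant calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptascrub import variants as V
from ptascrub.annotations import AnnotationSet
from ptascrub.classifier import RFBundle, artifact_probabilities
from ptascrub.config import PipelineConfig
from ptascrub.coverage import (
    CoveragePON,
    coverage_segment_tests,
    coverage_segments,
    normalize_coverage,
)
from ptascrub.cutoffs import (
    CutoffResult,
    apply_cutoff,
    cosine_based_cutoff,
    final_cutoff,
    pr_based_cutoff,
)
from ptascrub.daf import daf_profile
from ptascrub.features import FeatureVector, extract_features
from ptascrub.imbalance import assess_candidate, orient_hets
from ptascrub.linkage import LinkageCategory, assess_linkage, classify_linkage
from ptascrub.prefilter import apply_prefilters
from ptascrub.svcalls import (
    Segment,
    call_cn_segments,
    filter_breakends,
    integrate_svs,
    pair_breakends,
)
from ptascrub.variants import CandidateVariant, VarType


@dataclass
class SnvResult:
    variants: list[CandidateVariant]
    candidates: list[CandidateVariant]
    probabilities: np.ndarray
    cutoff: CutoffResult
    categories: list[LinkageCategory]

    @property
    def n_pass(self) -> int:
        return sum(1 for v in self.candidates if v.is_pass)

    @property
    def n_fail(self) -> int:
        return len(self.candidates) - self.n_pass


def classify_snvs(
    variants: list[CandidateVariant],
    test_sample: str,
    bundle: RFBundle,
    control_samples: list[str] | None = None,
    phased_records: list[dict] | None = None,
    annotations: AnnotationSet | None = None,
    feature_vectors: list[FeatureVector] | None = None,
    substitutions: list[tuple] | None = None,
    read_evidence: dict | None = None,
    pon_sites: set | None = None,
    config: PipelineConfig | None = None,
    private_mode_samples: list[str] | None = None,
    manual_cutoff: float | None = None,
) -> SnvResult:
    """Prefilter, score, calibrate a cutoff, and flag base substitutions.

    ``feature_vectors``/``substitutions`` may be supplied directly (e.g.
    from the simulator); otherwise they are derived from ``annotations``
    and the allelic-imbalance / phased-het inputs.
    """
    cfg = config or PipelineConfig()
    apply_prefilters(
        variants, test_sample,
        control_samples=control_samples,
        pon_sites=pon_sites, config=cfg,
        private_mode_samples=private_mode_samples,
    )
    candidates = [v for v in variants if v.var_type is VarType.SNV and v.is_pass]
    if not candidates:
        raise ValueError("no candidate SNVs survive the prefilters")

    series_by_chrom = {}
    if phased_records:
        by_chrom: dict[str, list[dict]] = {}
        for r in phased_records:
            by_chrom.setdefault(V.normalize_chrom(r["chrom"]), []).append(r)
        series_by_chrom = {c: orient_hets(rs) for c, rs in by_chrom.items()}

    if feature_vectors is None:
        if annotations is None:
            raise ValueError("annotations are required when feature vectors are not supplied")
        feature_vectors = []
        for v in candidates:
            ai = None
            series = series_by_chrom.get(V.normalize_chrom(v.chrom))
            call = v.call(test_sample)
            if series is not None and call.total_depth:
                ai = assess_candidate(series, v.pos, call.alt_depth, call.total_depth, cfg)
                v.ai_log_p = ai.log_p if ai.defined else None
            feature_vectors.append(extract_features(v, annotations, ai, cfg.rf_distance_cap))
    if len(feature_vectors) != len(candidates):
        raise ValueError("feature vectors must align with the surviving candidates")

    if read_evidence is not None:
        for v in candidates:
            obs = read_evidence.get(f"{V.normalize_chrom(v.chrom)}:{v.pos}")
            if obs:
                v.linkage_score = assess_linkage(obs, cfg).phred_score
    categories = [
        classify_linkage(v.linkage_score, cfg.linkage_false_max, cfg.linkage_true_min)
        for v in candidates
    ]

    probabilities = artifact_probabilities(bundle, feature_vectors)

    if substitutions is None:
        if annotations is None:
            raise ValueError("annotations are required when substitutions are not supplied")
        substitutions = []
        for v in candidates:
            ctx = annotations.context(v.chrom, v.pos, flank=1)
            substitutions.append((v.ref, v.alt, ctx[0], ctx[2]))

    if manual_cutoff is not None:
        cutoff = CutoffResult(None, 0.0, None, float(manual_cutoff), "manual")
    else:
        pr = pr_based_cutoff(categories, probabilities)
        cosine = cosine_based_cutoff(substitutions, probabilities, cfg)
        cutoff = final_cutoff(pr, cosine, cfg)
    apply_cutoff(candidates, probabilities, cutoff.final_cutoff)

    return SnvResult(
        variants=variants,
        candidates=candidates,
        probabilities=probabilities,
        cutoff=cutoff,
        categories=categories,
    )


@dataclass
class SvResult:
    profile: object
    daf: object
    segments: list[Segment] = field(default_factory=list)
    breakend_calls: list = field(default_factory=list)
    final_calls: list[dict] = field(default_factory=list)


def call_svs(
    sample_counts: pd.DataFrame,
    pon_tables: list[pd.DataFrame],
    hets: pd.DataFrame,
    breakends: list | None = None,
    breakend_pon=None,
    centromeres=None,
    config: PipelineConfig | None = None,
) -> SvResult:
    """Coverage + DAF copy-number calling and breakend filtering/integration."""
    cfg = config or PipelineConfig()
    pon = CoveragePON.build(pon_tables, cfg.pon_outlier_quantile)
    profile = normalize_coverage(sample_counts, pon, centromeres, cfg)
    cov_segs = coverage_segments(profile, cfg)
    coverage_segment_tests(cov_segs, profile, pon, cfg)
    daf_prof = daf_profile(hets[["chrom", "pos", "vaf"]], cfg)
    segments = call_cn_segments(cov_segs, daf_prof, cfg)

    calls = []
    if breakends:
        calls = pair_breakends(breakends)
        filter_breakends(calls, breakend_pon, profile, daf_prof, segments, cfg)
    final = integrate_svs(segments, calls)
    return SvResult(
        profile=profile, daf=daf_prof, segments=segments,
        breakend_calls=calls, final_calls=final,
    )


def segments_to_bed(segments: list[Segment], path) -> None:
    rows = [
        {
            "chrom": s.chrom, "start": s.start, "end": s.end, "state": s.state,
            "mean_cn": "" if s.mean_cn is None else round(s.mean_cn, 4),
            "mean_daf": "" if s.mean_daf is None or not np.isfinite(s.mean_daf)
            else round(s.mean_daf, 4),
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
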