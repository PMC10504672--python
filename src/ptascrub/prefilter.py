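"""SMuRF-style quality, depth, VAF, control and panel-of-normals prefilters.

These define the candidate somatic set: a variant is candidate-somatic iff
its flag set is empty after this stage.  All failures are recorded
cumulatively, not first-hit.

Thresholds (inclusive/strict exactly as configured by default): QUAL ≥ 100; depth ≥ 10
(~30x class) or ≥ 5 (~15x class) in the test and each control sample;
MQ > 55; het/hom-alt SNV GQ ≥ 99/≥ 10; SNV VAF ≥ 0.2 (15x) or ≥ 0.3 (30x);
indel VAF ≥ 0.25 and GQ ≥ 99 in both test and control; no evidence in any
control; absence from the panel of normals.
"""

from __future__ import annotations

from ptascrub import variants as V
from ptascrub.config import PipelineConfig
from ptascrub.variants import CandidateVariant, Genotype, VarType


def _depth_of(call) -> int | None:
    """AD-sum depth with DP unavailable here; missing fields stay missing."""
    return call.total_depth


def _control_has_evidence(call) -> bool:
    """Strictest reading: any alt read or a non-hom-ref genotype is evidence."""
    if call.alt_depth is not None and call.alt_depth > 0:
        return True
    return call.genotype in (Genotype.HET, Genotype.HOM_ALT)


def apply_prefilters(
    variants: list[CandidateVariant],
    test_sample: str,
    control_samples: list[str] | None = None,
    pon_sites: set[tuple[str, int, str, str]] | None = None,
    config: PipelineConfig | None = None,
    private_mode_samples: list[str] | None = None,
) -> list[CandidateVariant]:
    """Flag every variant against every prefilter; returns the same objects.

    ``control_samples`` names dedicated germline controls.  When no control
    exists, ``private_mode_samples`` selects the leave-one-out mode: a
    variant is rejected when any *other* sample of the individual shows
    evidence for it (only variants private to the test sample survive).
    """
    cfg = config or PipelineConfig()
    controls = list(control_samples or [])
    pon = pon_sites or set()
    others = [s for s in (private_mode_samples or []) if s != test_sample]
    if not controls and not others:
        raise ValueError(
            "configuration error: name control samples or supply "
            "private_mode_samples for the no-control mode"
        )

    for v in variants:
        flags = v.filter_flags
        test = v.samples[test_sample]
        is_snv = v.var_type is VarType.SNV

        # pre-existing hard-filter verdicts from the input VCF are honored
        if v.input_filters:
            flags.add(V.FAIL_QUAL)
        if v.site_quality is None or v.site_quality < cfg.min_qual:
            flags.add(V.FAIL_QUAL)
        if v.mapping_quality is None or not v.mapping_quality > cfg.min_mq:
            flags.add(V.FAIL_MQ)

        depth_samples = [test] + [v.samples[c] for c in controls if c in v.samples]
        for call in depth_samples:
            d = _depth_of(call)
            if d is None or d < cfg.min_depth:
                flags.add(V.FAIL_DEPTH)
                break

        # control evidence / private-variant mode
        for c in controls:
            if c in v.samples and _control_has_evidence(v.samples[c]):
                flags.add(V.FAIL_CONTROL_EVIDENCE)
                break
        else:
            if others:
                n_with_evidence = sum(
                    1 for s in others
                    if s in v.samples and _control_has_evidence(v.samples[s])
                )
                if n_with_evidence >= 1:  # shared by >= 2 samples incl. the test
                    flags.add(V.FAIL_CONTROL_EVIDENCE)

        if v.key() in pon:
            flags.add(V.FAIL_PON)

        gq = test.genotype_quality
        if is_snv:
            if test.genotype is Genotype.HET and (gq is None or gq < cfg.min_gq_het):
                flags.add(V.FAIL_GQ)
            elif test.genotype is Genotype.HOM_ALT and (gq is None or gq < cfg.min_gq_hom):
                flags.add(V.FAIL_GQ)
        else:
            gq_calls = [test] + [v.samples[c] for c in controls if c in v.samples]
            for call in gq_calls:
                cgq = call.genotype_quality
                if cgq is None or cgq < cfg.min_gq_indel:
                    flags.add(V.FAIL_GQ)
                    break

        vaf = test.vaf
        min_vaf = cfg.min_vaf_snv if is_snv else cfg.min_vaf_indel
        if vaf is None or vaf < min_vaf:
            flags.add(V.FAIL_VAF)

    return variants
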