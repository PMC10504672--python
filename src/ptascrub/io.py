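"""VCF input/output via pysam, plus readers for the small tabular formats.

Multi-allelic rows are split into one :class:`CandidateVariant` per alt
allele so every downstream filter sees a single (ref, alt) pair with its
own allele depths.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from ptascrub.variants import (
    CandidateVariant,
    Genotype,
    SampleCall,
    normalize_chrom,
)

logger = logging.getLogger("ptascrub")

# INFO keys written by the classifier
INFO_PROB = "PTAPROB"
INFO_AI = "AILOGP"
INFO_LINK = "LINKSCORE"


def _genotype_for_alt(gt: tuple | None, alt_index: int) -> Genotype:
    """Genotype of one sample relative to a single alt allele of the row."""
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype.MISSING
    n_alt = sum(a == alt_index for a in alleles)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def _sample_call(rec_sample, alt_index: int) -> SampleCall:
    ad = rec_sample.get("AD")
    ref_depth = alt_depth = None
    if ad is not None and len(ad) > alt_index and ad[0] is not None:
        ref_depth = int(ad[0])
        if ad[alt_index] is not None:
            alt_depth = int(ad[alt_index])
    gq = rec_sample.get("GQ")
    return SampleCall(
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        genotype_quality=float(gq) if gq is not None else None,
        genotype=_genotype_for_alt(rec_sample.get("GT"), alt_index),
    )


def read_variants(
    vcf_path: str | Path,
    test_sample: str | None = None,
    control_samples: list[str] | None = None,
) -> list[CandidateVariant]:
    """Read a multi-sample VCF into split per-alt candidate records.

    Reference-confidence rows (no alt, or only symbolic ``<NON_REF>``) are
    dropped.  Missing per-sample fields stay ``None`` — they are never
    zero-filled.

    Raises
    ------
    ValueError
        If a requested sample is absent from the header (configuration
        error) or a row cannot be parsed (reported with its row number).
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    variants: list[CandidateVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_samples = list(vcf.header.samples)
        wanted = ([test_sample] if test_sample else []) + list(control_samples or [])
        for name in wanted:
            if name not in header_samples:
                raise ValueError(
                    f"sample {name!r} not present in {vcf_path} "
                    f"(header samples: {header_samples})"
                )
        has_mq = "MQ" in vcf.header.info
        for row_number, rec in enumerate(vcf, 1):
            try:
                alts = rec.alts or ()
                filters = tuple(rec.filter.keys())
                if filters == ("PASS",):
                    filters = ()
                for alt_index, alt in enumerate(alts, start=1):
                    if alt is None or alt.startswith("<"):
                        continue  # symbolic / reference-confidence allele
                    samples = {
                        name: _sample_call(rec.samples[name], alt_index)
                        for name in (header_samples if not wanted else wanted)
                    }
                    mq = rec.info.get("MQ") if has_mq else None
                    variants.append(
                        CandidateVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            samples=samples,
                            site_quality=rec.qual,
                            mapping_quality=float(mq) if mq is not None else None,
                            input_filters=filters,
                            info={k: v for k, v in rec.info.items()},
                            id=rec.id,
                        )
                    )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{vcf_path}: cannot parse row {row_number}: {exc}") from exc
    return variants


_GT_OUT = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}

_FLAG_DESCRIPTIONS = {
    "FAIL_CONTROL_EVIDENCE": "Evidence for the variant in a control sample",
    "FAIL_QUAL": "Site quality below threshold or non-PASS in input",
    "FAIL_DEPTH": "Insufficient depth in test or control sample",
    "FAIL_MQ": "Mapping quality below threshold",
    "FAIL_PON": "Present in the panel of normals",
    "FAIL_GQ": "Genotype quality below threshold",
    "FAIL_VAF": "Variant allele fraction below threshold",
    "FAIL_RF": "Artifact probability above the sample-specific cutoff",
    "FAIL_EXCLUSION": "Recurrent indel present in the exclusion list",
    "FAIL_HOMOPOLYMER": "Insertion extending a 5bp+ reference homopolymer",
}


def write_classified_vcf(variants: list[CandidateVariant], destination: str | Path) -> None:
    """Write candidates with their final flag sets to an uncompressed VCF.

    FILTER is ``PASS`` or the semicolon-joined flag names; the artifact
    probability, allelic-imbalance log-p, and linkage score go into INFO.
    """
    header = pysam.VariantHeader()
    for name, desc in _FLAG_DESCRIPTIONS.items():
        header.filters.add(name, None, None, desc)
    header.info.add("MQ", 1, "Float", "Mapping quality")
    header.info.add(INFO_PROB, 1, "Float", "Probability that the variant is a PTA artifact")
    header.info.add(INFO_AI, 1, "Float", "Natural log of the allelic imbalance binomial p-value")
    header.info.add(INFO_LINK, 1, "Float", "Phred-scaled read-backed phasing (linkage) score")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    sample_names: list[str] = []
    for v in variants:
        for name in v.samples:
            if name not in sample_names:
                sample_names.append(name)
    for name in sample_names:
        header.add_sample(name)
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)

    with pysam.VariantFile(str(destination), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.id,
                qual=v.site_quality,
            )
            if v.filter_flags:
                for flag in sorted(v.filter_flags):
                    rec.filter.add(flag)
            else:
                rec.filter.add("PASS")
            if v.mapping_quality is not None:
                rec.info["MQ"] = float(v.mapping_quality)
            if v.artifact_probability is not None:
                rec.info[INFO_PROB] = round(float(v.artifact_probability), 6)
            if v.ai_log_p is not None:
                rec.info[INFO_AI] = round(float(v.ai_log_p), 6)
            if v.linkage_score is not None:
                rec.info[INFO_LINK] = round(float(v.linkage_score), 6)
            for name in sample_names:
                call = v.samples.get(name)
                if call is None:
                    continue
                rec.samples[name]["GT"] = _GT_OUT[call.genotype]
                if call.ref_depth is not None and call.alt_depth is not None:
                    rec.samples[name]["AD"] = (call.ref_depth, call.alt_depth)
                if call.genotype_quality is not None:
                    rec.samples[name]["GQ"] = int(call.genotype_quality)
            out.write(rec)


def read_classified_vcf(path: str | Path) -> list[CandidateVariant]:
    """Round-trip reader for :func:`write_classified_vcf` output."""
    variants = read_variants(path)
    for v in variants:
        v.filter_flags = set(v.input_filters)
        v.input_filters = ()
        if INFO_PROB in v.info:
            v.artifact_probability = float(v.info[INFO_PROB])
        if INFO_AI in v.info:
            v.ai_log_p = float(v.info[INFO_AI])
        if INFO_LINK in v.info:
            v.linkage_score = float(v.info[INFO_LINK])
    return variants


def read_pon_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Panel-of-normals site list from a VCF or a 4-column TSV (chrom,pos,ref,alt)."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return {v.key() for v in read_variants(path)}
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ref", "alt"])
    return {
        (normalize_chrom(str(r.chrom)), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    }


def read_phased_hets(
    vcf_path: str | Path,
    sample: str,
    control_sample: str | None = None,
):
    """Extract phased germline het records from a VCF.

    Returns a list of dicts with the fields the allelic-imbalance module
    consumes: position, dbSNP-style id, haplotype of the alt allele
    (1 for ``0|1``, 2 for ``1|0``), and the ``sample``'s allele depths.
    Heterozygosity is checked in ``control_sample`` (default: ``sample``).
    Unphased or haplotype-less sites are dropped and counted.
    """
    control = control_sample or sample
    records = []
    n_dropped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for name in (sample, control):
            if name not in list(vcf.header.samples):
                raise ValueError(f"sample {name!r} not present in {vcf_path}")
        for rec in vcf:
            if not rec.alts or len(rec.alts) != 1:
                continue
            ctrl_gt = rec.samples[control].get("GT")
            if _genotype_for_alt(ctrl_gt, 1) is not Genotype.HET:
                continue
            if rec.id is None or rec.id == ".":
                continue
            phase_src = rec.samples[control]
            gt = phase_src.get("GT")
            if gt is None or not phase_src.phased or None in gt:
                n_dropped += 1
                continue
            hap = 1 if tuple(gt) == (0, 1) else 2 if tuple(gt) == (1, 0) else None
            if hap is None:
                n_dropped += 1
                continue
            ad = rec.samples[sample].get("AD")
            if ad is None or ad[0] is None or ad[1] is None:
                n_dropped += 1
                continue
            records.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "id": rec.id,
                    "hap": hap,
                    "ref_depth": int(ad[0]),
                    "alt_depth": int(ad[1]),
                }
            )
    if n_dropped:
        logger.warning("read_phased_hets: dropped %d unusable sites", n_dropped)
    return records
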