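"""Shared genomic data model: candidate variants and per-sample calls.

Coordinates are 0-based half-open everywhere inside the package; VCF
parsing and writing converts at the boundary.  ``CandidateVariant.pos`` is
the 1-based VCF position for interoperability; ``start``/``end`` expose the
internal convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class VarType(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    COMPLEX = "complex"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


# filter flag names; a variant is candidate-somatic iff its flag set is empty
FAIL_CONTROL_EVIDENCE = "FAIL_CONTROL_EVIDENCE"
FAIL_QUAL = "FAIL_QUAL"
FAIL_DEPTH = "FAIL_DEPTH"
FAIL_MQ = "FAIL_MQ"
FAIL_PON = "FAIL_PON"
FAIL_GQ = "FAIL_GQ"
FAIL_VAF = "FAIL_VAF"
FAIL_RF = "FAIL_RF"
FAIL_EXCLUSION = "FAIL_EXCLUSION"
FAIL_HOMOPOLYMER = "FAIL_HOMOPOLYMER"


def classify_var_type(ref: str, alt: str) -> VarType:
    """Variant type from REF/ALT lengths (deterministic)."""
    if len(ref) == 1 and len(alt) == 1:
        return VarType.SNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return VarType.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VarType.DELETION
    if len(ref) == len(alt):
        return VarType.COMPLEX
    return VarType.INSERTION if len(alt) > len(ref) else VarType.DELETION


@dataclass
class SampleCall:
    """One sample's genotype record at a site.

    ``ref_depth``/``alt_depth`` are the AD entries for the reference and the
    single alt allele of the (split) record; ``None`` means the field was
    missing in the VCF, which is distinct from zero.
    """

    ref_depth: int | None = None
    alt_depth: int | None = None
    genotype_quality: float | None = None
    genotype: Genotype = Genotype.MISSING

    @property
    def total_depth(self) -> int | None:
        if self.ref_depth is None or self.alt_depth is None:
            return None
        return self.ref_depth + self.alt_depth

    @property
    def vaf(self) -> float | None:
        total = self.total_depth
        if total is None or total == 0:
            return None
        return self.alt_depth / total


@dataclass
class CandidateVariant:
    """One candidate somatic call (one alt allele of one VCF row)."""

    chrom: str
    pos: int                      # 1-based, as printed in the VCF
    ref: str
    alt: str
    samples: dict[str, SampleCall] = field(default_factory=dict)
    site_quality: float | None = None
    mapping_quality: float | None = None
    filter_flags: set[str] = field(default_factory=set)
    input_filters: tuple[str, ...] = ()   # non-PASS FILTER values from the input VCF
    info: dict = field(default_factory=dict)
    id: str | None = None

    # annotations attached downstream
    artifact_probability: float | None = None
    ai_log_p: float | None = None
    linkage_score: float | None = None

    @property
    def var_type(self) -> VarType:
        return classify_var_type(self.ref, self.alt)

    @property
    def start(self) -> int:
        """0-based start of the reference allele."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the reference allele."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags

    def call(self, sample: str) -> SampleCall:
        return self.samples[sample]

    def key(self) -> tuple[str, int, str, str]:
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)


def normalize_chrom(chrom: str) -> str:
    """Strip a "chr" prefix for matching; the original name is kept for output."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom
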