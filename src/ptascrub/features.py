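"""The 26-feature representation of a candidate base substitution.

Feature families and their counts:

* allelic-imbalance log p-value (1, may be undefined)
* mutation type on the pyrimidine strand (1, six classes)
* sequence context, 10 bp up- and downstream of the variant (20 categorical
  base features, positions −10..−1 and +1..+10)
* distance to the nearest gene (1; 0 inside a gene)
* distance to the nearest simple repeat (1; 0 inside)
* transcriptional strand (1: untranscribed / plus / minus / both)
* replication timing (1, may be undefined)

Total: 26.  Purine-reference variants are reverse-complemented onto the
pyrimidine strand, with the context reversed accordingly, so the
representation is strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ptascrub.annotations import AnnotationSet
from ptascrub.spectra import SUB_TYPES, reverse_complement
from ptascrub.variants import CandidateVariant

STRANDS = ("untranscribed", "plus", "minus", "both")
CONTEXT_OFFSETS = tuple(range(-10, 0)) + tuple(range(1, 11))

#: column order of the numeric feature matrix (26 columns)
FEATURE_COLUMNS: tuple[str, ...] = (
    ("ai_log_p", "mutation_type")
    + tuple(f"ctx_{o:+d}" for o in CONTEXT_OFFSETS)
    + ("gene_distance", "repeat_distance", "transcriptional_strand", "replication_timing")
)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class FeatureVector:
    ai_log_p: float | None
    mutation_type: str                    # one of SUB_TYPES
    context: str                          # 20 bases, positions -10..-1,+1..+10
    gene_distance: float
    repeat_distance: float
    transcriptional_strand: str
    replication_timing: float | None

    def __post_init__(self) -> None:
        if self.mutation_type not in SUB_TYPES:
            raise ValueError(f"unknown mutation type {self.mutation_type!r}")
        if len(self.context) != 20:
            raise ValueError("context must hold exactly 20 bases")
        if self.transcriptional_strand not in STRANDS:
            raise ValueError(f"unknown strand {self.transcriptional_strand!r}")

    @property
    def ai_defined(self) -> bool:
        return self.ai_log_p is not None

    @property
    def rt_defined(self) -> bool:
        return self.replication_timing is not None

    def context_base(self, offset: int) -> str:
        """Base at the given offset (−10..−1, +1..+10) from the variant."""
        idx = CONTEXT_OFFSETS.index(offset)
        return self.context[idx]


def extract_features(
    variant: CandidateVariant,
    annotations: AnnotationSet,
    ai_result=None,
    distance_cap: float = 1e7,
) -> FeatureVector:
    """Populate all 26 features for one candidate SNV.

    Overlapping gene annotations are resolved deterministically: strand by the
    distinct union (plus+minus → both) and replication timing by the
    median.  Distances are 0 when the position lies inside a feature.
    Context windows running off a chromosome end are padded with N.
    """
    ctx21 = annotations.context(variant.chrom, variant.pos, flank=10)
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if ref in ("A", "G"):
        ctx21 = reverse_complement(ctx21)
        from ptascrub.spectra import _COMPLEMENT

        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    mutation_type = f"{ref}>{alt}"
    context = ctx21[:10] + ctx21[11:]

    pos0 = variant.start
    gene_distance = annotations.genes.distance(variant.chrom, pos0)
    repeat_distance = annotations.simple_repeats.distance(variant.chrom, pos0)
    gene_distance = float(min(gene_distance, distance_cap)) if gene_distance is not None else distance_cap
    repeat_distance = float(min(repeat_distance, distance_cap)) if repeat_distance is not None else distance_cap

    strands = set(annotations.genes.values_overlapping(variant.chrom, pos0, pos0 + 1))
    if not strands:
        strand = "untranscribed"
    elif strands == {"+"}:
        strand = "plus"
    elif strands == {"-"}:
        strand = "minus"
    else:
        strand = "both"

    rt_vals = annotations.replication_timing.values_overlapping(variant.chrom, pos0, pos0 + 1)
    replication_timing = float(np.median(rt_vals)) if len(rt_vals) else None

    ai_log_p = None
    if ai_result is not None and getattr(ai_result, "defined", False):
        ai_log_p = ai_result.log_p

    return FeatureVector(
        ai_log_p=ai_log_p,
        mutation_type=mutation_type,
        context=context,
        gene_distance=gene_distance,
        repeat_distance=repeat_distance,
        transcriptional_strand=strand,
        replication_timing=replication_timing,
    )


def encode_features(vectors: list[FeatureVector], distance_cap: float = 1e7) -> pd.DataFrame:
    """Numeric 26-column matrix for the forest.

    Categoricals are ordinal-encoded; distances are log-transformed after
    capping for split stability.  Undefined AI / replication timing become
    NaN (rows carrying NaN are excluded from training and routed to the
    fallback models at scoring time).
    """
    rows = np.empty((len(vectors), len(FEATURE_COLUMNS)))
    for i, fv in enumerate(vectors):
        row = [
            np.nan if fv.ai_log_p is None else fv.ai_log_p,
            SUB_TYPES.index(fv.mutation_type),
        ]
        row.extend(_BASE_CODE[b] for b in fv.context)
        row.append(np.log10(1.0 + min(fv.gene_distance, distance_cap)))
        row.append(np.log10(1.0 + min(fv.repeat_distance, distance_cap)))
        row.append(STRANDS.index(fv.transcriptional_strand))
        row.append(np.nan if fv.replication_timing is None else fv.replication_timing)
        rows[i] = row
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
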