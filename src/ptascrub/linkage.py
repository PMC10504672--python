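"""Read-backed phasing (linked-read) analysis of candidate somatic variants.

A genuine somatic variant lies on one haplotype, so reads spanning both the
candidate and a nearby germline het should phase consistently: either
(alt, alt)/(ref, ref) pairs (cis) or (alt, ref)/(ref, alt) pairs (trans).
Chimera-like amplification artifacts phase inconsistently.  Per germline
site the cis/trans counts are scored under three hypotheses — cis, trans,
mixed — with expected cis-read fractions (1−ε, ε, 0.5); binomial
likelihoods are multiplied across sites under a uniform prior and the
posterior is folded into a single Phred-scaled score.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from ptascrub.config import PipelineConfig


class LinkageCategory(str, enum.Enum):
    FALSE_POSITIVE = "false_positive"
    UNCERTAIN = "uncertain"
    TRUE_VARIANT = "true_variant"
    UNINFORMATIVE = "uninformative"


@dataclass
class ReadObservation:
    """Alleles one read pair shows at the somatic site and a germline site."""

    read_id: str
    somatic_allele: str    # "ref", "alt", or "none"
    germline_allele: str   # "ref", "alt", or "none"


@dataclass
class LinkageResult:
    n_cis: int
    n_trans: int
    phred_score: float | None
    category: LinkageCategory


def count_phase_support(observations: list[ReadObservation]) -> tuple[int, int]:
    """Cis/trans counts for one (somatic, germline) site pair.

    A read counts as cis when it carries the alt alleles of both sites or
    the ref alleles of both sites; any other spanning read counts as
    trans.  Reads that miss either site do not count.
    """
    n_cis = n_trans = 0
    for obs in observations:
        if obs.somatic_allele == "none" or obs.germline_allele == "none":
            continue
        if obs.somatic_allele == obs.germline_allele:
            n_cis += 1
        else:
            n_trans += 1
    return n_cis, n_trans


def linkage_quality(
    counts_over_germline_sites: list[tuple[int, int]],
    error_rate: float = 0.005,
    phred_cap: float = 3000.0,
) -> float | None:
    """Phred-scaled phasing-consistency score from per-site (cis, trans) counts.

    Returns ``None`` (uninformative) when no site has spanning reads.
    The score is −10·log10(1 − max(P(cis), P(trans))) under the three-way
    posterior, capped at ``phred_cap``; only "mixedness" lowers it.
    """
    counts = [(c, t) for c, t in counts_over_germline_sites if c + t > 0]
    if not counts:
        return None
    eps = error_rate
    log_lik = np.zeros(3)  # cis, trans, mixed
    for p_h, idx in ((1.0 - eps, 0), (eps, 1), (0.5, 2)):
        for n_cis, n_trans in counts:
            log_lik[idx] += n_cis * math.log(p_h) + n_trans * math.log1p(-p_h)
    # posterior with uniform prior, in a numerically safe form
    log_lik -= log_lik.max()
    lik = np.exp(log_lik)
    post = lik / lik.sum()
    p_err = 1.0 - max(post[0], post[1])
    if p_err <= 0.0:
        return phred_cap
    return min(-10.0 * math.log10(p_err), phred_cap)


def classify_linkage(
    phred_score: float | None,
    false_max: float = 100.0,
    true_min: float = 1000.0,
) -> LinkageCategory:
    """Step-function classification of the Phred score.

    score < 100 → false positive; 100 ≤ score ≤ 1000 → uncertain;
    score > 1000 → true variant.  Boundaries land in "uncertain".
    """
    if phred_score is None:
        return LinkageCategory.UNINFORMATIVE
    if phred_score < false_max:
        return LinkageCategory.FALSE_POSITIVE
    if phred_score > true_min:
        return LinkageCategory.TRUE_VARIANT
    return LinkageCategory.UNCERTAIN


def assess_linkage(
    per_site_observations: list[list[ReadObservation]],
    config: PipelineConfig | None = None,
) -> LinkageResult:
    """Count, score, and classify phase support over several germline sites."""
    cfg = config or PipelineConfig()
    counts = [count_phase_support(obs) for obs in per_site_observations]
    score = linkage_quality(counts, cfg.linkage_error_rate, cfg.linkage_phred_cap)
    category = classify_linkage(score, cfg.linkage_false_max, cfg.linkage_true_min)
    return LinkageResult(
        n_cis=sum(c for c, _ in counts),
        n_trans=sum(t for _, t in counts),
        phred_score=score,
        category=category,
    )


def read_evidence_tsv(path) -> dict[str, list[list[ReadObservation]]]:
    """Pre-extracted read evidence, keeping tests BAM-free.

    TSV columns: candidate_id, germline_site, read_id, somatic_allele,
    germline_allele.  Returns per-candidate lists of per-germline-site
    observation lists.
    """
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["candidate", "germline_site", "read_id", "somatic_allele", "germline_allele"],
        header=0,
    )
    out: dict[str, list[list[ReadObservation]]] = {}
    for (cand, _site), sub in df.groupby(["candidate", "germline_site"], sort=True):
        obs = [
            ReadObservation(str(r.read_id), str(r.somatic_allele), str(r.germline_allele))
            for r in sub.itertuples()
        ]
        out.setdefault(str(cand), []).append(obs)
    return out
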