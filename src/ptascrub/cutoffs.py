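"""Sample-specific artifact-probability cutoff calibration.

Two complementary procedures produce a per-sample cutoff above which
candidates are called artifacts:

1. *Precision–recall*: candidates the linked-read analysis labeled
   confidently (score ≥ 1000 → likely true; < 1 → likely artifact) anchor
   precision/recall curves over a 101-point cutoff grid; the cutoff where
   the two curves intersect is taken, with the precision reached there
   recording how trustworthy the curve is.
2. *Cosine similarity*: 29 nested groups of candidates (probability below
   cutoffs 0.1..0.8, step 0.025) yield 96-channel spectra; hierarchical
   clustering of their pairwise cosine similarities into two clusters
   finds where artifact admixture makes the spectra diverge, and the
   highest cutoff in the cluster containing the lowest-cutoff group wins.

The final cutoff is the mean of the two, or the cosine cutoff alone when
the precision–recall curve is weak (best value < 0.7) or absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from ptascrub import variants as V
from ptascrub.config import PipelineConfig
from ptascrub.linkage import LinkageCategory
from ptascrub.spectra import Spectrum96, cosine_similarity, spectrum96


@dataclass
class CutoffResult:
    pr_cutoff: float | None
    pr_best_value: float
    cosine_cutoff: float | None
    final_cutoff: float
    method_used: str  # "mean" or "cosine_only"


def pr_based_cutoff(
    linkage_categories: list[LinkageCategory],
    probabilities,
    grid_step: float = 0.01,
) -> tuple[float | None, float]:
    """Cutoff from the intersection of the precision and recall curves.

    Only candidates labeled ``true_variant`` or ``false_positive`` by the
    linked-read analysis participate.  ``p_artifact < c`` predicts "true";
    over the 101-point grid the cutoff minimizing |precision − recall| is
    returned (ties → lower cutoff), along with the precision reached
    there.  Grid points with no positive prediction have undefined
    precision and are skipped.  Returns ``(None, 0.0)`` when either
    labeled group is empty.
    """
    probs = np.asarray(probabilities, dtype=float)
    cats = np.asarray([c.value if isinstance(c, LinkageCategory) else c
                       for c in linkage_categories])
    is_true = cats == LinkageCategory.TRUE_VARIANT.value
    is_false = cats == LinkageCategory.FALSE_POSITIVE.value
    keep = is_true | is_false
    if not is_true.any() or not is_false.any():
        return None, 0.0
    probs, y = probs[keep], is_true[keep]
    n_true = int(y.sum())

    grid = np.round(np.arange(0, 1.0 + grid_step / 2, grid_step), 10)
    best_cut, best_gap, best_prec = None, np.inf, 0.0
    for c in grid:
        predicted = probs < c
        n_pred = int(predicted.sum())
        if n_pred == 0:
            continue  # precision undefined at this cutoff
        tp = int((predicted & y).sum())
        precision = tp / n_pred
        recall = tp / n_true
        gap = abs(precision - recall)
        if gap < best_gap - 1e-12:
            best_cut, best_gap, best_prec = float(c), gap, precision
    if best_cut is None:
        return None, 0.0
    return best_cut, best_prec


def cosine_based_cutoff(
    substitutions,
    probabilities,
    config: PipelineConfig | None = None,
) -> float | None:
    """Cutoff from clustering the spectra of nested probability groups.

    ``substitutions`` are (ref, alt, 5' base, 3' base) tuples aligned with
    ``probabilities``.  Requires at least ``min_spectrum_mutations``
    substitutions below the lowest grid cutoff for a stable spectrum;
    otherwise returns ``None``.
    """
    cfg = config or PipelineConfig()
    probs = np.asarray(probabilities, dtype=float)
    subs = list(substitutions)
    if len(subs) != len(probs):
        raise ValueError("substitutions and probabilities differ in length")
    n_steps = int(round((cfg.cosine_cutoff_hi - cfg.cosine_cutoff_lo) / cfg.cosine_cutoff_step)) + 1
    grid = np.round(cfg.cosine_cutoff_lo + cfg.cosine_cutoff_step * np.arange(n_steps), 10)

    lowest = probs < grid[0]
    if int(lowest.sum()) < cfg.min_spectrum_mutations:
        return None

    spectra: list[Spectrum96] = []
    for c in grid:
        members = [s for s, p in zip(subs, probs) if p < c]
        spectra.append(spectrum96(members))

    k = len(grid)
    sim = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = cosine_similarity(spectra[i], spectra[j])

    # complete-linkage clustering of the similarity profiles into 2 clusters
    z = scipy_linkage(sim, method="complete", metric="euclidean")
    clusters = fcluster(z, t=2, criterion="maxclust")
    true_cluster = clusters[0]  # the cluster holding the lowest-cutoff group
    return float(grid[clusters == true_cluster].max())


def final_cutoff(
    pr_result: tuple[float | None, float],
    cosine_cutoff: float | None,
    config: PipelineConfig | None = None,
) -> CutoffResult:
    """Merge the two candidate cutoffs into the sample's final cutoff."""
    cfg = config or PipelineConfig()
    pr_cut, pr_best = pr_result
    if pr_cut is None and cosine_cutoff is None:
        raise ValueError(
            "no cutoff could be determined from either method; "
            "set a manual cutoff for this sample"
        )
    if pr_cut is not None and cosine_cutoff is not None and pr_best >= cfg.pr_min_best_value:
        return CutoffResult(pr_cut, pr_best, cosine_cutoff,
                            (pr_cut + cosine_cutoff) / 2.0, "mean")
    if cosine_cutoff is not None:
        return CutoffResult(pr_cut, pr_best, cosine_cutoff, cosine_cutoff, "cosine_only")
    # only the PR cutoff exists and it is strong enough to stand alone
    if pr_best >= cfg.pr_min_best_value:
        return CutoffResult(pr_cut, pr_best, None, pr_cut, "pr_only")
    raise ValueError(
        "precision-recall cutoff too weak and no cosine cutoff available; "
        "set a manual cutoff for this sample"
    )


def apply_cutoff(variants, probabilities, cutoff: float) -> None:
    """Flag candidates with artifact probability above the cutoff FAIL_RF."""
    for v, p in zip(variants, probabilities):
        v.artifact_probability = float(p)
        if p > cutoff:
            v.filter_flags.add(V.FAIL_RF)


def write_cutoff_report(result: CutoffResult, n_pass: int, n_fail: int, path) -> None:
    """Per-sample cutoff report as a small TSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "pr_cutoff": result.pr_cutoff,
                "pr_best_value": result.pr_best_value,
                "cosine_cutoff": result.cosine_cutoff,
                "final_cutoff": result.final_cutoff,
                "method_used": result.method_used,
                "n_pass": n_pass,
                "n_fail": n_fail,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
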