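"""Allelic imbalance modeling from phased germline heterozygous sites.

PTA amplifies the two haplotypes unevenly, so the B-allele frequency (BAF)
of germline hets drifts smoothly along the genome.  A true somatic variant
on one haplotype should show a VAF consistent with the local haplotype
balance; an amplification artifact need not.  We orient BAFs by haplotype,
fit a locally weighted degree-2 regression in a window around the
candidate, and score the candidate's allele counts with an exact two-sided
binomial test against the predicted BAF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from ptascrub.config import PipelineConfig


@dataclass
class PhasedHetSeries:
    """Haplotype-oriented BAFs of phased germline hets along one chromosome."""

    positions: np.ndarray      # 1-based
    hap_labels: np.ndarray     # 1 or 2
    ref_depths: np.ndarray
    alt_depths: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.positions, kind="stable")
        for name in ("positions", "hap_labels", "ref_depths", "alt_depths"):
            setattr(self, name, np.asarray(getattr(self, name))[order])

    @property
    def weights(self) -> np.ndarray:
        """Total depth per site (regression weights)."""
        return self.ref_depths + self.alt_depths

    @property
    def oriented_baf(self) -> np.ndarray:
        """BAF after swapping allele depths of hap-2 sites.

        For a hap-1 site the oriented BAF is alt/(ref+alt); for a hap-2
        site the depths are swapped, so it equals 1 − raw BAF.
        """
        total = self.weights.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = self.alt_depths / total
        return np.where(self.hap_labels == 2, 1.0 - raw, raw)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class AIResult:
    predicted_baf: float | None
    alt_depth: int | None
    total_depth: int | None
    log_p: float | None
    defined: bool

    @classmethod
    def undefined(cls) -> "AIResult":
        return cls(None, None, None, None, defined=False)


def orient_hets(records: list[dict]) -> PhasedHetSeries:
    """Build an oriented series from phased het records (see io.read_phased_hets).

    Input records are already restricted to control-het, dbSNP-annotated
    sites; here we only apply the haplotype orientation.
    """
    if not records:
        return PhasedHetSeries(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
        )
    return PhasedHetSeries(
        positions=np.array([r["pos"] for r in records], dtype=np.int64),
        hap_labels=np.array([r["hap"] for r in records], dtype=np.int64),
        ref_depths=np.array([r["ref_depth"] for r in records], dtype=np.int64),
        alt_depths=np.array([r["alt_depth"] for r in records], dtype=np.int64),
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def predict_baf(
    series: PhasedHetSeries,
    candidate_pos: int,
    window: int = 200_000,
    min_hets: int = 10,
    degree: int = 2,
    clamp: float = 0.001,
) -> float | None:
    """Locally weighted degree-2 least squares prediction of the BAF.

    All phased germline hets within ``window`` bp of the candidate are
    used, with tricube distance weights over the window times the total
    allele depth of each site.  Returns ``None`` when fewer than
    ``min_hets`` informative sites are available.
    """
    pos = np.asarray(series.positions, dtype=float)
    mask = np.abs(pos - candidate_pos) <= window
    n = int(mask.sum())
    if n < min_hets:
        return None
    x = pos[mask] - candidate_pos          # center so the prediction is the intercept
    y = series.oriented_baf[mask]
    depth_w = series.weights[mask].astype(float)
    span = max(np.abs(x).max(), 1.0)
    w = _tricube(x / (span * 1.0001)) * depth_w
    ok = (w > 0) & np.isfinite(y)
    x, y, w = x[ok], y[ok], w[ok]
    if len(x) < min_hets:
        return None
    deg = min(degree, max(len(np.unique(x)) - 1, 0))
    # weighted polynomial LS; evaluate at 0 (the candidate position)
    xs = x / span                          # scale for conditioning
    design = np.vander(xs, deg + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    pred = float(coef[0])
    return float(np.clip(pred, clamp, 1.0 - clamp))


def ai_log_p(alt_depth: int, total_depth: int, predicted_baf: float) -> float:
    """Natural log of the exact two-sided binomial p-value.

    Two-sided by point-probability summation: the p-value is the total
    probability of outcomes no more likely than the observed count under
    Binomial(total_depth, predicted_baf).
    """
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("alt_depth must lie in [0, total_depth]")
    if not 0.0 < predicted_baf < 1.0:
        raise ValueError("predicted_baf must lie in (0, 1)")
    p = binomtest(alt_depth, total_depth, predicted_baf, alternative="two-sided").pvalue
    p = min(p, 1.0)
    if p <= 0.0:  # numerically impossible for valid inputs, but stay defined
        return -math.inf
    return math.log(p)


def assess_candidate(
    series: PhasedHetSeries,
    candidate_pos: int,
    alt_depth: int,
    total_depth: int,
    config: PipelineConfig | None = None,
) -> AIResult:
    """Predict the local BAF and test the candidate's allele counts against it."""
    cfg = config or PipelineConfig()
    pred = predict_baf(
        series,
        candidate_pos,
        window=cfg.ai_window,
        min_hets=cfg.ai_min_hets,
        degree=cfg.ai_loess_degree,
        clamp=cfg.ai_baf_clamp,
    )
    if pred is None or total_depth <= 0:
        return AIResult.undefined()
    log_p = ai_log_p(alt_depth, total_depth, pred)
    return AIResult(
        predicted_baf=pred,
        alt_depth=alt_depth,
        total_depth=total_depth,
        log_p=log_p,
        defined=True,
    )
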