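"""Deviation-of-allele-frequency (DAF) profiles of germline hets.

DAF = |VAF − 0.5| maps perfect heterozygosity to 0 and homozygous
appearance to 0.5, so uneven amplification and real copy-number changes
both surface as elevated mean DAF per 100-kb bin.  Two segmentations are
kept: one over all hets (losses, cnLOH) and one excluding hets that
already look LOH (DAF > 0.45), which protects copy-number-gain detection
from amplification dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ptascrub.config import PipelineConfig
from ptascrub.segmentation import segment_values
from ptascrub.variants import normalize_chrom


def daf(vaf) -> np.ndarray | float:
    """|VAF − 0.5|; 0 at perfect heterozygosity, 0.5 at 0 or 1."""
    return np.abs(np.asarray(vaf, dtype=float) - 0.5)


@dataclass
class DAFSegment:
    chrom: str
    start: int
    end: int
    mean_daf: float
    n_hets: int


@dataclass
class DAFProfile:
    """Per-het DAFs with binned means and the two segmentations."""

    hets: pd.DataFrame  # chrom, pos (1-based), vaf, daf
    config: PipelineConfig = field(default_factory=PipelineConfig)
    segments_all: list[DAFSegment] = field(default_factory=list)
    segments_no_loh: list[DAFSegment] = field(default_factory=list)

    def binned(self, exclude_loh: bool = False) -> pd.DataFrame:
        """Mean DAF per 100-kb bin (optionally dropping DAF > 0.45 hets)."""
        size = self.config.coarse_bin_size
        hets = self.hets
        if exclude_loh:
            hets = hets[hets["daf"] <= self.config.loh_daf_min]
        out = hets.copy()
        out["start"] = ((out["pos"] - 1) // size) * size
        grouped = (
            out.groupby(["chrom", "start"], sort=True)
            .agg(mean_daf=("daf", "mean"), n_hets=("daf", "size"))
            .reset_index()
        )
        grouped["end"] = grouped["start"] + size
        return grouped[["chrom", "start", "end", "mean_daf", "n_hets"]]

    def mean_daf(self, chrom: str, start: int, end: int) -> float:
        sel = self.hets[
            (self.hets["chrom"] == normalize_chrom(chrom))
            & (self.hets["pos"] - 1 >= start)
            & (self.hets["pos"] - 1 < end)
        ]
        return float(sel["daf"].mean()) if len(sel) else np.nan

    def vafs_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        sel = self.hets[
            (self.hets["chrom"] == normalize_chrom(chrom))
            & (self.hets["pos"] - 1 >= start)
            & (self.hets["pos"] - 1 < end)
        ]
        return sel["vaf"].to_numpy(float)

    @property
    def sample_mean_daf(self) -> float:
        return float(self.hets["daf"].mean())


def _segment_binned(
    binned: pd.DataFrame,
    hets: pd.DataFrame,
    cfg: PipelineConfig,
) -> list[DAFSegment]:
    segments: list[DAFSegment] = []
    for chrom, sub in binned.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        segs = segment_values(sub["mean_daf"].to_numpy(), gamma=cfg.segmentation_gamma)
        chrom_hets = hets[hets["chrom"] == chrom]
        for seg in segs:
            start = int(sub["start"].iloc[seg.start_index])
            end = int(sub["end"].iloc[seg.end_index - 1])
            start, end = _snap_to_hets(start, end, seg.mean, chrom_hets, cfg)
            inside = chrom_hets[(chrom_hets["pos"] - 1 >= start) & (chrom_hets["pos"] - 1 < end)]
            if not len(inside):
                continue
            segments.append(
                DAFSegment(
                    chrom=str(chrom), start=start, end=end,
                    mean_daf=float(inside["daf"].mean()), n_hets=len(inside),
                )
            )
    return segments


def _snap_to_hets(start: int, end: int, seg_mean: float, hets: pd.DataFrame, cfg: PipelineConfig):
    """Snap crude bin boundaries to the nearest het with a similar DAF.

    Candidate hets must lie within 200 kb of the boundary and have a DAF
    within the snap tolerance of the segment mean.
    """
    pos = hets["pos"].to_numpy() - 1
    similar = np.abs(hets["daf"].to_numpy() - seg_mean) <= cfg.daf_snap_tol
    for bound, setter in ((start, "start"), (end, "end")):
        near = similar & (np.abs(pos - bound) <= cfg.daf_snap_window)
        if near.any():
            snapped = int(pos[near][np.argmin(np.abs(pos[near] - bound))])
            if setter == "start":
                start = snapped
            else:
                end = snapped + 1
    return (start, end) if end > start else (start, start + 1)


def daf_profile(
    germline_hets: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> DAFProfile:
    """Build the DAF profile and both segmentations.

    ``germline_hets`` needs columns chrom, pos (1-based), vaf.
    """
    cfg = config or PipelineConfig()
    hets = germline_hets.copy()
    hets["chrom"] = hets["chrom"].map(lambda c: normalize_chrom(str(c)))
    hets["daf"] = daf(hets["vaf"])
    hets = hets.sort_values(["chrom", "pos"]).reset_index(drop=True)
    profile = DAFProfile(hets=hets, config=cfg)
    profile.segments_all = _segment_binned(profile.binned(exclude_loh=False), hets, cfg)
    no_loh = hets[hets["daf"] <= cfg.loh_daf_min]
    profile.segments_no_loh = _segment_binned(profile.binned(exclude_loh=True), no_loh, cfg)
    return profile


def vaf_modes(
    het_vafs,
    min_hets: int = 20,
    rel_density: float = 0.10,
) -> list[float]:
    """Kernel-density modes of a segment's VAF distribution.

    Gaussian KDE with Silverman bandwidth on a 512-point grid over [0,1];
    local maxima whose density is below ``rel_density`` of the global
    peak are suppressed.  Returns an empty list (state undetermined) when
    fewer than ``min_hets`` VAFs are supplied; a degenerate all-identical
    sample yields that single value.
    """
    vafs = np.asarray(het_vafs, dtype=float)
    vafs = vafs[np.isfinite(vafs)]
    if len(vafs) < min_hets:
        return []
    if np.ptp(vafs) < 1e-12:
        return [float(vafs[0])]
    kde = gaussian_kde(vafs, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, 512)
    dens = kde(grid)
    peaks = []
    for i in range(len(grid)):
        left = dens[i - 1] if i > 0 else -np.inf
        right = dens[i + 1] if i < len(grid) - 1 else -np.inf
        if dens[i] >= left and dens[i] > right:
            peaks.append(i)
    if not peaks:
        return []
    top = max(dens[i] for i in peaks)
    return [float(grid[i]) for i in peaks if dens[i] >= rel_density * top]
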