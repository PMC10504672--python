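"""Read-depth normalization against a coverage panel of normals (PON).

Input is a per-1-kb read-count table per sample (COBALT-compatible TSV:
chrom, start, end, count; GC normalization is assumed done upstream or is
approximated here by median-ratio correction).  The PON is the per-bin
mean over total-count-normalized normal samples; dividing a test sample
by it removes the shared amplification "waves".  Per-bin ratios are
expressed as copy number (2 = diploid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from ptascrub.annotations import IntervalTrack
from ptascrub.config import PipelineConfig
from ptascrub.segmentation import ValueSegment, fine_map_boundaries, segment_values
from ptascrub.variants import normalize_chrom

EXCL_PON_LOW = "pon_bottom_1pct"
EXCL_PON_HIGH = "pon_top_1pct"
EXCL_MARGIN = "centromere_telomere_margin"


def read_bin_counts(path: str | Path) -> pd.DataFrame:
    """Per-bin counts from a TSV with columns chrom,start,end,count."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "count"])
    df["chrom"] = df["chrom"].map(lambda c: normalize_chrom(str(c)))
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class CoveragePON:
    """Per-bin mean normalized count over >= 2 normal samples."""

    bins: pd.DataFrame  # chrom,start,end,mean_count,sd_count,outlier_low,outlier_high
    n_samples: int

    @classmethod
    def build(
        cls,
        sample_tables: list[pd.DataFrame],
        outlier_quantile: float = 0.01,
    ) -> "CoveragePON":
        if len(sample_tables) < 2:
            raise ValueError("a coverage PON needs at least 2 normal samples")
        base = sample_tables[0][["chrom", "start", "end"]].reset_index(drop=True)
        counts = np.empty((len(base), len(sample_tables)))
        target = float(np.mean([t["count"].sum() for t in sample_tables]))
        for k, table in enumerate(sample_tables):
            if len(table) != len(base) or not (
                table["start"].to_numpy() == base["start"].to_numpy()
            ).all():
                raise ValueError("PON samples must share one bin grid")
            # every sample normalized to the same total read count
            counts[:, k] = table["count"].to_numpy(float) * (target / table["count"].sum())
        bins = base.copy()
        bins["mean_count"] = counts.mean(axis=1)
        bins["sd_count"] = counts.std(axis=1, ddof=1)
        lo = np.quantile(bins["mean_count"], outlier_quantile)
        hi = np.quantile(bins["mean_count"], 1.0 - outlier_quantile)
        bins["outlier_low"] = bins["mean_count"] < lo
        bins["outlier_high"] = bins["mean_count"] > hi
        return cls(bins=bins, n_samples=len(sample_tables))

    @property
    def total(self) -> float:
        return float(self.bins["mean_count"].sum())


@dataclass
class CoverageProfile:
    """Normalized per-1-kb coverage of one sample.

    ``bins`` columns: chrom, start, end, count, ratio, copy_number,
    excluded (reason string, empty when usable).
    """

    bins: pd.DataFrame
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def included(self) -> pd.DataFrame:
        return self.bins[self.bins["excluded"] == ""]

    def coarse_bins(self, bin_size: int | None = None) -> pd.DataFrame:
        """Median copy number per coarse (default 100-kb) bin."""
        size = bin_size or self.config.coarse_bin_size
        inc = self.included().copy()
        inc["coarse_start"] = (inc["start"] // size) * size
        grouped = (
            inc.groupby(["chrom", "coarse_start"], sort=True)["copy_number"]
            .median()
            .reset_index()
            .rename(columns={"coarse_start": "start", "copy_number": "median_cn"})
        )
        grouped["end"] = grouped["start"] + size
        return grouped[["chrom", "start", "end", "median_cn"]]

    def mean_cn(self, chrom: str, start: int, end: int) -> float:
        inc = self.included()
        sel = inc[(inc["chrom"] == normalize_chrom(chrom))
                  & (inc["start"] < end) & (inc["end"] > start)]
        return float(sel["copy_number"].mean()) if len(sel) else np.nan


def normalize_coverage(
    sample_table: pd.DataFrame,
    pon: CoveragePON,
    centromeres: IntervalTrack | None = None,
    config: PipelineConfig | None = None,
) -> CoverageProfile:
    """Divide total-normalized sample counts by the PON per-bin means.

    Bins in the PON's bottom/top 1% and bins within 1 Mb of a centromere
    or chromosome end are excluded with a reason and carry no ratio.
    """
    cfg = config or PipelineConfig()
    bins = sample_table[["chrom", "start", "end"]].copy().reset_index(drop=True)
    if len(bins) != len(pon.bins) or not (
        bins["start"].to_numpy() == pon.bins["start"].to_numpy()
    ).all():
        raise ValueError("sample and PON must share one bin grid")

    counts = sample_table["count"].to_numpy(float)
    counts = counts * (pon.total / counts.sum())  # match the PON's total
    pon_mean = pon.bins["mean_count"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pon_mean > 0, counts / pon_mean, np.nan)

    excluded = np.array([""] * len(bins), dtype=object)
    excluded[pon.bins["outlier_low"].to_numpy()] = EXCL_PON_LOW
    excluded[pon.bins["outlier_high"].to_numpy()] = EXCL_PON_HIGH

    margin = cfg.centromere_margin
    for chrom, sub in bins.groupby("chrom"):
        chrom_n = normalize_chrom(str(chrom))
        chrom_end = int(sub["end"].max())
        zones = [(0, margin), (max(0, chrom_end - margin), chrom_end)]
        if centromeres is not None and chrom_n in centromeres.starts:
            for cs, ce in zip(centromeres.starts[chrom_n], centromeres.ends[chrom_n]):
                zones.append((max(0, cs - margin), ce + margin))
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        near = np.zeros(len(sub), dtype=bool)
        for zs, ze in zones:
            near |= (mid >= zs) & (mid < ze)
        excluded[sub.index[near]] = EXCL_MARGIN

    bins["count"] = counts
    bins["ratio"] = np.where(excluded == "", ratio, np.nan)
    bins["copy_number"] = bins["ratio"] * 2.0
    bins["excluded"] = excluded
    return CoverageProfile(bins=bins, config=cfg)


@dataclass
class CoverageSegment:
    chrom: str
    start: int
    end: int
    mean_cn: float
    n_bins: int
    sample_p: float | None = None
    pon_p: float | None = None
    direction: int = 0           # +1 gain-like, -1 loss-like
    is_candidate: bool = False


def coverage_segments(
    profile: CoverageProfile,
    config: PipelineConfig | None = None,
) -> list[CoverageSegment]:
    """Segment 100-kb median copy numbers, fine-mapped on 1-kb segments."""
    cfg = config or profile.config
    out: list[CoverageSegment] = []
    coarse = profile.coarse_bins()
    inc = profile.included()
    for chrom, sub in coarse.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        coarse_segs = segment_values(sub["median_cn"].to_numpy(), gamma=cfg.segmentation_gamma)
        coarse_bp = [
            (int(sub["start"].iloc[s.start_index]), int(sub["end"].iloc[s.end_index - 1]))
            for s in coarse_segs
        ]
        fine = inc[inc["chrom"] == chrom].sort_values("start").reset_index(drop=True)
        if len(fine):
            fine_segs = segment_values(fine["copy_number"].to_numpy(), gamma=cfg.segmentation_gamma)
            fine_bp = [
                (int(fine["start"].iloc[s.start_index]), int(fine["end"].iloc[s.end_index - 1]))
                for s in fine_segs
            ]
            coarse_bp = fine_map_boundaries(coarse_bp, fine_bp)
        for start, end in coarse_bp:
            sel = fine[(fine["start"] < end) & (fine["end"] > start)]
            if not len(sel):
                continue
            out.append(
                CoverageSegment(
                    chrom=str(chrom), start=start, end=end,
                    mean_cn=float(sel["copy_number"].mean()), n_bins=len(sel),
                )
            )
    return out


def coverage_segment_tests(
    segments: list[CoverageSegment],
    profile: CoverageProfile,
    pon: CoveragePON,
    config: PipelineConfig | None = None,
) -> list[CoverageSegment]:
    """Sample and PON one-sided z-tests per segment, in place.

    The within-sample reference distribution is the per-1-kb copy number
    of the top 25% of segments whose mean is closest to 2.  The PON test
    compares the segment's mean against the PON's per-bin copy numbers in
    the same region.  A segment is a copy-number candidate iff
    sample_p < 0.05 and pon_p < 0.2.
    """
    cfg = config or profile.config
    if len(segments) < 4:
        n_ref = max(1, len(segments))
    else:
        n_ref = max(1, int(np.ceil(len(segments) * 0.25)))
    ranked = sorted(segments, key=lambda s: abs(s.mean_cn - 2.0))
    ref_segs = ranked[:n_ref]
    inc = profile.included()
    ref_values = []
    for seg in ref_segs:
        sel = inc[(inc["chrom"] == seg.chrom) & (inc["start"] < seg.end) & (inc["end"] > seg.start)]
        ref_values.append(sel["copy_number"].to_numpy())
    ref_values = np.concatenate(ref_values) if ref_values else np.empty(0)
    ref_mean = float(ref_values.mean()) if len(ref_values) else np.nan
    ref_sd = float(ref_values.std(ddof=1)) if len(ref_values) > 1 else np.nan

    pon_bins = pon.bins
    pon_cn_all = 2.0 * pon_bins["mean_count"].to_numpy(float) / pon_bins["mean_count"].mean()

    for seg in segments:
        if not np.isfinite(ref_sd) or ref_sd == 0.0:
            seg.sample_p = None
        else:
            z = (seg.mean_cn - ref_mean) / ref_sd
            seg.direction = 1 if z > 0 else -1 if z < 0 else 0
            seg.sample_p = float(norm.sf(abs(z)))
        mask = (
            (pon_bins["chrom"] == seg.chrom)
            & (pon_bins["start"] < seg.end)
            & (pon_bins["end"] > seg.start)
        ).to_numpy()
        pon_cn = pon_cn_all[mask]
        if len(pon_cn) > 1 and pon_cn.std(ddof=1) > 0:
            zp = (seg.mean_cn - pon_cn.mean()) / pon_cn.std(ddof=1)
            seg.pon_p = float(norm.sf(abs(zp)))
        else:
            seg.pon_p = None
        seg.is_candidate = (
            seg.sample_p is not None
            and seg.pon_p is not None
            and seg.sample_p < cfg.sample_p_max
            and seg.pon_p < cfg.pon_p_max
        )
    return segments
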