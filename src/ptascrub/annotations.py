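"""Annotation tracks and reference-sequence access.

Intervals are 0-based half-open internally (BED convention); VCF-style
1-based inputs are converted at the boundary.  Tracks are stored as sorted
numpy arrays per chromosome so nearest-feature queries are O(log n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ptascrub.variants import normalize_chrom


class DictReference:
    """In-memory reference: a mapping of chromosome name -> sequence string."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {normalize_chrom(c): s.upper() for c, s in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases in [start, end), 0-based; out-of-range positions read as N."""
        seq = self._seqs[normalize_chrom(chrom)]
        left = "N" * min(max(0, -start), end - start)
        right = "N" * max(0, end - max(len(seq), start))
        return left + seq[max(0, start):min(len(seq), end)] + right

    def length(self, chrom: str) -> int:
        return len(self._seqs[normalize_chrom(chrom)])

    def chromosomes(self) -> list[str]:
        return list(self._seqs)


class FastaReference:
    """Reference backed by an indexed FASTA file (pyfaidx)."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self._names = {normalize_chrom(name): name for name in self._fasta.keys()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        name = self._names[normalize_chrom(chrom)]
        n = len(self._fasta[name])
        left = "N" * min(max(0, -start), end - start)
        right = "N" * max(0, end - max(n, start))
        core = str(self._fasta[name][max(0, start):min(n, end)]) if end > 0 and start < n else ""
        return left + core + right

    def length(self, chrom: str) -> int:
        return len(self._fasta[self._names[normalize_chrom(chrom)]])

    def chromosomes(self) -> list[str]:
        return list(self._names)


@dataclass
class IntervalTrack:
    """Sorted, per-chromosome interval lists with an optional value column."""

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str | None = None) -> "IntervalTrack":
        """Build from columns chrom/start/end (0-based half-open) and optionally a value."""
        track = cls()
        for chrom, sub in df.groupby(df["chrom"].astype(str).map(normalize_chrom)):
            sub = sub.sort_values("start")
            track.starts[chrom] = sub["start"].to_numpy(dtype=np.int64)
            track.ends[chrom] = sub["end"].to_numpy(dtype=np.int64)
            if value_col is not None:
                track.values[chrom] = sub[value_col].to_numpy()
        return track

    @classmethod
    def from_bed(cls, path: str | Path, value_col: str | None = None) -> "IntervalTrack":
        names = ["chrom", "start", "end"]
        if value_col is not None:
            names.append(value_col)
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=names, usecols=range(len(names)))
        return cls.from_dataframe(df, value_col=value_col)

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of intervals overlapping [start, end)."""
        chrom = normalize_chrom(chrom)
        if chrom not in self.starts:
            return np.empty(0, dtype=np.int64)
        idx = np.nonzero((self.starts[chrom] < end) & (self.ends[chrom] > start))[0]
        return idx

    def values_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        idx = self.overlapping(chrom, start, end)
        chrom = normalize_chrom(chrom)
        if chrom not in self.values:
            return np.empty(0)
        return self.values[chrom][idx]

    def distance(self, chrom: str, pos0: int) -> int | None:
        """Distance in bp from a 0-based position to the nearest interval.

        0 when the position lies inside an interval; ``None`` when the
        chromosome carries no intervals.
        """
        chrom = normalize_chrom(chrom)
        if chrom not in self.starts or len(self.starts[chrom]) == 0:
            return None
        starts, ends = self.starts[chrom], self.ends[chrom]
        inside = (starts <= pos0) & (ends > pos0)
        if inside.any():
            return 0
        # gap to the closest interval on either side, in whole bases
        left = pos0 - ends + 1          # >0 when the interval ends before pos0
        right = starts - pos0           # >0 when the interval starts after pos0
        gaps = np.minimum(np.where(left > 0, left, np.iinfo(np.int64).max),
                          np.where(right > 0, right, np.iinfo(np.int64).max))
        return int(gaps.min())

    def n_intervals(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.starts.get(normalize_chrom(chrom), ()))
        return sum(len(v) for v in self.starts.values())


@dataclass
class AnnotationSet:
    """The annotation tracks the feature extractor needs."""

    genes: IntervalTrack = field(default_factory=IntervalTrack)          # value = strand "+"/"-"
    simple_repeats: IntervalTrack = field(default_factory=IntervalTrack)
    replication_timing: IntervalTrack = field(default_factory=IntervalTrack)  # scalar value
    centromeres: IntervalTrack = field(default_factory=IntervalTrack)
    reference: DictReference | FastaReference | None = None

    def context(self, chrom: str, pos: int, flank: int = 10) -> str:
        """Reference sequence around a 1-based position, padded with N off-end."""
        if self.reference is None:
            raise ValueError("AnnotationSet has no reference sequence")
        center = pos - 1
        return self.reference.fetch(chrom, center - flank, center + flank + 1)


def read_replication_timing(path: str | Path) -> IntervalTrack:
    """TSV with columns chrom,start,end,value (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    return IntervalTrack.from_dataframe(df, value_col="value")
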