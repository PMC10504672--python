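"""Copy-number state calling, breakend filtering, and SV integration.

State rules (all thresholds in :class:`~ptascrub.config.PipelineConfig`):

* loss — coverage-loss candidate (sample p < 0.05, PON p < 0.2, downward)
  whose mean DAF exceeds 0.45;
* gain — coverage-gain candidate whose mean DAF exceeds the sample
  average and whose VAF distribution is multimodal with one mode near
  1/3 and one near 2/3 (±0.12), judged on the LOH-excluded segmentation;
* cnLOH — a DAF segment above 0.45 with no overlapping coverage
  candidate;
* breakend-supported SVs — GRIDSS-style BND records paired by MATEID,
  classified by orientation, and filtered by the DAF/ratio,
  junction-count, size, and rescue rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ptascrub.annotations import IntervalTrack
from ptascrub.config import PipelineConfig
from ptascrub.coverage import CoverageProfile, CoverageSegment
from ptascrub.daf import DAFProfile, vaf_modes
from ptascrub.variants import normalize_chrom


@dataclass
class Segment:
    """A genomic interval with its evidence and final state call."""

    chrom: str
    start: int
    end: int
    mean_cn: float | None = None
    mean_daf: float | None = None
    n_bins: int = 0
    n_hets: int = 0
    sample_p: float | None = None
    pon_p: float | None = None
    vaf_mode_list: list[float] = field(default_factory=list)
    state: str = "undetermined"   # loss / neutral / gain / cnLOH / undetermined
    evidence: set[str] = field(default_factory=set)


def _overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def _gain_mode_rule(modes: list[float], cfg: PipelineConfig) -> bool:
    if len(modes) < 2:
        return False
    has_low = any(abs(m - cfg.gain_mode_low) <= cfg.gain_mode_tol for m in modes)
    has_high = any(abs(m - cfg.gain_mode_high) <= cfg.gain_mode_tol for m in modes)
    return has_low and has_high


def call_cn_segments(
    coverage_segs: list[CoverageSegment],
    daf_prof: DAFProfile,
    config: PipelineConfig | None = None,
) -> list[Segment]:
    """Integrate coverage candidates with DAF evidence into state calls."""
    cfg = config or PipelineConfig()
    calls: list[Segment] = []
    sample_daf = daf_prof.sample_mean_daf

    for cov in coverage_segs:
        seg = Segment(
            chrom=cov.chrom, start=cov.start, end=cov.end,
            mean_cn=cov.mean_cn, n_bins=cov.n_bins,
            sample_p=cov.sample_p, pon_p=cov.pon_p,
        )
        seg.mean_daf = daf_prof.mean_daf(cov.chrom, cov.start, cov.end)
        vafs = daf_prof.vafs_in(cov.chrom, cov.start, cov.end)
        seg.n_hets = len(vafs)
        if cov.is_candidate and cov.direction < 0:
            if seg.mean_daf is not None and seg.mean_daf > cfg.loh_daf_min:
                seg.state = "loss"
                seg.evidence |= {"coverage", "daf"}
        elif cov.is_candidate and cov.direction > 0:
            # gains are judged on hets not already looking LOH
            non_loh = vafs[np.abs(vafs - 0.5) <= cfg.loh_daf_min]
            seg.vaf_mode_list = vaf_modes(non_loh, cfg.mode_min_hets, cfg.mode_rel_density)
            daf_ok = np.isfinite(seg.mean_daf) and seg.mean_daf > sample_daf
            if daf_ok and _gain_mode_rule(seg.vaf_mode_list, cfg):
                seg.state = "gain"
                seg.evidence |= {"coverage", "daf"}
        else:
            seg.state = "neutral" if seg.sample_p is not None else "undetermined"
        calls.append(seg)

    # cnLOH: high-DAF segments (all-het segmentation) without coverage support
    cnv_calls = [s for s in calls if s.state in ("loss", "gain")]
    for dseg in daf_prof.segments_all:
        if dseg.mean_daf <= cfg.loh_daf_min:
            continue
        if any(
            s.chrom == dseg.chrom and _overlap(s.start, s.end, dseg.start, dseg.end)
            for s in cnv_calls
        ):
            continue
        calls.append(
            Segment(
                chrom=dseg.chrom, start=dseg.start, end=dseg.end,
                mean_daf=dseg.mean_daf, n_hets=dseg.n_hets,
                state="cnLOH", evidence={"daf"},
            )
        )
    return calls


# ---------------------------------------------------------------------------
# breakends
# ---------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?P<leading>[ACGTN]*)(?P<open>[\[\]])(?P<chrom>[^:]+):(?P<pos>\d+)(?P=open)(?P<trailing>[ACGTN]*)$"
)


@dataclass
class Breakend:
    """One side of an SV junction (a VCF BND record)."""

    id: str
    chrom: str
    pos: int
    mate_id: str | None
    mate_chrom: str | None
    mate_pos: int | None
    orientation: str  # "+" = breakend at the right end of its segment
    junction_count: int = 0


@dataclass
class BreakendCall:
    """A mate-paired junction with its classification and filter flags."""

    chrom_a: str
    pos_a: int
    chrom_b: str | None
    pos_b: int | None
    sv_class: str            # DEL / DUP / INV / CTX / BND
    size: int | None
    junction_count: int = 1
    mate_missing: bool = False
    local_cn: float | None = None
    local_daf: float | None = None
    filter_flags: set[str] = field(default_factory=set)
    evidence: set[str] = field(default_factory=set)

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags


def parse_bnd_alt(alt: str) -> tuple[str, int, str] | None:
    """(mate chrom, mate pos, orientation) from a BND ALT string.

    Orientation is "+" when the ALT places the novel junction after the
    reference base (forms ``t[p[`` / ``t]p]``), "-" when before
    (``]p]t`` / ``[p[t``).
    """
    m = _BND_RE.match(alt)
    if not m:
        return None
    orientation = "+" if m.group("leading") else "-"
    return m.group("chrom"), int(m.group("pos")), orientation


def read_breakends(vcf_path) -> list[Breakend]:
    """BND records from a GRIDSS-style VCF."""
    import pysam

    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                parsed = parse_bnd_alt(alt)
                if parsed is None:
                    continue
                mate_chrom, mate_pos, orientation = parsed
                mate_id = rec.info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0] if mate_id else None
                out.append(
                    Breakend(
                        id=rec.id or f"{rec.chrom}:{rec.pos}",
                        chrom=rec.chrom, pos=rec.pos,
                        mate_id=mate_id, mate_chrom=mate_chrom, mate_pos=mate_pos,
                        orientation=orientation,
                    )
                )
    return out


def pair_breakends(breakends: list[Breakend]) -> list[BreakendCall]:
    """Pair BND records by MATEID and classify the junctions.

    For an intra-chromosomal pair with the lower breakend first,
    (+,−) → DEL, (−,+) → DUP, (+,+)/(−,−) → INV; different chromosomes →
    CTX.  Records whose mate is absent become single-ended calls with
    ``mate_missing`` set (flagged, not fatal).
    """
    by_id = {b.id: b for b in breakends}
    seen: set[str] = set()
    calls: list[BreakendCall] = []
    for b in breakends:
        if b.id in seen:
            continue
        mate = by_id.get(b.mate_id) if b.mate_id else None
        if mate is None:
            calls.append(
                BreakendCall(
                    chrom_a=b.chrom, pos_a=b.pos,
                    chrom_b=b.mate_chrom, pos_b=b.mate_pos,
                    sv_class="BND", size=None, mate_missing=True,
                )
            )
            seen.add(b.id)
            continue
        seen.update((b.id, mate.id))
        first, second = (b, mate) if (b.chrom, b.pos) <= (mate.chrom, mate.pos) else (mate, b)
        if normalize_chrom(first.chrom) != normalize_chrom(second.chrom):
            sv_class, size = "CTX", None
        else:
            pair = (first.orientation, second.orientation)
            size = abs(second.pos - first.pos)
            if pair == ("+", "-"):
                sv_class = "DEL"
            elif pair == ("-", "+"):
                sv_class = "DUP"
            else:
                sv_class = "INV"
        calls.append(
            BreakendCall(
                chrom_a=first.chrom, pos_a=first.pos,
                chrom_b=second.chrom, pos_b=second.pos,
                sv_class=sv_class, size=size,
            )
        )
    # junction counts: reciprocal partners of the same class and locus group
    window = 2000
    for cls in ("INV", "CTX"):
        group = [c for c in calls if c.sv_class == cls]
        for i, a in enumerate(group):
            count = 1
            for j, b in enumerate(group):
                if i == j:
                    continue
                if (
                    normalize_chrom(a.chrom_a) == normalize_chrom(b.chrom_a)
                    and (a.chrom_b is None or b.chrom_b is None
                         or normalize_chrom(a.chrom_b) == normalize_chrom(b.chrom_b))
                    and abs(a.pos_a - b.pos_a) <= max(window, (a.size or 0))
                    and (a.pos_b is None or b.pos_b is None
                         or abs(a.pos_b - b.pos_b) <= max(window, (a.size or 0)))
                ):
                    count += 1
            a.junction_count = count
    for c in calls:
        if c.junction_count == 0:
            c.junction_count = 1
    return calls


def build_breakend_pon(
    per_individual_positions: dict[str, list[tuple[str, int]]],
    window: int = 2000,
    min_individuals: int = 2,
) -> IntervalTrack:
    """Breakend PON: positions recurring within ``window`` bp in >= 2 individuals."""
    import pandas as pd

    rows = []
    for individual, positions in per_individual_positions.items():
        for chrom, pos in positions:
            rows.append((individual, normalize_chrom(chrom), pos))
    df = pd.DataFrame(rows, columns=["individual", "chrom", "pos"])
    intervals = []
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        ind = sub["individual"].to_numpy()
        for i in range(len(sub)):
            near = np.abs(pos - pos[i]) <= window
            if len(set(ind[near])) >= min_individuals:
                intervals.append((chrom, max(0, pos[i] - window), pos[i] + window))
    if not intervals:
        return IntervalTrack()
    out = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    return IntervalTrack.from_dataframe(out)


def _local_stats(call: BreakendCall, profile: CoverageProfile | None,
                 daf_prof: DAFProfile | None, flank: int = 10_000):
    """Copy number and DAF between the breakpoints (or around a lone end)."""
    if call.chrom_b is not None and call.pos_b is not None and \
            normalize_chrom(call.chrom_a) == normalize_chrom(call.chrom_b or ""):
        start, end = sorted((call.pos_a, call.pos_b))
        start, end = start - 1, end
    else:
        start, end = call.pos_a - 1 - flank, call.pos_a + flank
    if profile is not None:
        call.local_cn = profile.mean_cn(call.chrom_a, start, end)
    if daf_prof is not None:
        call.local_daf = daf_prof.mean_daf(call.chrom_a, start, end)
    return start, end


def filter_breakends(
    calls: list[BreakendCall],
    breakend_pon: IntervalTrack | None = None,
    profile: CoverageProfile | None = None,
    daf_prof: DAFProfile | None = None,
    cnv_segments: list[Segment] | None = None,
    config: PipelineConfig | None = None,
) -> list[BreakendCall]:
    """Apply every breakend filter; flags are cumulative and idempotent.

    DUP: filtered when local DAF < 0.18 or copy-number ratio < 2.5.
    DEL: filtered when local DAF < 0.4 or ratio > 1.5.  In the 15x
    coverage class, breakends in bins with > 100 reads are excluded.
    Inversions need two junctions and >= 1 kb size; inter-chromosomal
    events need two junctions unless within 100 kb of a CNV.
    """
    cfg = config or PipelineConfig()
    cnvs = [s for s in (cnv_segments or []) if s.state in ("loss", "gain")]
    for call in calls:
        flags = call.filter_flags
        if call.mate_missing:
            flags.add("MATE_MISSING")
        _local_stats(call, profile, daf_prof)

        if breakend_pon is not None:
            for chrom, pos in ((call.chrom_a, call.pos_a), (call.chrom_b, call.pos_b)):
                if chrom is None or pos is None:
                    continue
                if len(breakend_pon.overlapping(chrom, pos - 1, pos)) > 0:
                    flags.add("PON")
                    break

        if call.sv_class == "DUP":
            if call.local_daf is not None and call.local_daf < cfg.dup_min_daf:
                flags.add("LOW_DAF")
            if call.local_cn is not None and call.local_cn < cfg.dup_min_ratio:
                flags.add("LOW_RATIO")
        elif call.sv_class == "DEL":
            if call.local_daf is not None and call.local_daf < cfg.del_min_daf:
                flags.add("LOW_DAF")
            if call.local_cn is not None and call.local_cn > cfg.del_max_ratio:
                flags.add("HIGH_RATIO")
        elif call.sv_class == "INV":
            if call.junction_count < 2:
                flags.add("SINGLE_JUNCTION")
            if call.size is not None and call.size < cfg.min_inversion_size:
                flags.add("TOO_SMALL")
        elif call.sv_class in ("CTX", "BND"):
            if call.junction_count < 2:
                near_cnv = any(
                    (normalize_chrom(s.chrom) == normalize_chrom(c))
                    and abs(p - s.start) <= cfg.ctx_rescue_distance + (s.end - s.start)
                    and (s.start - cfg.ctx_rescue_distance) <= p <= (s.end + cfg.ctx_rescue_distance)
                    for s in cnvs
                    for c, p in ((call.chrom_a, call.pos_a), (call.chrom_b or "", call.pos_b or -1))
                    if p >= 0
                )
                if not near_cnv:
                    flags.add("SINGLE_JUNCTION")

        if cfg.coverage_class == "15x" and profile is not None:
            for chrom, pos in ((call.chrom_a, call.pos_a), (call.chrom_b, call.pos_b)):
                if chrom is None or pos is None:
                    continue
                bins = profile.bins
                sel = bins[
                    (bins["chrom"] == normalize_chrom(chrom))
                    & (bins["start"] <= pos - 1)
                    & (bins["end"] > pos - 1)
                ]
                if len(sel) and float(sel["count"].iloc[0]) > cfg.max_bnd_coverage_15x:
                    flags.add("HIGH_COVERAGE")
                    break
        call.evidence.add("breakend")
    return calls


def integrate_svs(
    cn_segments: list[Segment],
    breakend_calls: list[BreakendCall],
) -> list[dict]:
    """Final SV list: CNVs from coverage+DAF, balanced SVs from breakends.

    A surviving DEL/DUP junction matching a called CNV of the same
    direction merges into the CNV call (both evidence tags); other
    surviving junctions are emitted as breakend-supported events.
    """
    final: list[dict] = []
    cnvs = [s for s in cn_segments if s.state in ("loss", "gain", "cnLOH")]
    matched: set[int] = set()
    for seg in cnvs:
        entry = {
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "type": seg.state, "evidence": set(seg.evidence),
        }
        want = "DEL" if seg.state == "loss" else "DUP" if seg.state == "gain" else None
        for i, call in enumerate(breakend_calls):
            if not call.is_pass or call.sv_class != want or call.pos_b is None:
                continue
            if normalize_chrom(call.chrom_a) == normalize_chrom(seg.chrom) and _overlap(
                min(call.pos_a, call.pos_b), max(call.pos_a, call.pos_b), seg.start, seg.end
            ):
                entry["evidence"].add("breakend")
                matched.add(i)
        final.append(entry)
    for i, call in enumerate(breakend_calls):
        if i in matched or not call.is_pass:
            continue
        final.append(
            {
                "chrom": call.chrom_a, "start": call.pos_a,
                "end": call.pos_b if call.pos_b is not None else call.pos_a,
                "chrom_b": call.chrom_b,
                "type": call.sv_class, "evidence": set(call.evidence),
            }
        )
    return final
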