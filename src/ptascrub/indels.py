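"""Somatic indel filtering by recurrence and homopolymer context.

PTA artifact indels recur at the same positions across unrelated
individuals, so an exclusion list of indels seen in >= 2 individuals
(collected at VAF > 0.15, after each individual's own germline removal)
plus a rule removing 1–2 bp insertions that extend a >= 5 bp reference
homopolymer is sufficient — no classifier is trained for indels.

Match keys are (chrom, pos, ref, alt) after left-alignment against the
reference, so equivalent indel representations always collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ptascrub import variants as V
from ptascrub.config import PipelineConfig
from ptascrub.spectra import homopolymer_run
from ptascrub.variants import CandidateVariant, VarType, normalize_chrom

Key = tuple[str, int, str, str]


def left_align(chrom: str, pos: int, ref: str, alt: str, reference=None) -> Key:
    """Canonical left-aligned key for an indel.

    The shared suffix then prefix are trimmed completely, leaving a pure
    inserted or deleted sequence S at a 1-based position ``p`` (for a
    deletion, the first deleted base; for an insertion, the base before
    which S is inserted).  With a reference accessor, S is rotated left
    while the preceding reference base equals its last base — the
    standard left-alignment — so every representation of the same event
    collides on one key.  Empty alleles are written as ".".
    """
    ref, alt = ref.upper(), alt.upper()
    while ref and alt and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref and alt) or (not ref and not alt):
        # SNV or complex substitution: trimming alone is canonical
        return (normalize_chrom(chrom), pos, ref or ".", alt or ".")
    seq = ref or alt  # the deleted (ref) or inserted (alt) bases
    if reference is not None:
        while pos > 1 and reference.fetch(chrom, pos - 2, pos - 1) == seq[-1]:
            seq = seq[-1] + seq[:-1]
            pos -= 1
    return (normalize_chrom(chrom), pos, seq if ref else ".", seq if alt else ".")


@dataclass
class IndelExclusionList:
    """Recurrent-indel database keyed by left-aligned (chrom,pos,ref,alt)."""

    entries: dict[Key, dict] = field(default_factory=dict)

    def __contains__(self, key: Key) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                "individual_count": v["individual_count"],
                "sample_count": v["sample_count"],
                "individual_frequency": v["individual_frequency"],
                "sample_frequency": v["sample_frequency"],
            }
            for k, v in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IndelExclusionList":
        df = pd.read_csv(path, sep="\t")
        out = cls()
        for r in df.itertuples():
            key = (normalize_chrom(str(r.chrom)), int(r.pos), str(r.ref), str(r.alt))
            out.entries[key] = {
                "individual_count": int(r.individual_count),
                "sample_count": int(r.sample_count),
                "individual_frequency": float(r.individual_frequency),
                "sample_frequency": float(r.sample_frequency),
            }
        return out


def build_indel_exclusion_list(
    calls_by_individual: dict[str, dict[str, list[CandidateVariant]]],
    reference=None,
    config: PipelineConfig | None = None,
    test_sample_of: dict[str, str] | None = None,
) -> IndelExclusionList:
    """Aggregate per-individual indel calls into the exclusion list.

    ``calls_by_individual`` maps individual -> sample -> candidate indels
    (germline already removed upstream).  Only calls with VAF > 0.15 in
    their own sample are collected; keys observed in >= 2 distinct
    individuals are retained with individual/sample counts and
    frequencies.
    """
    import logging

    cfg = config or PipelineConfig()
    if len(calls_by_individual) < 2:
        logging.getLogger("ptascrub").warning(
            "indel exclusion list built from %d individual(s); "
            "recurrence filtering needs at least 2", len(calls_by_individual)
        )
    individuals_of: dict[Key, set[str]] = {}
    samples_of: dict[Key, set[tuple[str, str]]] = {}
    n_individuals = len(calls_by_individual)
    n_samples = sum(len(s) for s in calls_by_individual.values())
    for individual, by_sample in calls_by_individual.items():
        for sample, calls in by_sample.items():
            for v in calls:
                if v.var_type is VarType.SNV:
                    continue
                sample_name = (test_sample_of or {}).get(sample, sample)
                call = v.samples.get(sample_name) or next(iter(v.samples.values()))
                vaf = call.vaf
                if vaf is None or vaf <= cfg.indel_db_min_vaf:
                    continue
                key = left_align(v.chrom, v.pos, v.ref, v.alt, reference)
                individuals_of.setdefault(key, set()).add(individual)
                samples_of.setdefault(key, set()).add((individual, sample))
    out = IndelExclusionList()
    for key, individuals in individuals_of.items():
        if len(individuals) < cfg.indel_min_individuals:
            continue
        n_ind = len(individuals)
        n_smp = len(samples_of[key])
        out.entries[key] = {
            "individual_count": n_ind,
            "sample_count": n_smp,
            "individual_frequency": n_ind / max(n_individuals, 1),
            "sample_frequency": n_smp / max(n_samples, 1),
        }
    return out


def filter_indels(
    candidates: list[CandidateVariant],
    exclusion_list: IndelExclusionList,
    reference,
    config: PipelineConfig | None = None,
) -> list[CandidateVariant]:
    """Flag excluded and homopolymer-insertion indels; flags cumulative.

    The homopolymer rule removes 1–2 bp insertions of a single repeated
    base whose inserted base extends a reference run of >= 5 identical
    bases adjacent to the insertion point (the run is counted on the
    reference only).  Deletions are untouched by this rule.
    """
    cfg = config or PipelineConfig()
    for v in candidates:
        if v.var_type is VarType.SNV:
            continue
        key = left_align(v.chrom, v.pos, v.ref, v.alt, reference)
        if key in exclusion_list:
            v.filter_flags.add(V.FAIL_EXCLUSION)
        if v.var_type is VarType.INSERTION and reference is not None:
            chrom, ins_before, ref_part, inserted = key
            if ref_part == "." and 1 <= len(inserted) <= 2 and len(set(inserted)) == 1:
                # key position is the base the insertion precedes
                run = homopolymer_run(reference, chrom, ins_before - 1, inserted[0])
                if run >= cfg.homopolymer_min_run:
                    v.filter_flags.add(V.FAIL_HOMOPOLYMER)
    return candidates
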