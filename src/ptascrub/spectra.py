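"""96-channel trinucleotide spectra, indel contexts, burdens.

Substitutions are expressed on the pyrimidine strand: a purine reference
(A or G) is reverse-complemented together with its flanking bases, so
G>A at T[G]T lands in the same channel as C>T at A[C]A.  Channel order is
the COSMIC convention: substitution class (C>A, C>G, C>T, T>A, T>C, T>G)
major, then 5' base, then 3' base, each in A,C,G,T order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: channel labels like "A[C>A]A", COSMIC order
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES
    for five in BASES
    for three in BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def pyrimidine_context(ref: str, alt: str, five: str, three: str) -> tuple[str, str, str]:
    """(substitution class, 5' base, 3' base) on the pyrimidine strand."""
    ref, alt = ref.upper(), alt.upper()
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = reverse_complement(three), reverse_complement(five)
    return f"{ref}>{alt}", five.upper(), three.upper()


def channel_of(ref: str, alt: str, five: str, three: str) -> int | None:
    """Channel index, or None when the context contains N."""
    sub, f, t = pyrimidine_context(ref, alt, five, three)
    label = f"{f}[{sub}]{t}"
    return _CHANNEL_INDEX.get(label)


@dataclass
class Spectrum96:
    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("a 96-channel spectrum needs exactly 96 counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"channel": CHANNELS, "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "Spectrum96":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        counts = df.set_index("channel").loc[list(CHANNELS), "count"].to_numpy(float)
        return cls(counts)


def spectrum96(substitutions, reference=None) -> Spectrum96:
    """Spectrum from SNVs given as (ref, alt, 5' base, 3' base) tuples or
    as :class:`~ptascrub.variants.CandidateVariant` with a reference accessor.

    Substitutions whose context contains N are skipped and counted in
    ``n_skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for sub in substitutions:
        if isinstance(sub, tuple):
            ref, alt, five, three = sub
        else:
            if reference is None:
                raise ValueError("reference accessor required for variant records")
            ctx = reference.fetch(sub.chrom, sub.pos - 2, sub.pos + 1)
            ref, alt, five, three = sub.ref, sub.alt, ctx[0], ctx[2]
        idx = channel_of(ref, alt, five, three)
        if idx is None:
            skipped += 1
            continue
        counts[idx] += 1
    return Spectrum96(counts, n_skipped=skipped)


def cosine_similarity(a, b) -> float:
    """Cosine of two spectra (or any non-negative vectors); undefined for zeros."""
    a = np.asarray(getattr(a, "counts", a), dtype=float)
    b = np.asarray(getattr(b, "counts", b), dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# small-indel channels: type x length x repeat context (minimal scheme)
# ---------------------------------------------------------------------------

def homopolymer_run(reference, chrom: str, pos: int, base: str, max_scan: int = 50) -> int:
    """Length of the reference run of ``base`` flanking the point after
    1-based position ``pos`` (the insertion point), scanning both sides."""
    base = base.upper()
    right = 0
    i = pos  # 0-based index of the base after the insertion point
    while right < max_scan and reference.fetch(chrom, i, i + 1) == base:
        right += 1
        i += 1
    i = pos - 1
    left = 0
    while left < max_scan and reference.fetch(chrom, i, i + 1) == base:
        left += 1
        i -= 1
    # the run is contiguous across the insertion point, so both flanks count
    return left + right


def indel_channel(variant, reference) -> str:
    """Minimal indel classification: type, length class, homopolymer context."""
    from ptascrub.variants import VarType

    vt = variant.var_type
    if vt is VarType.INSERTION:
        inserted = variant.alt[len(variant.ref):]
        kind = "ins"
    elif vt is VarType.DELETION:
        inserted = variant.ref[len(variant.alt):]
        kind = "del"
    else:
        return "complex"
    length = min(len(inserted), 5)
    length_label = f"{length}" if length < 5 else "5+"
    run = 0
    if len(set(inserted)) == 1:
        run = homopolymer_run(reference, variant.chrom, variant.pos, inserted[0])
    run_label = f"{min(run, 5)}" if run < 5 else "5+"
    return f"{kind}.{length_label}.rep{run_label}"


def extrapolate_burden(n_pass_autosomal: int, callable_fraction: float) -> float:
    """Genome-wide burden: observed count divided by the surveyed fraction."""
    if not 0.0 < callable_fraction <= 1.0:
        raise ValueError("callable fraction must lie in (0, 1]")
    return n_pass_autosomal / callable_fraction


def callable_fraction(callable_track, genome_length: int, chroms=None) -> float:
    """Fraction of the genome covered by the callable-regions track."""
    total = 0
    for chrom, starts in callable_track.starts.items():
        if chroms is not None and chrom not in chroms:
            continue
        total += int((callable_track.ends[chrom] - starts).sum())
    return total / genome_length


def count_in_regions(variants, track) -> int:
    """Number of variants overlapping the track (e.g. callable regions)."""
    return sum(1 for v in variants if len(track.overlapping(v.chrom, v.start, v.end)) > 0)
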