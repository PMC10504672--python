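"""Synthetic inputs with the statistical structure the method assumes.

Every stage of the pipeline can be exercised without sequencing data:

* :func:`simulate_phased_hets` — phased germline hets whose oriented BAFs
  follow a smooth haplotype-imbalance profile, with binomial allele
  depths (the signal the allelic-imbalance regression models);
* :func:`simulate_candidates` — labeled true-somatic / artifact base
  substitutions: true somatics have VAF ~ Binomial(depth, 0.5)/depth and
  clock-like trinucleotide contexts, artifacts have sub-clonal VAFs
  (q ~ U(0.1, 0.4)), a T>C/C>T-enriched spectrum, and more distant,
  earlier-replicating genomic feature values; a separation parameter
  scales the divergence between the class distributions (0 = identical);
* :func:`simulate_coverage_daf` — per-1-kb read counts for a sample and
  a panel of normals around a shared wavy baseline, plus germline-het
  VAF tables reflecting the local copy-number state;
* :func:`simulate_indels` — true indels at random loci vs artifact
  insertions at homopolymers and recurrent sites.

Truth labels are emitted alongside every simulated object and never leak
into the observables except through the stated distributions.  Fixing the
seed fixes every emitted file bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ptascrub.annotations import DictReference
from ptascrub.features import STRANDS, FeatureVector
from ptascrub.imbalance import PhasedHetSeries
from ptascrub.linkage import classify_linkage, linkage_quality
from ptascrub.spectra import BASES, CHANNELS, SUB_TYPES, reverse_complement
from ptascrub.variants import CandidateVariant, Genotype, SampleCall

# ---------------------------------------------------------------------------
# packaged 96-channel spectra used by the generator (constants, so tests
# are reproducible)
# ---------------------------------------------------------------------------


def _build_spectrum(weights: dict[str, float], base_weight: float) -> np.ndarray:
    spec = np.full(96, base_weight)
    for i, label in enumerate(CHANNELS):
        sub = label[2:5]
        five, three = label[0], label[6]
        if sub in weights:
            spec[i] += weights[sub]
        if sub == "C>T" and three == "G" and "CpG" in weights:
            spec[i] += weights["CpG"]
    return spec / spec.sum()


#: clock-like true-somatic spectrum: C>T dominated, strongly CpG-enriched
TRUE_SPECTRUM_96: np.ndarray = _build_spectrum(
    {"C>T": 2.0, "CpG": 12.0, "T>C": 0.8, "C>A": 0.6}, base_weight=0.25
)

#: amplification-artifact-like spectrum: T>C and non-CpG C>T enriched
ARTIFACT_SPECTRUM_96: np.ndarray = _build_spectrum(
    {"T>C": 4.0, "C>T": 1.2, "T>A": 1.0, "C>A": 0.8}, base_weight=0.25
)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated observables."""

    labels: np.ndarray | None = None          # "true_somatic" / "artifact"
    segments: list[tuple[int, int, str]] | None = None
    breakend_valid: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_tsv(self, path: str | Path) -> None:
        if self.labels is not None:
            pd.DataFrame({"index": np.arange(len(self.labels)), "label": self.labels}).to_csv(
                path, sep="\t", index=False
            )
        elif self.segments is not None:
            pd.DataFrame(self.segments, columns=["start", "end", "state"]).to_csv(
                path, sep="\t", index=False
            )


# ---------------------------------------------------------------------------
# phased germline hets
# ---------------------------------------------------------------------------

def simulate_phased_hets(
    region_length: int,
    het_density: float,
    mean_depth: float,
    imbalance_profile=None,
    seed: int = 0,
    chrom: str = "1",
) -> tuple[PhasedHetSeries, list[dict], SimTruth]:
    """Phased hets at Poisson spacing with binomial allele depths.

    ``imbalance_profile`` maps position -> expected haplotype-1 allele
    fraction (constant 0.5 for balanced regions).  Haplotype labels
    alternate randomly; a hap-2 site's alt allele lies on haplotype 2, so
    its raw BAF is drawn with success probability 1 − profile(pos).
    """
    if het_density <= 0:
        raise ValueError("het_density must be positive")
    if mean_depth < 1:
        raise ValueError("mean_depth must be at least 1")
    rng = np.random.default_rng(seed)
    profile = imbalance_profile or (lambda pos: np.full_like(np.asarray(pos, float), 0.5))

    gaps = rng.exponential(1.0 / het_density, size=int(region_length * het_density * 2) + 10)
    positions = np.cumsum(gaps).astype(np.int64) + 1
    positions = positions[positions <= region_length]
    positions = np.unique(positions)
    n = len(positions)

    haps = rng.integers(1, 3, size=n)
    depths = np.maximum(rng.poisson(mean_depth, size=n), 1)
    p_hap1 = np.clip(np.asarray(profile(positions), dtype=float), 0.0, 1.0)
    p_alt = np.where(haps == 1, p_hap1, 1.0 - p_hap1)
    alt_depths = rng.binomial(depths, p_alt)
    ref_depths = depths - alt_depths

    records = [
        {
            "chrom": chrom,
            "pos": int(positions[i]),
            "id": f"rs{900000 + i}",
            "hap": int(haps[i]),
            "ref_depth": int(ref_depths[i]),
            "alt_depth": int(alt_depths[i]),
        }
        for i in range(n)
    ]
    series = PhasedHetSeries(positions, haps, ref_depths, alt_depths)
    truth = SimTruth(
        params={"region_length": region_length, "het_density": het_density,
                "mean_depth": mean_depth},
        seed=seed,
    )
    return series, records, truth


def write_phased_vcf(records: list[dict], path: str | Path, sample: str = "SIM") -> None:
    """Emit phased het records as a minimal single-sample VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    contigs = sorted({r["chrom"] for r in records})
    lines[1:1] = [f"##contig=<ID={c}>" for c in contigs]
    for r in sorted(records, key=lambda x: (x["chrom"], x["pos"])):
        gt = "0|1" if r["hap"] == 1 else "1|0"
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t{r['id']}\tA\tG\t.\tPASS\t.\tGT:AD\t"
            f"{gt}:{r['ref_depth']},{r['alt_depth']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# labeled candidate base substitutions
# ---------------------------------------------------------------------------

def _sample_channel_context(rng, spectrum: np.ndarray):
    """(ref, alt, five, three) on the pyrimidine strand from a 96-spectrum."""
    idx = rng.choice(96, p=spectrum)
    label = CHANNELS[idx]
    sub, five, three = label[2:5], label[0], label[6]
    return sub[0], sub[2], five, three


def simulate_candidates(
    n_true: int,
    n_artifact: int,
    feature_separation: float = 1.0,
    seed: int = 0,
    depth_mean: float = 30.0,
    region_length: int = 10_000_000,
    chrom: str = "1",
    informative_fraction: float = 0.2,
    undefined_ai_fraction: float = 0.04,
    undefined_rt_fraction: float = 0.03,
) -> tuple[list[CandidateVariant], list[FeatureVector], SimTruth]:
    """Labeled candidates with class-conditional features.

    ``feature_separation`` in [0, 1] scales the divergence of the two
    class distributions; at 0 the classes share one distribution and no
    classifier can beat chance.
    """
    if n_true < 0 or n_artifact < 0:
        raise ValueError("counts must be non-negative")
    s = float(np.clip(feature_separation, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    n = n_true + n_artifact
    labels = np.array(["true_somatic"] * n_true + ["artifact"] * n_artifact)
    order = rng.permutation(n)
    labels = labels[order]

    positions = np.sort(rng.choice(np.arange(1001, region_length - 1000), size=n, replace=False))
    art_spectrum = (1.0 - s) * TRUE_SPECTRUM_96 + s * ARTIFACT_SPECTRUM_96

    strand_base = np.array([0.5, 0.2, 0.2, 0.1])
    strand_true = (1.0 - s) * strand_base + s * np.array([0.3, 0.3, 0.3, 0.1])

    variants: list[CandidateVariant] = []
    vectors: list[FeatureVector] = []
    link_scores = np.full(n, np.nan)
    for i in range(n):
        is_true = labels[i] == "true_somatic"
        depth = max(int(rng.poisson(depth_mean)), 4)
        if is_true:
            p_alt = 0.5
        else:
            q = rng.uniform(0.1, 0.4)
            p_alt = 0.5 - s * (0.5 - q)
        alt_depth = int(np.clip(rng.binomial(depth, p_alt), 1, depth))
        ref_depth = depth - alt_depth

        # allelic imbalance: test the simulated counts against local balance
        if rng.random() < undefined_ai_fraction:
            ai = None
        else:
            from ptascrub.imbalance import ai_log_p

            ai = ai_log_p(alt_depth, depth, 0.5)

        spectrum = TRUE_SPECTRUM_96 if is_true else art_spectrum
        ref, alt, five, three = _sample_channel_context(rng, spectrum)
        flanks = "".join(rng.choice(list(BASES), size=18))
        context = flanks[:9] + five + three + flanks[9:]  # positions -10..-1,+1..+10
        mutation_type = f"{ref}>{alt}"

        if is_true:
            gene_distance = float(rng.lognormal(9.2, 1.0))
            rt = float(rng.normal(45.0 + 15.0 * s, 12.0))
            strand = rng.choice(STRANDS, p=strand_true)
        else:
            gene_distance = float(rng.lognormal(9.2 + 3.2 * s, 1.0))
            rt = float(rng.normal(45.0, 12.0))
            strand = rng.choice(STRANDS, p=strand_base)
        repeat_distance = float(rng.lognormal(8.0, 1.0))
        if rng.random() < undefined_rt_fraction:
            rt = None

        vectors.append(
            FeatureVector(
                ai_log_p=ai,
                mutation_type=mutation_type,
                context=context,
                gene_distance=gene_distance,
                repeat_distance=repeat_distance,
                transcriptional_strand=str(strand),
                replication_timing=rt,
            )
        )

        # genome-strand representation: half the purine-strand variants
        g_ref, g_alt, g_five, g_three = ref, alt, five, three
        if rng.random() < 0.5:
            g_ref, g_alt = reverse_complement(ref), reverse_complement(alt)
            g_five, g_three = reverse_complement(three), reverse_complement(five)
        v = CandidateVariant(
            chrom=chrom,
            pos=int(positions[i]),
            ref=g_ref,
            alt=g_alt,
            samples={"SIM": SampleCall(ref_depth, alt_depth, 99.0, Genotype.HET)},
            site_quality=200.0,
            mapping_quality=60.0,
        )
        v.info["five"] = g_five
        v.info["three"] = g_three
        v.ai_log_p = ai

        # read-backed phasing evidence for the informative subset
        if rng.random() < informative_fraction:
            n_span = max(int(rng.poisson(18)), 2)
            if is_true:
                phase_p = 0.995 if rng.random() < 0.5 else 0.005  # cis or trans
            else:
                phase_p = 0.5  # chimeric artifact phases inconsistently
            n_cis = int(rng.binomial(n_span, phase_p))
            score = linkage_quality([(n_cis, n_span - n_cis)])
            v.linkage_score = score
            link_scores[i] = score if score is not None else np.nan
        variants.append(v)

    truth = SimTruth(
        labels=labels,
        params={
            "n_true": n_true, "n_artifact": n_artifact,
            "feature_separation": feature_separation, "depth_mean": depth_mean,
        },
        seed=seed,
    )
    return variants, vectors, truth


def substitutions_of(variants: list[CandidateVariant]) -> list[tuple[str, str, str, str]]:
    """(ref, alt, 5', 3') tuples for spectrum building, genome orientation."""
    return [(v.ref, v.alt, v.info["five"], v.info["three"]) for v in variants]


def linkage_categories_of(variants: list[CandidateVariant], config=None):
    from ptascrub.config import PipelineConfig

    cfg = config or PipelineConfig()
    return [
        classify_linkage(v.linkage_score, cfg.linkage_false_max, cfg.linkage_true_min)
        for v in variants
    ]


# ---------------------------------------------------------------------------
# coverage + DAF (structural variants)
# ---------------------------------------------------------------------------

STATE_COPY_NUMBER = {"loss": 1.0, "neutral": 2.0, "gain": 3.0, "cnLOH": 2.0}


def simulate_coverage_daf(
    cn_segments: list[tuple[int, int, str]],
    n_pon_samples: int = 12,
    seed: int = 0,
    mean_count: float = 50.0,
    het_density: float = 0.0008,
    het_depth_mean: float = 30.0,
    wave_amplitude: float = 0.25,
    bin_size: int = 1000,
    chrom: str = "1",
) -> dict:
    """Per-1-kb counts (sample + PON) and germline het VAFs for a profile.

    ``cn_segments`` must tile [0, L) with states in
    {loss, neutral, gain, cnLOH}.  All samples share a smooth wavy
    baseline (so PON division removes the waves); the test sample's
    counts scale with the local copy number.  Het VAF success
    probabilities: 0.5 (CN 2), 1/3 or 2/3 (CN 3), 0.02/0.98 (loss and
    cnLOH).
    """
    if n_pon_samples < 2:
        raise ValueError("need at least 2 PON samples")
    ends = [seg[1] for seg in cn_segments]
    starts = [seg[0] for seg in cn_segments]
    if starts[0] != 0 or any(e != s for e, s in zip(ends[:-1], starts[1:])):
        raise ValueError("cn_segments must tile the chromosome contiguously from 0")
    length = ends[-1]
    rng = np.random.default_rng(seed)

    n_bins = length // bin_size
    mid = (np.arange(n_bins) + 0.5) * bin_size
    wave = (
        1.0
        + wave_amplitude * np.sin(2 * np.pi * mid / 1.7e6)
        + 0.4 * wave_amplitude * np.sin(2 * np.pi * mid / 4.3e5 + 1.0)
    )
    wave = np.clip(wave, 0.2, None)

    cn = np.full(n_bins, 2.0)
    for start, end, state in cn_segments:
        cn[(mid >= start) & (mid < end)] = STATE_COPY_NUMBER[state]

    grid = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_bins, dtype=np.int64) * bin_size,
            "end": (np.arange(n_bins, dtype=np.int64) + 1) * bin_size,
        }
    )
    sample_counts = grid.copy()
    sample_counts["count"] = rng.poisson(mean_count * wave * cn / 2.0)
    pon_tables = []
    for _ in range(n_pon_samples):
        t = grid.copy()
        t["count"] = rng.poisson(mean_count * wave)
        pon_tables.append(t)

    # germline hets
    gaps = rng.exponential(1.0 / het_density, size=int(length * het_density * 2) + 10)
    positions = np.cumsum(gaps).astype(np.int64) + 1
    positions = np.unique(positions[positions <= length])
    state_of = np.empty(len(positions), dtype=object)
    for start, end, state in cn_segments:
        state_of[(positions - 1 >= start) & (positions - 1 < end)] = state
    p_alt = np.empty(len(positions))
    for i, state in enumerate(state_of):
        if state == "neutral":
            p_alt[i] = 0.5
        elif state == "gain":
            p_alt[i] = 1 / 3 if rng.random() < 0.5 else 2 / 3
        else:  # loss, cnLOH: one allele (nearly) dropped
            p_alt[i] = 0.02 if rng.random() < 0.5 else 0.98
    local_cn = np.array([STATE_COPY_NUMBER[s] for s in state_of])
    depths = np.maximum(rng.poisson(het_depth_mean * local_cn / 2.0), 1)
    alt = rng.binomial(depths, p_alt)
    hets = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref_depth": depths - alt,
            "alt_depth": alt,
            "vaf": alt / depths,
        }
    )

    truth = SimTruth(
        segments=list(cn_segments),
        params={
            "n_pon_samples": n_pon_samples, "mean_count": mean_count,
            "het_density": het_density, "wave_amplitude": wave_amplitude,
        },
        seed=seed,
    )
    return {
        "sample_counts": sample_counts,
        "pon_tables": pon_tables,
        "hets": hets,
        "truth": truth,
    }


def write_bin_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[["chrom", "start", "end", "count"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# reference sequence and indels
# ---------------------------------------------------------------------------

def simulate_reference(length: int, seed: int = 0, chrom: str = "1",
                       homopolymer_rate: float = 2e-4) -> DictReference:
    """Random reference with embedded >= 5 bp homopolymer runs."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    n_runs = rng.poisson(homopolymer_rate * length)
    starts = rng.integers(0, max(length - 12, 1), size=n_runs)
    for s in starts:
        run_len = int(rng.integers(5, 10))
        seq[s:s + run_len] = seq[s]
    return DictReference({chrom: "".join(seq)})


def write_fasta(reference: DictReference, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in reference.chromosomes():
            fh.write(f">{chrom}\n")
            seq = reference.fetch(chrom, 0, reference.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_indels(
    n_true: int,
    n_artifact: int,
    reference: DictReference,
    seed: int = 0,
    chrom: str = "1",
    depth_mean: float = 30.0,
) -> tuple[list[CandidateVariant], SimTruth]:
    """True indels at random loci; artifact 1-bp insertions in homopolymers.

    Artifact insertions are placed at reference runs of >= 5 identical
    bases (the dominant PTA indel error mode); true indels avoid them.
    """
    rng = np.random.default_rng(seed)
    length = reference.length(chrom)
    seq = reference.fetch(chrom, 0, length)

    # locate homopolymer runs of >= 5
    runs = []
    i = 0
    while i < length:
        j = i
        while j < length and seq[j] == seq[i]:
            j += 1
        if j - i >= 5:
            runs.append((i, j))
        i = j
    if n_artifact > 0 and not runs:
        raise ValueError("reference has no homopolymer runs for artifact placement")

    variants: list[CandidateVariant] = []
    labels = []
    used = set()
    for _ in range(n_true):
        while True:
            pos0 = int(rng.integers(10, length - 10))
            base = seq[pos0]
            nxt = seq[pos0 + 1]
            in_run = any(r[0] - 2 <= pos0 < r[1] + 1 for r in runs)
            if not in_run and base != "N" and pos0 not in used and nxt != base:
                break
        used.add(pos0)
        if rng.random() < 0.5:  # insertion of a base different from both neighbours
            ins = rng.choice([b for b in "ACGT" if b not in (base, nxt)])
            ref_a, alt_a = base, base + ins
        else:  # deletion of the next base
            ref_a, alt_a = base + nxt, base
        depth = max(int(rng.poisson(depth_mean)), 4)
        alt_d = int(np.clip(rng.binomial(depth, 0.5), 1, depth))
        variants.append(
            CandidateVariant(
                chrom=chrom, pos=pos0 + 1, ref=ref_a, alt=alt_a,
                samples={"SIM": SampleCall(depth - alt_d, alt_d, 99.0, Genotype.HET)},
                site_quality=200.0, mapping_quality=60.0,
            )
        )
        labels.append("true_somatic")
    for _ in range(n_artifact):
        start, end = runs[int(rng.integers(0, len(runs)))]
        pos0 = start  # anchor just before the run; insertion extends it
        anchor = seq[pos0 - 1]
        depth = max(int(rng.poisson(depth_mean)), 4)
        alt_d = int(np.clip(rng.binomial(depth, rng.uniform(0.2, 0.5)), 1, depth))
        variants.append(
            CandidateVariant(
                chrom=chrom, pos=pos0, ref=anchor, alt=anchor + seq[start],
                samples={"SIM": SampleCall(depth - alt_d, alt_d, 99.0, Genotype.HET)},
                site_quality=200.0, mapping_quality=60.0,
            )
        )
        labels.append("artifact")
    truth = SimTruth(labels=np.array(labels), seed=seed,
                     params={"n_true": n_true, "n_artifact": n_artifact})
    return variants, truth
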