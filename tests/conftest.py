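import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FILTER=<ID=SNP_LowQual,Description="low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF from (samples, row lines) and return its path."""

    def _make(rows, samples=("S1",), name="test.vcf"):
        path = tmp_path / name
        text = VCF_HEADER.format(samples="\t".join(samples))
        text += "\n".join(rows) + "\n"
        path.write_text(text)
        return path

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_annotations():
    """A tiny annotation set over one 2-kb chromosome."""
    import pandas as pd

    from ptascrub.annotations import AnnotationSet, DictReference, IntervalTrack

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    # fixed motif at 1000 (0-based): 5'-A [C] G-3'
    seq = seq[:999] + "ACG" + seq[1002:]
    genes = pd.DataFrame(
        {"chrom": ["1", "1"], "start": [900, 950], "end": [1100, 1020],
         "strand": ["+", "-"]}
    )
    repeats = pd.DataFrame({"chrom": ["1"], "start": [1500], "end": [1600]})
    timing = pd.DataFrame(
        {"chrom": ["1", "1"], "start": [0, 1000], "end": [1000, 2000],
         "value": [10.0, 30.0]}
    )
    return AnnotationSet(
        genes=IntervalTrack.from_dataframe(genes, value_col="strand"),
        simple_repeats=IntervalTrack.from_dataframe(repeats),
        replication_timing=IntervalTrack.from_dataframe(timing, value_col="value"),
        reference=DictReference({"1": seq}),
    )


def make_variant(
    chrom="1", pos=100, ref="A", alt="T", sample="S1",
    ref_depth=20, alt_depth=10, gq=99, genotype=None, qual=200.0, mq=60.0,
    extra_samples=None,
):
    """Convenience constructor used across the unit tests."""
    from ptascrub.variants import CandidateVariant, Genotype, SampleCall

    gt = genotype or Genotype.HET
    samples = {sample: SampleCall(ref_depth, alt_depth, gq, gt)}
    if extra_samples:
        samples.update(extra_samples)
    return CandidateVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, samples=samples,
        site_quality=qual, mapping_quality=mq,
    )
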