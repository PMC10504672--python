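# ptascrub

Filtering of whole-genome-amplification artifacts from PTA-based
single-cell whole-genome sequencing data.

## The problem

Primary template-directed amplification (PTA) makes single-cell WGS
practical, but every amplification reaction still introduces hundreds to
thousands of artifactual variant calls — chimeric base substitutions,
recurrent indels at homopolymers, and coverage/allele-frequency noise that
derails structural-variant calling.  Simple quality filters cannot
separate these artifacts from genuine somatic mutations, and tools that
rely on read-backed phasing alone have low sensitivity because only
10–30% of candidates sit close enough to a phased germline het to be
checked.

`ptascrub` is for researchers analysing PTA single-cell WGS who need
genome-wide somatic SNV, indel, and SV calls with the artifacts removed.

## The method

**Base substitutions.** After SMuRF-style prefilters (QUAL ≥ 100, MQ > 55,
depth ≥ 10 at ~30x / ≥ 5 at ~15x, GQ ≥ 99 (het) / ≥ 10 (hom), VAF ≥ 0.3 at
30x / ≥ 0.2 at 15x, no control evidence, not in a panel of normals), each
candidate is represented by 26 genomic features:

* the log p-value of an exact two-sided binomial test of the candidate's
  allele counts against the locally expected B-allele frequency — a
  degree-2 locally weighted regression of haplotype-oriented germline-het
  BAFs within 200 kb, weighted by allele depth;
* the pyrimidine-strand mutation type and the 20 bases of sequence
  context (±10 bp);
* distance to the nearest gene and simple repeat, transcriptional strand,
  and replication timing.

A random forest (500 trees, 4 variables per split, classes balanced 1:1,
with two fallback forests for candidates lacking the allelic-imbalance or
replication-timing feature) turns the features into an artifact
probability *p*.  A **sample-specific cutoff** on *p* is then calibrated
two ways and merged: (1) candidates confidently labeled by read-backed
phasing — reads spanning the candidate and a germline het are scored
cis/trans/mixed under a Bayesian three-hypothesis model and Phred-scaled —
anchor precision–recall curves whose intersection gives a cutoff;
(2) the 96-trinucleotide spectra of candidates below each of 29 trial
cutoffs (0.1–0.8, step 0.025) are compared by cosine similarity, and
2-cluster hierarchical clustering finds where artifact admixture makes
the spectra diverge.  The final cutoff is the mean of the two, or the
cosine cutoff alone when the precision–recall curve is weak.

**Indels** are filtered by recurrence — an exclusion list of indels seen
at VAF > 0.15 in at least two unrelated individuals — plus removal of
1–2 bp insertions extending ≥ 5 bp reference homopolymers.  No classifier
is needed.

**Structural variants.** Per-1-kb read counts are divided by a coverage
panel of normals, segmented by an exact penalized least-squares dynamic
program (gamma = 100), and tested against the sample's own diploid
segments and the PON (one-sided z-tests).  Germline-het deviation of
allele frequency, DAF = |VAF − 0.5|, is binned, segmented the same way,
and combined with VAF-distribution modes: loss = coverage loss + DAF
> 0.45; gain = coverage gain + elevated DAF + modes near 1/3 and 2/3;
cnLOH = DAF > 0.45 with diploid coverage.  GRIDSS-style breakends are
paired, classified by orientation, and filtered by the published DAF /
copy-ratio / junction-count / size rules before integration with the CNV
segments.

A first-class synthetic-data module (`ptascrub.simulate`) generates
phased hets, labeled candidates, coverage/DAF profiles, and indels with
the statistical structure the method assumes, so the whole pipeline is
testable without sequencing data.

## Worked example

```python
from ptascrub.simulate import (simulate_candidates, substitutions_of,
                               linkage_categories_of)
from ptascrub.classifier import train_rf, artifact_probabilities
from ptascrub.cutoffs import pr_based_cutoff, cosine_based_cutoff, final_cutoff

variants, features, truth = simulate_candidates(400, 400, 1.0, seed=7)
bundle = train_rf(features, (truth.labels == "artifact").astype(int), seed=7)
print("OOB balanced accuracy:", round(bundle.oob_balanced_accuracy(), 3))

probs = artifact_probabilities(bundle, features)
cutoff = final_cutoff(
    pr_based_cutoff(linkage_categories_of(variants), probs),
    cosine_based_cutoff(substitutions_of(variants), probs),
)
print("cutoff:", cutoff.final_cutoff, cutoff.method_used)
```

prints

```
OOB balanced accuracy: 0.98
cutoff: 0.2 cosine_only
```

Trained on 400 true somatic and 400 artifact candidates at the
generator's default separation, the forest separates the classes with
out-of-bag balanced accuracy 0.98.  Too few candidates reach a decisive
phasing score for the precision–recall route here, so the calibration
falls back to the cosine method and places the sample's cutoff at
p = 0.2; flagging every candidate above it keeps 384 candidates with
precision 1.0 and recall 0.96 against the generator's truth.

The command line mirrors the library:

```bash
ptascrub simulate --what coverage --out sim/ --seed 5
ptascrub sv --cov sim/sample.cov.tsv $(printf -- "--pon-cov %s " sim/pon*.cov.tsv) \
            --hets sim/hets.tsv --out svout
```

which recovers the simulated loss, gain, and cnLOH segments in
`svout.segments.bed` and writes the integrated calls to `svout.svs.tsv`.
`ptascrub snv` and `ptascrub indel` run the corresponding workflows from
VCF/BED/TSV inputs.

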