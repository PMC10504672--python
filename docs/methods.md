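# Methods

This note documents the models, parameter choices, and numerical details
behind `ptascrub`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Allelic imbalance

PTA amplifies the two haplotypes of a region unevenly, so the B-allele
frequency (BAF) of germline hets drifts smoothly along a chromosome.  A
true somatic variant lies on one haplotype and should show a VAF
consistent with that local drift; an artifact need not.

Germline hets are restricted to sites heterozygous in the control sample
and carrying a dbSNP-style identifier, then oriented by haplotype: allele
depths of sites phased `1|0` are swapped, so the oriented BAF of every
site refers to the same haplotype.  The local BAF at a candidate is
predicted by weighted least squares of degree 2 over all oriented hets
within **200 kb**, with weights = tricube(distance / window span) × total
allele depth.  The published procedure fixes the degree and the depth
weighting but not the kernel or span; we use a tricube kernel whose span
covers all in-window points (classical loess defaults).  With fewer than
**min_hets = 10** informative sites the feature is undefined and the
candidate is routed to a fallback forest.  The prediction is clamped to
[0.001, 0.999] (1/1000 is far below any realistic depth resolution) so
the subsequent test is always defined.

The candidate's alt/total depths are tested against the predicted BAF
with an exact two-sided binomial test, two-sided by point-probability
summation (the common exact-binomial convention; the direction of
deviation is not prescribed).  The natural log of the p-value is the
classifier feature.  Degenerate inputs (zero depth) yield an undefined
result rather than a sentinel value.

## Read-backed phasing (linked reads)

Reads spanning a candidate and a nearby germline het are counted cis
(both alt or both ref) or trans (one of each).  Counts per germline site
are scored under three hypotheses with expected cis-read fractions
1−ε / ε / 0.5 (cis / trans / mixed); per-site binomial likelihoods are
multiplied across sites under a uniform prior, and the score is
−10·log₁₀(1 − max(P(cis), P(trans))), capped at 3000.  ε defaults to
**0.005** (allele-observation error; configurable).  The mixed
hypothesis, with cis fraction 0.5, is what makes chimera-like artifacts
score near zero.  Scores below 100 label a candidate "false positive",
above 1000 "true variant", between them "uncertain"; candidates with no
spanning reads are uninformative.

A consequence of this parameterization is that each concordant read adds
only ≈ 3 dB of evidence against the mixed hypothesis, so at typical
30–60× depths a clean candidate's score plateaus near 60–200 — below the
"true variant" threshold.  The precision–recall cutoff route (below)
therefore rarely finds a confidently-true group on simulated data and
the sample cutoff falls back to the cosine route, which is exactly the
fallback the method prescribes for samples with too few linkage-labeled
true variants.  The phasing score still contributes by labeling
confident artifacts (score < 1).

## The 26-feature classifier

Feature families: allelic-imbalance log-p (1), pyrimidine-strand mutation
type (1), sequence context at positions −10..−1 and +1..+10 (20),
distance to nearest gene (1), distance to nearest simple repeat (1),
transcriptional strand (1), replication timing (1) — 26 in total, the
only decomposition of the published feature families consistent with
per-position context encoding.  Purine-reference variants are
reverse-complemented (context reversed) so the representation is
strand-symmetric.  Overlapping gene annotations resolve strand by
distinct-union (plus+minus → both) and replication timing by the median.
Distances are 0 inside a feature, capped at 10⁷ bp and log₁₀-transformed
for split stability.

The forest: 500 trees, 4 variables per split, out-of-bag scoring.
scikit-learn's trees split on ordered values only, so categorical
features (mutation type, strand, context bases) are ordinal-encoded;
this keeps the matrix at exactly 26 columns, and with fully grown trees
the vote fraction equals the artifact probability.  Rows lacking the
allelic-imbalance or replication-timing value are excluded from
training; the majority class is subsampled to 1:1 before fitting (class
balance was found decisive for training quality).  Two fallback forests
— without AI (25 features) and without AI and RT (24) — are trained on
the same rows and used at scoring time for candidates whose features are
undefined; their probabilities are strongly rank-correlated with the
full model's on rows where all apply.

Feature importance is impurity-decrease (Gini); the ablation curve
retrains after repeatedly dropping the least-important feature and
reports out-of-bag balanced accuracy, (TPR + TNR)/2, per feature count.

## Cutoff calibration

*Precision–recall route.* Candidates with phasing score ≥ 1000 (likely
true) or < 1 (likely artifact) form a labeled subset.  Over the 101-point
grid c = 0, 0.01, …, 1, "p < c" predicts true; the cutoff is the grid
point where precision and recall cross (argmin |precision − recall|,
ties to the lower cutoff, grid points with no positive predictions
skipped since precision is undefined there).  The precision reached at
the crossing is kept as the route's quality; below 0.7 the route is
distrusted.

*Cosine route.* For the 29 trial cutoffs 0.1–0.8 (step 0.025) the
96-channel spectrum of candidates with p below the cutoff is computed
(at least **30** candidates must sit below the lowest cutoff, else the
route abstains).  The 29×29 cosine-similarity matrix is clustered
(complete linkage, Euclidean distance on the similarity rows — the
similarity-profile embedding makes Euclidean distance meaningful) into
two clusters; the highest cutoff in the cluster containing the
0.1-cutoff group is returned.  Because group membership is *p < c*, the
first grid point at or above a probability gap is still uncontaminated,
so the returned cutoff sits at the gap's upper grid point.

*Merge.* Mean of the two cutoffs when both exist and the PR quality is
≥ 0.7; otherwise the cosine cutoff alone.  If only the PR cutoff exists
and is strong it stands alone; if neither exists the pipeline refuses
and asks for a manual cutoff (`--cutoff` on the CLI).

## Indels

Artifact indels recur across unrelated individuals.  The exclusion list
collects indels at VAF > 0.15 (after each individual's own germline
removal) and keeps keys seen in ≥ 2 individuals, with sample/individual
counts and frequencies.  Keys are canonical left-aligned forms — the
pure inserted/deleted sequence after suffix/prefix trimming, rotated
left through the reference — so equivalent VCF representations always
collide.  Additionally, 1–2 bp insertions of a single repeated base
whose run in the reference (both flanks of the insertion point combined)
reaches **5 bp** are removed; the run is counted on the reference only,
and deletions and multi-base insertions are exempt.  No classifier is
trained for indels: recurrence filtering alone was found more effective.

## Structural variants

*Coverage.* Per-1-kb counts (GC normalization accepted from upstream)
are total-normalized to the PON, divided by the PON per-bin means, and
doubled into copy-number units.  PON bottom/top 1% bins and bins within
1 Mb of centromeres or chromosome ends are excluded.  100-kb median
copy numbers are segmented; boundaries snap to the nearest boundary of a
1-kb-resolution segmentation (capped at half the shortest segment so
snapping cannot erase one).

*Segmentation.* Exact dynamic programming minimizing SSE +
gamma·σ̂²·(#breakpoints), with σ̂ the scaled median absolute first
difference (floored at 10⁻¹²  so noiseless input still pays a positive
per-breakpoint price).  This makes the published gamma = 100 unitless
and scale-free; the DP is verified against exhaustive enumeration in the
tests.

*Tests per segment.* The within-sample reference is the top 25% of
segments with mean copy number closest to 2; z = (segment mean − reference
mean)/reference SD of per-bin values, one-sided normal p in the
direction of the deviation ("sample p").  The same construction against
the PON's per-bin copy numbers in the segment gives the "PON p".
Candidates require sample p < 0.05 **and** PON p < 0.2.  Degenerate
zero-variance references leave the segment undetermined.

*DAF.* DAF = |VAF − 0.5| per germline het, meaned in 100-kb bins and
segmented with the same engine; crude boundaries snap to the nearest het
with DAF within **0.1** of the segment mean within 200 kb (the snap
tolerance is ours; "similar DAF" is not quantified in the source).  Two
segmentations are kept: all hets (losses, cnLOH) and hets with
DAF ≤ 0.45 (gains), since amplification dropout creates artificial LOH
that would otherwise inflate gain evidence.  VAF modes per segment come
from a Gaussian KDE (Silverman bandwidth, 512-point grid); maxima below
10% of the peak density are suppressed; ≥ 20 hets are required.  Note the
0.45 LOH threshold is stated alongside "VAF < 0.1 or > 0.9", which would
correspond to DAF 0.4; the stated 0.45 is implemented.

*States.* loss = coverage-loss candidate with segment DAF > 0.45;
gain = coverage-gain candidate with DAF above the sample mean and modes
within 0.33 ± 0.12 and 0.66 ± 0.12; cnLOH = DAF segment > 0.45 with no
overlapping coverage candidate; everything else neutral/undetermined.

*Breakends.* BND records are paired by MATEID and classified by
orientation ((+,−) DEL, (−,+) DUP, same-sign INV, cross-chromosome CTX);
records without a mate are flagged, not fatal.  Filters: breakend-PON
(positions recurring within 2 kb in ≥ 2 individuals); DUP removed if
local DAF < 0.18 or copy ratio < 2.5; DEL removed if DAF < 0.4 or ratio
> 1.5 (local values over the interval between breakpoints, ±10 kb for
single ends); in the 15x coverage class, breakends in bins with > 100
reads removed; inversions need two junctions and ≥ 1 kb; single-junction
inter-chromosomal events removed unless within 100 kb of a called CNV
(rescuing unbalanced translocations).  Junction grouping for the
two-junction rules pairs same-class junctions whose ends co-locate
within 2 kb (or the event size).  Integration: CNVs stand on
coverage+DAF evidence regardless of breakends; a surviving DEL/DUP
junction matching a CNV merges into it; surviving balanced events are
emitted on breakend evidence alone.

## Synthetic data: what it emulates and what it does not

The generators define fixed study conditions (all overridable):
sequencing depth Poisson(30); het density 0.8/kb; per-1-kb bin counts
Poisson around mean 50 on a shared two-frequency sinusoidal "wave" that
the PON division removes; true-somatic VAF ~ Binomial(depth, 0.5)/depth;
artifact VAF ~ Binomial(depth, q)/depth with q ~ U(0.1, 0.4), reflecting
the sub-clonal appearance of amplification errors (no explicit artifact
VAF model is published; this is a parameterized stand-in).  True
substitutions draw their trinucleotide channel from a clock-like,
CpG-enriched spectrum; artifacts from a packaged T>C/C>T-enriched
constant standing in for the universal PTA artifact signature.  True
variants sit nearer genes and replicate later; a separation parameter
interpolates the two class distributions down to identity at 0.
Informative phasing evidence is simulated for ~20% of candidates with
~18 spanning reads each (concordant for true variants, coin-flip for
artifacts).  CN profiles place hets at VAF success probabilities 0.5
(CN 2), 1/3 or 2/3 (CN 3), and 0.02/0.98 (loss and cnLOH).

What passing tests show: the operations implement their definitions
exactly (oracle-verified for the binomial test and the segmentation DP);
the pipeline recovers labels and CN states when the data follow the
assumed distributions at realistic effect sizes.  What they do not show:
performance under real PTA error processes (context-dependent chimera
rates, mappability artifacts, GC waves not shared with the PON,
cell-cycle coverage structure), nor calibration of the absolute artifact
probabilities on real genomes.  The generator's classes are
conditionally independent given the label within each feature family,
which is more favorable than reality.

Acceptance-scale choices: labeled sets of 400+400 candidates, one 20-Mb
chromosome with three 1.5-Mb aberrant segments for CN-state recovery,
and a 10-Mb genome for the end-to-end run — sizes at which every
statistic the tests assert is far from its decision boundary.  The
CN-state layout keeps the aberrant fraction near 20% because the gain
rule compares a segment's DAF with the sample average; a mostly-aberrant
toy genome would inflate that average in a way no real sample does.

## Known limitations

* The linkage-score parameterization cannot reach the published
  "true variant" threshold at realistic depths (see above); cutoff
  calibration therefore leans on the cosine route.
* GC normalization of raw counts is accepted from upstream; the internal
  fallback is median-ratio correction, not a full GC model.
* The breakend caller consumes GRIDSS-style BNDs; it does not discover
  junctions from reads.
* Multi-allelic sites are split and filtered per alt allele; phased
  multi-nucleotide events are not reassembled.
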