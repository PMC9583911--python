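# Methods

## Problem setting

Given shotgun metagenomic reads from several individuals sampled at multiple
skin sites and timepoints, find for each individual a DNA marker — a contig
from their resident skin microbes carrying strain-private variants — together
with an abundance decision rule, such that an unknown sample can be assigned
to its donor, or to an explicit *unlabeled* outcome when the donor is not in
the cohort. No reference genomes, alignments to databases, or taxonomic
profiles are used; everything is computed from k-mer content and read
recruitment.

## Module 1 — data preparation

Samples are described by a TSV manifest (sample, individual, body site,
timepoint, FASTQ paths). QC removes a sample when its read count is strictly
below `max(median/10, absolute_min_reads)` (both knobs exposed; the absolute
floor defaults to 0), or when its body site is on an exclusion list (sites
dominated by environment/habit rather than host, e.g. plantar sites). The
retained samples are split 70/30 per individual, rounding toward the training
side; for each target individual the negative class (everyone else's training
samples) is undersampled without replacement to `round(ratio × positives)`
(ratio default 2.0), drawn round-robin across the other individuals so no
single person dominates the negative set.

## Module 2 — individual-specific k-mers

Canonical 31-mers are counted per sample: every N-free window contributes one
count to the lexicographic minimum of the window and its reverse complement
(k odd, so no self-complementary k-mers). Keys seen fewer than `min_count = 3`
times ("more than twice") are discarded as sequencing error. Counts are
normalised by the sample's total retained occurrences to give frequencies
n_i(j) ∈ [0, 1]; the matrix over positive and negative samples is the union of
per-sample key sets, with logical presence `f_i(j) > 0`. K-mers absent from
more than 80% of positives **and** 80% of negatives are removed as
uninformative ("highly sparse").

Each remaining k-mer is a one-feature classifier in one of two directions —
presence ⇒ positive, or absence ⇒ positive — scored by ASS, the mean of
sensitivity and specificity; the better direction is kept, ties going to
presence (a usable fingerprint must be detectable in its donor). K-mers with
ASS ≥ θ₁ are *individual-specific*; θ₁ defaults to 0.80 and may be set
per-individual (0.8–0.9 is the practical range; noisier data warrants the
stricter value). K-fold cross-validation (default 6 folds, stratified so each
validation fold keeps both groups) re-scores fold-detected k-mers on the
held-out fold; the secondary validation threshold defaults to ASS ≥ 0.8.
`evaluate_on_grouping` applies the same re-scoring to arbitrary partitions
(timepoints, body-site strata) to quantify temporal and spatial stability.

The "6-fold leave-one-out" phrasing in the source describes standard 6-fold
cross-validation (per-fold detected-k-mer counts are in the tens of
thousands, impossible under leave-one-out); that is what is implemented.
Absence-direction k-mers are recorded but not carried into marker assembly:
a fingerprint contig must be sequencable from the donor's own reads.

## Module 3 — marker assembly, quantification, selection

Reads containing at least `min_hits = 3` distinct specific k-mers (exact
canonical match, either strand — the k-mer equivalent of mismatch-free
alignment) are recruited from the donor's training samples and assembled with
a single-k canonical de Bruijn unitig assembler (`k_asm = 31`): k-mers below a
coverage floor of 2 are dropped (singleton error nodes), and maximal
non-branching paths become contigs, emitted canonically and ordered longest
first. Recruited sets are small clusters around variant loci, so non-branching
compaction suffices; an external assembler's FASTA can be substituted through
`load_contigs_fasta`. Contigs shorter than 100 bp are suppressed.

Abundance is RPKM = mapped reads / (contig length in kb × library size in
millions), the library size being the sample's total read count (a
panel-relative denominator would be degenerate for one-contig panels). Mapping
is exact k-mer containment: by default a read maps to a contig only when
**every** 31-mer window of the read occurs in the contig — equivalent to
end-to-end alignment with zero mismatches, which is what the marker logic
requires: a read overlapping the variant position with the other allele must
not count. An integer `min_shared_kmers` relaxes this to partial sharing when
a tolerant pseudo-alignment is wanted. A multiply-matching read goes to the
contig sharing most k-mers (ties: lexicographically first contig id). Per-base
depth profiles normalised per million reads support log₁₀(coverage + 1)
heatmap export.

Candidates with mean training RPKM strictly greater than 0.01 in the donor's
samples are ranked by mean validation AUC over the same stratified folds
(AUC computed by the rank/Mann–Whitney formulation, ties counted half); ties
are broken by longer contig (longer fingerprints are more specific in larger
populations), then contig id. For the selected contig, each fold's ROC is
scanned on a threshold grid of step 0.001 from 0 to the maximum observed
RPKM, classifying positive at RPKM ≥ t; the optimal threshold is the grid
point minimising the Euclidean distance of (sensitivity, 1−specificity) from
(1, 0), ties to the smallest threshold, and the fold optima are averaged.
Thresholds are computed on each fold's training portion and AUC on its
validation portion (the source does not specify; the training portion has
more samples and gives a stabler grid optimum). The scan is implemented
sparsely — sensitivity and FPR are step functions changing only at observed
values, so only the smallest grid point of each inter-value interval is
evaluated — which is exactly equivalent to the dense scan at any RPKM scale.

## Module 4 — identification tree

The tree asks one question per donor, reusing the fingerprint's fixed ROC
threshold (thresholds are *not* re-learned; only the question order is
chosen). At each node the remaining attribute minimising
`Gini_index(D, a) = Σ_v |D^v|/|D| · Gini(D^v)` with `Gini(D) = 1 − Σ p_k²`
over the two branches (RPKM ≥ / < threshold) is selected; ties are broken by
higher above-branch recall of the attribute's own donor, then donor id. The
above branch is committed as that donor's leaf even if impure (the impurity is
reported, not re-split); the below branch recurses, and when attributes are
exhausted the single unlabeled leaf terminates the chain, so each donor
appears exactly once per root-to-leaf path. If a node's sample subset empties,
the remaining attributes are appended in donor-id order — Gini is undefined on
empty sets, and every fingerprint must stay on the path so every donor remains
identifiable. Evaluation reports a predicted × true confusion matrix (the
unlabeled row counts as an error for in-cohort samples), per-donor precision
and recall, and overall accuracy.

## The cohort simulator

The simulator emulates exactly the structure the method exploits and nothing
more: one uniform-random resident genome (default 50 kb) shared by all
donors, per-donor haplotypes differing only by private variants (default 5
SNVs + one 1-bp indel), and shared uniform-random background genomes (default
two of 30 kb); reads are fixed-length (101 bp), uniformly placed, strand-
random, with an optional substitution-only error model and an optional
log-normal per-sample depth multiplier (default off: the reference conditions
use flat 20× coverage; σ > 0 exists to exercise the QC filter). Ground truth —
each donor's private canonical 31-mers — is computed by brute-force k-mer set
difference between the haplotype and every other genome, so tests assert exact
recovery rather than estimates. Planted loci are separated by at least three
read lengths: each locus then yields its own contig, no read spans two loci,
and every full-length window of a marker contig overlaps the variant, making
non-donor reads unmappable under mismatch-free containment. Out-of-cohort
samples use a fresh haplotype with its own private variants placed away from
all cohort loci, sharing the backgrounds.

What the simulator deliberately omits: repeat structure and shared
inter-genome homology (uniform random sequence makes 31-mers unique with
overwhelming probability), realistic community composition and taxon
abundance distributions, indel sequencing errors, GC/coverage bias, and
strain mixtures within one donor. Passing tests therefore demonstrate the
pipeline's correctness and its robustness to substitution noise and depth
variation — not performance on real skin metagenomes, where k-mer collisions
between related strains and uneven species abundance will lower ASS values
and shrink marker sets.

## Numerical and design notes

- 2-bit packed 62-bit integer codes for 31-mers; numeric order equals
  lexicographic order, so canonical = min(code, rc-code). Exact counting —
  cohort scale here does not warrant sketches.
- The frequency denominator is the sample's total retained *occurrences*
  (making n_i(j) a true frequency); logicalisation downstream is unaffected
  by this choice.
- Determinism: every stage derives its seed from the run seed and the stage
  name (CRC-based, < 2³¹), so staged re-execution from serialized artifacts
  is bit-identical to a full run; simulation seeds each sample's read stream
  independently of generation order.
- Degenerate inputs: empty k-mer tables, partitions missing a group, folds
  without positives, contigs below the coverage floor and ROC scans with
  inverted groups all either warn and return empty results or fail with the
  offending stage and item named.
- Reference conditions used by the acceptance tests and `scripts/acceptance.py`:
  6 donors × 4 sites × 2 timepoints (48 samples, ~22 k reads each), error-free
  for exact-recovery checks, plus 0.5% substitution error at θ₁ = 0.9 for the
  robustness replicate. These sizes keep a full end-to-end run at roughly one
  to two minutes on a single CPU while leaving every per-locus statistic far
  from its detection floor.

## Known limitations

- The unitig assembler is single-k with no bubble popping or scaffolding;
  markers from low-complexity or repetitive regions would fragment.
- Mismatch-free full-read containment is conservative: at error rate e only
  ≈ (1−e)^L of a donor's reads map, scaling RPKM (and thresholds) down by the
  same factor — harmless for classification, but RPKM values are not
  error-rate-invariant.
- ROC thresholds sit just above the training negatives' maximum (smallest
  zero-distance grid point); with overlapping RPKM distributions the margin
  can be thin. The tree inherits whatever margin selection produced.
- No multiple-testing control on per-k-mer ASS scores; detected sets on weakly
  separable cohorts contain chance discoveries, which the validation-fold
  re-scoring quantifies but does not remove.
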