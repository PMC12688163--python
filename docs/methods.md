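# Methods

## Problem and labelling model

Homologous recombination deficiency (HRD) leaves characteristic scars across
a tumour genome: copy-number instability, loss of heterozygosity, and
mutational-signature shifts (SBS3, ID6).  The package classifies breast
tumours as HRD-positive or -negative from whichever combination of three data
blocks is available — total copy number (CNA), allele-specific copy number
(ASCN) and somatic SNVs/indels (SNV) — using BRCA1/2 inactivation as the
training gold standard.

A sample is labelled HRD-positive when a pathogenic BRCA1/2 event (germline
mutation, somatic mutation, or BRCA1 promoter hypermethylation) co-occurs
with LOH of the same gene; HRD-negative when all four mutation flags are
explicitly negative or when neither gene shows LOH; unknown otherwise.
Positive clauses take precedence.  Two deliberate readings are documented in
`labelling.py`: missing flags never satisfy the "no detected mutations"
clause (missingness cannot manufacture negatives), and methylation without
LOH on either gene falls through to the negative no-LOH clause, which is
logged when it happens because the rule text leaves the case genuinely
ambiguous.

## Features

**CNA block.** Six summary scores of the total-CN profile — cna_burden
(altered fraction of the covered autosomal genome), cna_load (altered-segment
count), MACN (mean altered copy number), a tandem-duplication score and mean
TD-region size (local-maximum gains ≤ 10 Mb), and a chromothripsis score
(chromosomes with a ≥ 10-segment two-state CN oscillation) — plus six CX
copy-number-signature exposures (CX1–5, CX9).  The published score names come
with one-line descriptions rather than formulas, so the definitions here are
documented re-derivations; each is pinned by a brute-force oracle test, and
every threshold (altered margin 0.1 absolute CN, TD length cap 10 Mb,
oscillation minimum 10) is a keyword argument.  Scores are computed on
merged profiles (`merge_adjacent`), making them invariant to how a caller's
segmentation fragmented the genome.  CX quantification itself is out of
scope: exposures are accepted precomputed (the production path) or, for
synthetic data, refit by NNLS against a CX catalogue.

**ASCN block.** The three genomic scar scores, their sum (scarHRD,
conventional positivity cut-off 42), and eight allele-specific CN-signature
exposures (CN1, 2, 6, 7, 8, 9, 11, 17) refit by NNLS from the 48-channel
allele-specific catalogue (heterozygosity state × total-CN class × length;
the channel list ships as a data file).  Scar definitions follow the cited
primary literature: LOH counts sub-chromosomal minor-allele-zero regions
longer than 15 Mb; TAI counts allelic-imbalance regions touching a covered
chromosome end without crossing the centromere (no size floor; slack 0 bp —
both exposed as config); LST counts arm-wise breakpoints between ≥ 10 Mb
segments (gap ≤ 3 Mb) after removal of segments < 3 Mb, where smoothing
extends the larger neighbour and arms split at the centromere midpoint.

**SNV block.** SBS96 and ID83 catalogues are built from mutation tables with
flanking sequence (supplied or extracted from a FASTA), then refit by NNLS
against fixed signature catalogues, keeping 12 breast-cancer SBS signatures
(SBS1, 2, 3, 5, 6, 8, 13, 17b, 18, 20, 26, 30) and ID1–ID18 as candidates.
The ID83 binning convention (repeat units counted including the indel's own
copy; microhomology as the longest flank overlap, capped at length−1) is
defined by the shipped channel file, and a generator can produce an exemplar
variant for every channel, giving an exhaustive 83-channel round-trip test.
DNVs fall outside both schemas and are tallied as unclassifiable.  Exposures
default to the counts scale; per-sample normalisation to the classifiable
mutation count is a switch.

## Normalisation and selection

Each feature is transformed within each cohort as z = (x − mean x)/sd x with
x = ln(feature + 1) (sd with n−1).  Constant features become all-zero with a
warning.  At prediction time a cohort of ≥ 20 samples is normalised within
itself; smaller cohorts reuse stored training parameters (warned), since
within-cohort statistics are undefined for single samples.

Screening is a per-feature two-sided Wilcoxon rank-sum test (positive vs
negative samples; exact for ≤ 25 per group without ties), dropping features
with p > 0.05, deliberately without multiplicity correction — the screen is a
permissive first pass.  Pruning then removes one member of any within-block
pair with |Pearson r| > 0.8, processed by descending |r|; the automated rule
drops the larger-p member, and a manual-override list (shipped default:
`td_region_size`, `SBS2`) reproduces judgement-based removals.

## Models and training

Seven registry configurations: CNA (9 features), ASCN (CNA + 5 ASCN
features = 14), SNV (16), SNV+CNA (25), SNV+ASCN (30), plus no_scarHRD (13)
and scarHRD_only (1).  The published per-model decision thresholds
(0.382/0.450/0.344/0.296/0.374) are carried as reference metadata only; a
fresh training run always calibrates its own threshold.  The registry's
per-block retained-feature lists are a documented default (which candidates
survive screening is cohort-dependent) and can be overridden by a custom
registry file.

The base learner is a 500-tree random forest (mtry = ⌊√p⌋, min leaf 1, no
resampling — imbalance is handled by the threshold, not the sampler).  The
semi-supervised wrapper is Yarowsky-style self-training.  Two loop variants
are implemented:

* **relabel (default).**  Each round fits the forest on labelled plus
  currently pseudo-labelled samples, re-scores the whole unlabelled pool,
  admits every sample whose class-max probability reaches the confidence
  floor (0.5 by default, i.e. every prediction), and refreshes all
  pseudo-labels; iteration stops when the pseudo-labelling stabilises or at
  `max_iter` (40).  Original labels are immutable.
* **incremental.**  The never-revise scheme: grow the pseudo-labelled set by
  confidence-ranked batches (`batch_fraction`, default 10% of the pool per
  iteration) until `stop_fraction` (70%) of the pool is consumed.

The relabelling variant is the default because simulation shows the
incremental scheme systematically *hurts* a random-forest base learner: the
most confident samples are the spatially extreme ones, so confidence-ordered
admission trains intermediate forests on boundary-free subsets, degrades
them, and freezes the resulting mistakes.  On the two-Gaussian benchmark
(d = 10, per-feature shift 2, 20 labelled + 400 unlabelled) the relabelling
loop gains about two accuracy points over supervised-only while the
incremental loop loses five to nine, a failure shared by other incremental
implementations of the same idea.  Both variants are deterministic given the
seed.

Threshold calibration is leave-one-out cross-validation over the labelled
samples (the unlabelled pool is available to every fold), followed by a scan
of candidate thresholds at midpoints between consecutive sorted unique
probabilities plus the 0/1 boundaries; the smallest threshold attaining the
maximum F1 for the positive class is kept, and calls at exactly the
threshold are positive.

## Evaluation

ROC AUC follows the Mann–Whitney convention (ties count half).  PR AUC uses
step-wise integration over achievable operating points, whose uninformative
baseline equals the prevalence P/(P+N).  Confusion metrics report TP/FN/FP/TN
over labelled samples (unknown-status samples are tallied separately) with
sensitivity, specificity, precision and MCC.  Gene-association testing uses
two-sided Fisher exact p-values with Benjamini–Hochberg FDR; odds ratios are
the Haldane-corrected cross-product (0.5 added to every cell when any is
zero), a closed-form convention that deliberately differs from
conditional-MLE estimators in some packages.  Copy-number states code
loss/neutral/gain as −1/0/1 (CN < 2, = 2, > 2) and unfold into
loss-vs-neutral and gain-vs-neutral binary contrasts.

## Synthetic cohorts

The genome-level generator plants scar events on a diploid baseline at
class-conditional Poisson rates — defaults: LOH 17 / TAI 18 / LST 20 for
HRD-positive tumours (scarHRD-scale sum ≈ 55, above the 42 cut-off) versus
5/6/7 for HRD-negative — and draws mutation channel counts from
class-conditional signature mixtures (HRD-positive enriched for SBS3 and
ID6) at WES-scale burdens (lognormal, median 100 SNVs / 15 indels).  Each
planted event is placed with an 11 Mb clearance so it scores exactly once
under its own metric; event types still interact (an interstitial LOH region
necessarily contributes two large-scale transitions), so per-score
round-trip checks plant only one event type, and the truth record stores the
counts actually placed.  Evidence flags exercise all positive labelling
clauses (germline + LOH two-thirds of the time, methylation + LOH
one-third); masking to unknown status is independent of class.

The feature-level generator emits ln-Gaussian features with per-block class
shifts (CNA 0.5, ASCN 0.9, SNV 0.6 sd units), chosen so that information
accumulates across blocks — the nested models' accuracy then rises with each
added block, mirroring the multi-modal design — and so that every planted
feature is individually detectable by the screen at screening-scale n.  What
the synthetic cohorts do **not** model: correlated features within a block,
cohort batch effects, purity/ploidy estimation error, subclonality, and any
realistic chromosomal architecture; passing tests demonstrate the pipeline's
internal correctness and statistical behaviour, not clinical performance on
real tumours.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale: LOOCV with self-training refits
the wrapper once per labelled sample, so cohorts of 100–200 samples with
40–60-tree forests and `max_iter` 6–8 are used in the test suite and the
acceptance script; the published-scale cohort (1404 samples, 500 trees) is
the library default but is not exercised in CI-sized runs.  NNLS is solved
by active-set (scipy); exposures are exactly recovered on noiseless synthetic
mixtures.  Ties in the threshold scan resolve to the smallest candidate;
ties in pseudo-label confidence resolve in stable input order.  Degenerate
inputs have pinned contracts: empty segment tables score zero (warned), a
profile with no altered segments reports MACN = 2 (the neutral sentinel),
and constant features are rejected at training time.

## Known limitations

The CNA score formulas are re-derivations of one-line published
descriptions; absolute values will differ from the original scoring
routine's, so only within-cohort ordering is meaningful.  CX exposures are
validated pass-through, not a re-implementation of the published mixture-
model encoding.  The registry's retained-feature lists are a plausible
default, not a recovered ground truth.  Survival modelling, pCR logistic
models, PCA visualisation and comparisons that require running external WGS
classifiers are out of scope.
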