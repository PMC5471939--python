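# Methods

## Problem and representation

The package addresses binary hepatotoxicity (DILI) classification of small
molecules from 2-D structure alone. Each compound is represented by an 881-bit
PubChem-type substructure fingerprint; the bits encode, in fixed public section
ranges, hierarchic element counts (0–114), ring-system counts (115–262), atom
pairs (263–326), atom nearest-neighbor patterns (327–459) and SMARTS patterns
(460–880). Fingerprints are ingested from the PaDEL-Descriptor CSV dialect
(`Name,PubchemFP0,…,PubchemFP880`); the package does not recompute them, since
the bit definitions belong to the PubChem/PaDEL specification, not to this
method. Compound identity for dataset merging is string equality of RDKit
canonical SMILES, and label contradictions between sets remove *both*
conflicting records — the conservative reading of "eliminate contradictions".
Compounds whose fingerprints cannot be produced upstream (typically >1000 Da
natural products) are expected to be absent from the CSV; missing-compound
handling is a dropped record with a logged count, never a hard error.

## Substructure scoring

For bit *j* with class counts `c_SP[j]` (positives carrying the bit) and
`c_SN[j]`, the conditionals are Laplace-smoothed with pseudo-count *k* over the
two outcomes present/absent:

    P(S|pos) = (c_SP + k) / (N_pos + 2k),   P(S|neg) = (c_SN + k) / (N_neg + 2k).

Class priors are the empirical frequencies N_pos/(N_pos+N_neg) (a
`smooth_priors` flag applies the same pseudo-count to them; off by default
because class counts are two orders of magnitude larger than per-bit counts).
Bayes' rule yields P(pos|S), and the score is L = log2(P(pos|S)/P(neg|S)).
Base-2 logarithms are used throughout. The default k = 1 is classic add-one
smoothing; k = 0 is permitted only when no bit is degenerate (absent from, or
present in, an entire class), otherwise the error message directs the user to
k > 0.

Worked reference point: N_pos = 180, N_neg = 132, c_SP = 90, c_SN = 11, k = 1
gives P(S|pos) = 91/182 = 0.5, P(S|neg) = 12/134, P(pos|S) ≈ 0.8839,
L ≈ 2.929. The unit suite verifies this against an independent implementation
that literally appends k pseudo-observations per outcome and counts.

## Weighting

Bits with L ≥ θ (ties included) are *selected*; their weight is w = n·L, all
others keep w = 1, and the weight vector multiplies the 0/1 matrix
element-wise. θ must be positive (θ = +∞ is the no-weighting sentinel), which
guarantees every weight is positive. Amplifying by the thresholded score
itself, rather than by a flat constant, preserves the ranking of selected bits
inside the weighted representation; a flat multiplier or the raw (non-log)
posterior odds would select the same bits and differ only in relative
magnitudes. Only positively associated bits are weighted: the screen's loss
function is asymmetric (a missed hepatotoxicant is worse than a false alarm),
so negative-association information is deliberately left at weight 1.
Defaults θ = 1.5, n = 15 correspond to the best cross-validated cell observed
for the forest in this kind of data; the grid search exists precisely so users
re-select them per dataset (default grids θ ∈ {0.5, 1, 1.5, 2, 2.5},
n ∈ {5, 10, 15, 20}).

## Similarity kernel

Binary Tanimoto is intersection-over-union; for weighted (non-negative real)
vectors the continuous generalization T = a·b/(‖a‖²+‖b‖²−a·b) is used — the
standard extension that reduces *exactly* to the binary form on 0/1 input
(both variants share one arithmetic path, so the reduction is bit-exact, which
the unweighted-identity test exploits). Two all-zero vectors get similarity 0
with a warning. One algebraic property worth stating precisely: a single
global scale factor applied to every bit cancels (T(c·a, c·b) = T(a, b)); the
kernel is sensitive only to *non-uniform* per-bit weights — which is exactly
how fingerprint weighting reshapes the similarity space — and to rescaling one
vector relative to another.

## Classifiers and decision rule

*Random Forest*: scikit-learn, 500 trees, √d feature subsampling, score =
fraction of trees voting positive. Because each weight rescales one binary
column by a positive constant, the set of achievable axis-aligned splits is
unchanged; with identical seeds, weighted and unweighted forests build
identical partitions (asserted in the suite). Any practical benefit of
weighting for tree ensembles must therefore come from implementation quirks or
stochastic variation, not geometry; the package records both weighted and
unweighted results rather than asserting an improvement for RF.

*SVM*: C-classification on the precomputed Tanimoto kernel (default C = 1),
probability scores by the library's Platt mapping, seeded. With
`kernel_variant="continuous"` the kernel is built from the weighted rows —
here weighting genuinely moves the decision boundary; `"binary"` builds it
from the raw 0/1 fingerprints.

*Decision cutoff*: the largest c such that the fraction of calibration
positives with score ≥ c meets the target sensitivity (default 0.8), i.e. the
⌈target·N_pos⌉-th largest positive calibration score; classification is
score ≥ c → positive. Calibration scores are out-of-bag votes (RF) or inner
5-fold cross-validated probabilities (SVM), not resubstitution scores, to
avoid optimistic cutoffs. Note a consequence: the policy *intends* to leave up
to 1−target of positives below the cutoff, so even a perfectly separable
dataset shows accuracy near 0.9, not 1.0, under the calibrated cutoff —
ranking (AUC) is the right lens for separability, and the suite asserts
AUC = 1 there.

## Evaluation protocol

Stratified, seeded 10-fold cross-validation. By default the weight vector is
re-estimated inside each training fold; computing weights once on the full
dataset before CV is a leakage (held-out compounds inform their own features)
and is available only behind the explicit `global_weights_leakage` flag as a
comparison experiment. Grid cells share one fold split. Metrics: AUC-ROC
(rank statistic, ties ½ — verified against an all-pairs concordance oracle),
AUPR (average-precision step rule; PR integration conventions differ, this is
the standard step sum), and confusion metrics at the model's cutoff; both
pooled-over-held-out and per-fold/fold-mean values are reported since
conventions vary. Independent-test evaluation freezes weights and cutoff from
training and refuses compound-ID overlap unless explicitly overridden.

## Synthetic data generator

`SyntheticSpec` draws independent Bernoulli bits: a chosen causal subset fires
at rate `p_causal_pos` in positives vs `p_causal_neg` in negatives; all other
bits fire at one background rate in both classes. Defaults (180 positives,
132 negatives, 881 bits, 10 causal bits at 0.6 vs 0.1, background 0.1, k = 1)
mirror a realistically imbalanced small training collection with sparse
fingerprints. `expected_log_odds` supplies the population score
L = log2(p₁·π_pos) − log2(p₀·π_neg) that the empirical estimator converges to.
Compound IDs embed the generator seed so independent draws never collide by
identity.

What the generator does *not* emulate: real fingerprint bits are strongly
correlated (nested substructure definitions, element-count hierarchies),
classes differ in overall bit density, and causal structure in real data is
many weak, overlapping signals rather than ten clean planted bits. Passing the
synthetic benchmarks therefore demonstrates correctness of the machinery —
counting, smoothing, ranking, kernel algebra, calibration, fold hygiene — not
real-world predictive performance. Published real-data figures for this kind
of pipeline (CV accuracy ≈ 0.73–0.74, AUC ≈ 0.77–0.79; independent-test
accuracy ≈ 0.60) require externally retrieved pharmaceutical datasets that are
not packaged, and nothing in the test suite claims them.

## Numerical and statistical choices

- Problem sizes in tests and the acceptance script (e.g. 200+200 compounds for
  recovery, 60+60 for null CV, 5000/class for consistency, 20 replicates) are
  chosen so each Monte-Carlo check has comfortable power while the whole suite
  runs in well under a minute of compute.
- Null calibration asserts the grand mean of L against its own Monte-Carlo
  standard error (4·SE band) rather than a fixed constant.
- Large-sample consistency is asserted on the *mean* absolute deviation from
  theory (causal bits and all bits < 0.1 at n = 5000/class); a per-bit maximum
  still carries ≈ 0.06 sampling standard deviation per bit at that n, so a max
  criterion at 0.1 would fail by chance about half the time and is not a
  statement the data can support.
- Exact float round-tripping of weight tables uses `%.17g` on write and
  round-trip parsing on read, so persisted models reproduce predictions
  bit-identically.
- All stochastic components (fold shuffles, forests, Platt scaling, the
  generator) are seeded from a single user seed per run.

## Known limitations

- Alert descriptions ship at section-range granularity ("ring system bit
  PubchemFP137"); per-bit SMARTS text from the external fingerprint
  specification can be supplied by the caller as an annotation mapping.
- The continuous Tanimoto kernel is not guaranteed positive semi-definite for
  arbitrary weighted inputs; no PSD repair is attempted (the SVM tolerates the
  mild violations seen in practice).
- Multi-class DILI severity (most/less/no concern) is out of scope; labels are
  binary.
- Fingerprint computation from SMILES is not provided — the PaDEL CSV is the
  ingestion contract.
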