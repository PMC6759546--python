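# Methods

## Problem and model

Replication origins differ from background sequence in how guanine and
cytosine are distributed: the GC skew (f_G − f_C)/(f_G + f_C) tends to
switch sign around the initiation site, and origin regions are often
AT-rich overall. The package treats origin prediction as binary
classification of whole variable-length candidate regions, with a feature
encoder built specifically around this skew structure.

### Three-window partition

A length-L sequence is split at η = ⌈Lε⌉ and ξ = ⌈Lδ⌉ into front
[1, η], middle [η+1, ξ] and rear [ξ+1, L] windows (1-based inclusive; all
coordinates in user-facing messages follow this convention). The ceiling
is applied to the product L·ε rounded to 9 decimals first, so that exact
grid fractions are not pushed upward by binary floating point (40 × 0.15
must give η = 6, not 7). A split that leaves any window empty is an error
naming the window, not a silent adjustment.

### k-GCC composition

Sequences are reduced to {G, C, \*} with \* = A or T, because only the
G/C structure carries the signal of interest; this also shrinks the
k-tuple vocabulary from 4^k to 3^k. Each window's composition is the
normalised count of its overlapping k-tuples (window-local: tuples never
cross window boundaries). Word order is fixed as the base-3 expansion with
C = 0, G = 1, \* = 2, most significant position first; any fixed order
would do, this one is documented so feature indices are reproducible
across runs and versions.

### Skew correlation tiers

For tier j ∈ {1…λ}, tuples are taken every j positions from the window
start: with m = ⌈(len − k)/j⌉ there are m + 1 tuples, and
θ_j is the mean of their GC skews Θ = (n_G − n_C)/(n_G + n_C). Numerical
conventions, chosen once:

- a tuple with neither G nor C has Θ = 0 (the definition is 0/0 there; a
  G/C-free tuple is naturally skew-neutral and this keeps θ_j finite);
- the terminal tuple is truncated at the **window** end (the tier
  arithmetic is per-window, so truncating at the sequence end would leak
  across windows);
- when j > k a nominal start position can fall past the window end
  entirely; such a tuple contributes Θ = 0 while the divisor m + 1 is
  kept, consistent with the empty-tuple convention;
- a window no longer than k is a single truncated tuple.

λ is capped by min(η, ξ−η, L−ξ); parameter sets violating the cap for a
given sequence raise an error listing L, η and ξ rather than clamping, so
a parameter combination means the same thing for every sequence it is
applied to.

### Joint normalisation

Per window, φ_f = f_u/(Σf + w·Σθ) and φ_θ = w·θ_j/(Σf + w·Σθ); since
Σf = 1 the normaliser is 1 + w·Σθ. Because the tiers within a window all
estimate roughly the same window-level skew, Σθ ≈ λ·(window skew), and for
C-rich windows with large λ and w the normaliser can reach zero or below.
This is raised as an explicit error (the message suggests lowering w or λ)
instead of silently emitting sign-flipped "frequencies"; the grid search
logs and skips such combinations. Near-zero normalisers also amplify
component magnitudes, which is why float comparisons in the test suite use
1e−12 relative to component (or block L1) magnitude with 1e−12 absolute
for order-one values — plain absolute tolerance is below double-precision
resolution for those blocks.

The feature vector is [f-block, θ-block] × (front, middle, rear),
dimension 3·(3^k + λ). At w = 0 it collapses to the plain per-window
k-GCC composition with zero θ components. The 4-letter three-window k-mer
baseline (dimension 3·4^k) is kept for comparison experiments.

## Classifier and ensemble

Base learners are scikit-learn random forests with 600 trees, √d feature
subsampling, min_samples_leaf 1, min_samples_split 2 and gini impurity —
the published configuration for this predictor family. A predicted
probability is the mean of per-tree class-probability estimates (the
library's convention), not a hard-vote fraction; tests pin this contract
against per-tree extraction.

The ensemble fuses exactly ten members, each a forest over a different
encoder parameter set, selected as the top ten of a grid search over
ε ∈ {0.15…0.50} step 0.05, δ ∈ {0.55…0.85} step 0.05, k ∈ {3…7},
λ ∈ {1, 4, 7, 10}, w ∈ {0.1…1.0} step 0.1 (11 200 combinations), each
scored by stratified 5-fold CV and ranked by AUC with accuracy as
tie-break. Grid search evaluates single predictors, not ensembles: the
ensemble is assembled only from the winners.

Fusion weights live on the probability simplex (q_i ≥ 0, Σq = 1) so the
fused score ß = Σ q_iP_i remains a probability; ß > 0.5 (strictly) calls
an origin. The weights are fitted by a small real-valued genetic
algorithm: population 50, 100 generations, tournament selection (size 3),
blend crossover, Gaussian mutation (σ = 0.05), Euclidean projection back
to the simplex after every variation, elitism, fixed seed. The uniform
vector and all ten one-hot vectors are injected into generation 0, so the
returned weights are never worse than the plain mean or any single member.
The fitness is the AUC of the fused **out-of-fold** member probabilities
under the same 5-fold split used for member scoring; AUC was chosen over
accuracy to avoid coupling the weight search to the 0.5 threshold.

Model bundles persist as a directory with a JSON manifest (format version,
weights, per-member parameters, seeds, CV scores) plus joblib-serialised
forests; a load must reproduce predictions bit-identically, which the
tests check.

## Evaluation protocols

Sn, Sp and Acc are one minus the respective error rates; MCC uses the
error-rate reformulation

    MCC = [1 − (FN/N⁺ + FP/N⁻)] / √[(1 + (FP−FN)/N⁺)(1 + (FN−FP)/N⁻)]

which is algebraically identical to the textbook covariance form (the
tests verify this exhaustively for all confusion matrices up to 20
samples). When a predicted class is empty the denominator vanishes; MCC is
then reported as 0 with an explicit degeneracy flag. AUC is the rank-based
ROC area with midrank ties, equal to the normalised Mann–Whitney U.

The jackknife (leave-one-out) protocol retrains the supplied pipeline for
every held-out sample and pools the left-out scores. Two determinism
guarantees are enforced: fixed seeds make repeated runs identical, and
training rows are put into a canonical order (label, then lexicographic
feature bytes) before each fit — forest bootstrap draws are index-based,
so without this the result would depend on dataset row order. Inside each
jackknife fold nothing from the held-out sample is used; when the full
ensemble is evaluated this way, member forests and fusion weights are
re-derived from the N−1 training samples (weights from a 5-fold split of
those samples), the conservative no-leakage reading.

## Synthetic data

The generator emulates the statistical structure the encoder targets, not
yeast biology. Defaults: lengths uniform on [250, 1000] bp, GC content
0.38 (yeast-like), skew magnitude s = 0.6, and a 0.1 A/T enrichment in the
middle third. Positives sample each position with P(G) = (m/2)(1+s),
P(C) = (m/2)(1−s) in the 5′ half and the roles swapped in the 3′ half
(m = the local G+C mass), producing the sign-switching skew; negatives use
s = 0. The A/T mid-enrichment is applied to **both** classes so that at
s = 0 the classes are distributionally identical and the skew switch is
the only class signal.

What passing tests on this generator do show: the encoder recovers a
half-switching skew of the stated magnitude from variable-length
sequences, the pipeline is calibrated (AUC ≈ 0.5 on null data), and power
rises with effect size. What they do not show: performance on real
origins, which carry ARS consensus motifs, replication-timing structure,
chromatin context and non-i.i.d. composition that the generator does not
model. The published benchmark datasets (S. cerevisiae 340/342,
P. pastoris 305/302) are external downloads; re-running the jackknife on
them is a documented manual check, not part of the test suite.

## Problem sizes and defaults in the automated runs

The test suite and the acceptance script scale the experiments to desk
size as the package's own defaults for quick verification: discrimination
checks use 200+200 sequences with 300-tree forests, the jackknife
benchmark 30+30 with 100-tree forests, the effect-size monotonicity check
100+100 over five seeds, and grid-search demonstrations use the documented
reduced grid. The published-scale settings (600 trees, full 11 200-combo
grid, jackknife over the full benchmark) remain the library defaults.

## Known limitations

- The GC-skew tiers are correlated with each other and with the window
  composition; large λ adds little information and increases the risk of
  normaliser degeneracy.
- Weight optimisation by GA on out-of-fold probabilities can still overfit
  when members are highly correlated; the simplex constraint and the
  injected uniform baseline bound the damage.
- Per-tree OOB bookkeeping for permutation importance reconstructs
  bootstrap indices via scikit-learn's internal helper (with a local
  fallback); a future sklearn change could require updating that shim.
- Ambiguous IUPAC bases are mapped to an A/T-equivalent wildcard in
  non-strict mode; sequences dominated by ambiguity codes should be
  rejected upstream.
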