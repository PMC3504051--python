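# Methods

## The classification model

The semi-naïve Bayesian (SNB) classifier scores each feature f — a
(descriptor, bin) pair for binned numeric descriptors, or a
(descriptor, level) pair for categorical keys — with the
Laplacian-corrected log-likelihood ratio

    s_f = ln( ((A_f + 1) / (T_f + K)) / P ),   K = 1/P,

where T_f is the number of training compounds showing the feature, A_f
the number of those labelled desirable, and P the desirable-class prior.
The stabilizer K = 1/P gives two properties the model relies on: a
feature never seen in training is exactly neutral (s_f = 0), and the
score's sign tracks whether the feature's desirable rate exceeds the
prior. A compound's total score is the sum over its features;
classification is by sign, with an exact zero conservatively classed
undesirable (for continuous data a zero total has negligible
probability). Unseen key levels at prediction time contribute 0 — they
are no-data features, not errors.

"Semi-naïve" means features need not be single descriptors: a composite
key concatenates several measurements into one categorical level, so the
model assigns an independent score to every observed combination. The
shipped ring-topology key joins ring-bond, aromatic-bond and
ring-assembly counts (`11_11_1` = fused aromatic bicycle); the
functional-group key is a presence/absence bit string over a SMARTS
catalog; and numeric descriptors can be joined on the fly (the
atoms × polar-surface-area key used in the interdependency analysis).
This is what lets an additive model represent an XOR selection pattern
that no independent-descriptor model can.

## Featurization and binning

Continuous descriptors are discretized into 5 equal-frequency bins whose
edges come from the training portion only; values outside the training
range clamp into the end bins. Count descriptors keep their raw integer
levels while the training data show at most 25 distinct values — this
matters, because equal-frequency edges computed on a mostly-zero count
column all coincide at zero and would otherwise collapse the descriptor
into a single useless bin. Numeric components of on-the-fly joint keys
use 10 quantile bins rather than 5: joint levels subdivide the data, and
the finer component resolution is what lets the key localize an
interaction boundary; with ~3,700 compounds a 10 × 10 grid still leaves
double-digit counts per cell for the Laplacian correction to stabilize.
A constant descriptor degenerates to one bin with a warning and scores
zero everywhere.

## Cross-validation

All model quality is the mean area under the ROC curve (rank-based,
ties counted 1/2) over a 4-fold batch jackknife: the 8 survey batches
are paired as {1,2}, {3,4}, {5,6}, {7,8}; each fold trains on six
batches (bin edges recomputed from those batches only) and tests on the
held-out two. Fragments deliberately duplicated across batches can
appear on both sides of a fold — that is a property of the survey design
being emulated, not leakage, and it is why random selectors draw an
independent answer per *presentation* (see below). Folds whose test
labels are one-class are skipped with a warning.

Because the SNB total score is additive over descriptors, the search
engine featurizes and scores each single descriptor once per fold and
evaluates any candidate subset by summing cached score vectors; this is
algebraically identical to training the subset from scratch.

## Forward feature-subset selection

Candidates are all single descriptors plus combinations (up to 4
descriptors) of descriptors that pass an enrichment screen
(single-descriptor CV ROC > 0.6). Two curation rules keep the candidate
list in the low hundreds and the winner's ROC honest: (i) descriptor
pairs whose rank correlation exceeds 0.7, plus a short curated exclusion
list (atom count vs molecular weight, TPSA vs fractional TPSA, the ring
key vs the aromatic-ring count, …), are never combined — they measure
the same property; (ii) only the single best enriched descriptor per
parameter-class signature enters combinations. Evaluating thousands of
combinations would inflate the selected model's cross-validated ROC
through selection bias and admit spurious parameters.

Selection walks parameter counts greedily: the best (N+1)-count model
replaces the best N-count model only when its mean ROC improves by
strictly more than 0.009 (a 1e-12 epsilon guards the boundary against
float artifacts: a printed gain of exactly 0.009 must not count). A
local-minimum guard then compares the selected model to the global best
over all evaluated candidates; if the global best is more than 0.009
better, the walk is re-run without stopping at the first flat step. Ties
prefer fewer descriptors, then lexicographic order. The class of the
best one-parameter model is the primary parameter; remaining classes of
the selected model are secondary.

## Random-forest validation

An orthogonal check trains a balanced forest per selector: 500 CART
trees (Gini), depth ≤ 20, ≥ 10 samples per node, √p split candidates,
each tree grown on a bootstrap of n_min draws per class (majority class
down-sampled). Descriptors enter independently — no joint keys — since
trees encode interactions structurally. Importance is the percent of
internal split nodes using each descriptor, averaged over 3 seeded
trials × 4 jackknife training sets, standardized to z-scores across
descriptors within the model, and thresholded at z > 2.1.

Two numerical choices make this importance signal work:

* **Panel width.** With p descriptors of which k carry signal, the
  z-score of a signal descriptor is capped near √((p−k)/k); flagging
  four parameter classes at z > 2.1 is arithmetically impossible with a
  16-descriptor panel. The shipped panel therefore has ~70 descriptors,
  most of them narrow substructure or element counts that are rarely
  split on — they form the flat background against which the few
  signal-bearing descriptors stand out.
* **Chance-split pruning.** Unconstrained deep trees keep splitting on
  label noise after the signal is exhausted, spreading split counts
  uniformly and washing out the contrast. Splits are therefore
  pre-pruned unless their weighted Gini gain exceeds 6e-3. This value
  was calibrated on the rule-based simulated selectors — the weakest
  pruning at which every ground-truth class separates above the 2.1
  cutoff with predictive accuracy unchanged — the same way the 2.1
  cutoff itself was originally established.

The class of the top-z descriptor is the primary RF parameter; classes
of other descriptors above the cutoff are secondary. RF importance is
expected to include correlated extras (e.g. molecular weight tracking
atom count); recovery is asserted as a superset, not an exact set.

## Consensus and awareness statistics

Binary selection vectors are compared with the modified Tanimoto
similarity S_MT = ((2−p)/3)·S₁ + ((1+p)/3)·S₀, where S₁ = a/(a+b+c) is
agreement on selections, S₀ = d/(d+b+c) agreement on rejections, and p
the mean selection fraction of the two vectors; a component with a zero
denominator counts as perfect (vacuous) agreement so that any vector is
similarity 1 with itself. Consistency compares a selector's first and
second responses over duplicated fragments; consensus compares selectors
pairwise over co-evaluated fragments, with missing entries dropped
pairwise.

Consensus voting labels a fragment consensus-good (or -bad) when at
least 75% of evaluators agree; the cultural consensus model is then fit
on the high-agreement subset. The CCM implementation is the informal
match-matrix variant: raw match m_ij = fraction of co-answered items
with equal responses, chance-corrected for two response options as
m* = 2m − 1, factored by one-factor minimum residual (diagonal replaced
by iterated communalities; 25 iterations, tolerance 1e-6). First-factor
loadings, clipped to [0,1], are the per-respondent estimated consensus.
A single shared response pattern is declared when the first-to-second
eigenvalue ratio exceeds 3 *and* no loading is materially negative
(< −0.1): two complementary answer blocks also produce a dominant
factor, but with mixed-sign loadings, and must not be called one
culture. A vanishing second eigenvalue reports the capped sentinel 1e6.

Agreement on parameters uses exact statistics: upper-tail binomial tests
against uniform-choice nulls (1/9 for one of nine observed parameters;
1/C(9,2) for parameter pairs), one-tailed (positive-association) Fisher
exact tests between model-identified and self-reported parameters, and a
two-tailed paired t-test on parameter counts. No multiple-testing
correction is applied, matching the analysis being reproduced.

## The synthetic study

The generator decorates ~80 ring scaffolds with ~60 substituents
(seeded random draws, canonical-SMILES deduplication) to produce unique
fragments in the 150–300 Da window — the lower bound excludes
solvent-sized molecules that no screening library would contain. Small
polar substituents are drawn with double weight and the scaffold list is
rich in aza-heterocycles and polar cores, emulating the polarity-
enriched composition of a property-filtered fragment archive; the
resulting library has its atom-count median at 15 and its TPSA median
near 55 Å², so the strategy selectors' thresholds (15 atoms, 60 Å²)
split both attributes near-evenly and the two attributes are nearly
uncorrelated (Spearman ρ ≈ 0.13). These distributional targets were set
against the generator's own statistics; they are what make the XOR
strategy genuinely marginal-free, mirroring the study conditions in
which that contrast was established.

Batches: 3,700 fragments are split into 8 batches with 227 fragments
assigned to two distinct batches each (batch sizes within ±1 after
duplication; per-batch presentation order shuffled). Rule-based
selectors hold a fixed per-fragment opinion and flip each *presentation*
independently with 5% probability, so duplicated fragments probe
self-consistency. Random selectors draw an independent Bernoulli answer
per presentation: a random selector has no opinion to remember, and a
per-fragment draw would let the batch jackknife memorize duplicated
fragments through rare key levels, biasing the random-ceiling estimate
upward.

The shipped rule-based selectors use 1–4 conjunctive criteria spanning
size, polarity, ring topology and functional groups, with thresholds
placed where each clause genuinely filters the library; the 4-rule
selector combines milder property cutoffs with a substructure exclusion
(no aliphatic ether) so its conjunction still passes a substantial
fraction of fragments — a conjunction passing only a few percent would
leave the 5% label noise dominating the positives. Self-reports are
fabricated as ground truth plus a configurable number of distractor
classes (default 6), emulating respondents who report far more criteria
than their selections reflect.

What the generator does not emulate: real chemical-archive composition
and QC filtering, inter-chemist heterogeneity of *values* within a
parameter (all rule selectors share thresholds rather than individual
preference curves), fatigue/order effects, and any novelty/IP signal
(that class is defined but has no descriptor). Passing recovery tests
therefore show that the pipeline identifies what a rule-governed
selector does under realistic noise — not that it would decode any
particular human chemist.

## Problem sizes and runtime

The test suite builds two studies: 600 fragments for per-module
integration tests and the full 3,700-fragment study for the end-to-end
recovery, ceiling, interdependency and consensus checks. The full suite
runs in about 90 seconds; the acceptance script (library generation,
nine random selectors, full-panel cross-validation) in under 30 seconds.

## Known limitations

* The equal-frequency binning convention and the 10-bin joint-key
  resolution are defensible defaults, not uniquely determined choices;
  both are configurable.
* Ring-assembly counting treats fused and spiro systems as one assembly
  per connected ring-bond component; other toolkits' conventions differ.
* The redundancy screen (|ρ| > 0.7 plus a curated list) does not cover
  numeric-vs-key descriptor pairs; class-ambiguous descriptors whose
  variance aliases another class (e.g. sp³ fraction vs aromatic ring
  content in fragment-sized space) are excluded from the panel instead.
* The CCM is the informal eigenvalue method; the formal Bayesian model
  is out of scope.
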