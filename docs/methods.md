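# Methods

## Model

The classifier is a *filter chain*: an ordered list of binary features
x₁…x_L, each coded 1 = pathogenic-leaning. A variant walks the levels in
order; the first level with xᵢ = 0 exits it as Neutral (exit level i), and
surviving every level yields Pathogenic (exit level L+1). The final label is
the conjunction ∏xᵢ, hence identical for every ordering of the same feature
set; orderings differ only in where neutrals exit. The chain is a degenerate
decision tree — every neutral branch is terminal — and we deliberately do
not generalize to branching trees.

### Discretization

* **SPP** = 1 iff at least one of SIFT/PolyPhen/PROVEAN calls the variant
  pathogenic. PolyPhen "possibly damaging" counts as pathogenic by default
  (configurable through the call-code maps). A missing classical call is a
  precondition violation: such variants are removed by the training filter,
  never silently imputed.
* **ExAC**, **COMMON** = 1 iff the respective allele frequency is ≤ the
  threshold (default 10⁻⁴ for both nodes) *or* the variant is uncatalogued.
  The boundary value sits on the pathogenic side, consistent with "neutral
  only above the threshold". Missing frequency → 1 is a deliberate
  asymmetry: rarity is exactly what absence from a population catalogue
  suggests. Each imputation is recorded in the feature vector's provenance
  map so reports can quantify it. This asymmetry is also why
  allele-frequency features are barred from the root when inducing chains:
  variants from under-sequenced populations would be misrouted at the first
  level with no later chance of rescue.
* **NDamage** = 1 iff ≥ 5 of up to nine damage predictors call the variant
  pathogenic. Missing calls count as not-pathogenic (they lower the tally)
  rather than rescaling the cutoff — simpler, and monotone in added
  evidence. The roster of nine predictors is configurable; the cutoff 5 is
  the reference value.
* Auxiliary screened variables (domain overlap, transition/transversion,
  charged/uncharged and hydrophobic/hydrophilic amino-acid class crossings
  using the standard biochemical partitions {D,E,K,R,H} and
  {A,V,L,I,M,F,W,C}, plus pass-through flags) are implemented for screening
  but not used by the reference chain.

### Label harmonization

Clinical-significance strings are mapped with a `LabelPolicy`: numeric codes
2/3 → neutral, 4/5 → pathogenic (textual synonyms Benign/Likely_benign and
Likely_pathogenic/Pathogenic are translated to the numeric codes first).
Multi-valued fields resolve to a class only when *every* code falls on one
side; any mixture or unrecognized code (e.g. 0, "uncertain significance")
yields unlabeled. This is the conservative choice: ambiguous records are
excluded rather than risked as label noise. Training filters retain
non-synonymous variants with all three classical calls and a resolved
label, applied sequentially so removal counts per criterion sum to the
input size.

## Chain induction

`build_greedy` scores, at each level, every remaining candidate by the
whole-dataset accuracy of the provisional chain (an optional held-out
validation set can be scored instead; the trace additionally records
accuracy restricted to level survivors for diagnostics). The maximizer is
appended; ties break on the lexicographically smallest feature name. The
root is restricted to a caller-supplied set and is always placed — a chain
has length ≥ 1 — while the strict-improvement stopping rule applies from
level 2 (other stops: `max_depth`, default 4, and candidate exhaustion).
The builder is fully deterministic.

`exhaustive_best` enumerates every root-restricted ordered selection of
1..depth candidates (refusing > 6 features) with the same tie-break
(accuracy, then shorter, then lexicographic). It exists as the builder's
oracle: greedy accuracy can never exceed it, and on class-conditionally
independent features they agree. Note that all *full-depth* orderings of
one feature set tie exactly (conjunction), so the exhaustive winner among
them is decided by the tie-break; recovery tests therefore compare the
greedy chain to the planted order and to the exhaustive *accuracy*, not to
the exhaustive ordering.

## Evaluation protocol

Confusion cells are named from the clinic's perspective (True/False
Neutral, False/True Pathogenic). Primary rates condition on the *true*
class, so each class's pair sums to 1. The literal
sensitivity/Type I/specificity/Type II formulas that normalize within
predicted rows are reported alongside under `paper_formula_*`; the two
views disagree under class imbalance and conflating them is a known source
of confusion, so both are always computed. Zero denominators yield NaN,
never 0.

* **10-fold CV** stratifies by class: each class is permuted with the seed
  and split into 10 folds (sizes within one); iteration i tests on the
  union of the i-th folds. A fixed topology is evaluated as-is; a builder
  callable is refitted on the training folds.
* **Monte Carlo** draws `round(0.3·n)` variants uniformly *without*
  replacement per replicate (1000 replicates by default) — a "sample of
  30%" is subsampling, not bootstrap; a bootstrap mode sits behind a flag.
  Samples are not stratified by class. With fraction 1.0 every replicate is
  the full set and the spread is exactly zero.
* Replicate/fold spread uses the population standard deviation
  (denominator n); configurable should a sample-based estimate be wanted.
* **φ coefficient** is computed from the 2×2 table,
  φ = (n₁₁n₀₀ − n₁₀n₀₁)/√(n₁•n₀•n•₁n•₀), equal to the Pearson correlation
  of the indicators (cross-checked against scipy in the tests); degenerate
  margins are NaN and flagged, not zeroed.
* **Per-level reports** classify with each chain prefix and report
  accuracy, false-pathogenic rate among true neutrals and false-neutral
  rate among true pathogenics, as percentages. Along any chain the
  pathogenic set only shrinks with depth, so the false-pathogenic rate is
  non-increasing and the false-neutral rate non-decreasing — a structural
  invariant the tests enforce.

All resampling randomness flows from a single integer seed through
numpy's `default_rng`.

## Synthetic data

The generator draws a class per variant from a prevalence, then each
annotation independently from class-conditional distributions: Bernoulli
pathogenic calls per classical predictor; a catalogued/uncatalogued mixture
for each allele frequency with a log-uniform frequency draw when
catalogued (so the 10⁻⁴ threshold induces an exactly computable binary
rate); independent Bernoulli calls for nine damage predictors; Bernoulli
auxiliary flags; optional per-field missingness. Output is ordinary
`AnnotatedVariant` records consumable by the full pipeline, byte-reproducible
from the seed.

Class-conditional independence makes
P(chain = pathogenic | class) = ∏ᵢ P(xᵢ = 1 | class) exact;
`expected_confusion` evaluates it in closed form (Poisson-binomial dynamic
programming for the damage count, log-uniform CDF plus uncatalogued and
missing mass for the frequency features) and is the module's central
oracle against simulation. Real annotation variables are *not*
independent — the two population-frequency features in particular are
strongly associated — so an optional coupling parameter can tie the two
catalogued statuses for correlation-sensitivity experiments; the closed
form requires the coupling to be zero and says so.

Two presets define the study conditions:

* `demo_clinvar_like_config` (n = 30,000, 57% pathogenic, matching the
  class balance of a curated non-synonymous training set): class-conditional
  rates chosen so the reference chain lands near 91% correct among neutrals
  and 92% among pathogenics — the per-class pattern this family of
  classifiers shows on curated data. With independent features the
  real data's full marginal structure cannot be matched simultaneously
  (correlations are absent by construction), so this preset is a
  demonstration of the evaluation machinery, not a reproduction claim.
* `planted_chain_config` (n = 20,000, balanced): pathogenic-class rates
  uniformly 0.995 and neutral-class rates 0.50/0.55/0.60/0.65 along
  SPP-ExAC-NDamage-COMMON, giving strictly ordered separabilities where
  each level strictly improves accuracy on the survivors; used for
  induction-recovery tests. The frequency parameters for a target rate are
  solved analytically (range anchor 10⁻⁶), the damage-count rates by
  inverting the binomial tail.

Passing tests on these presets show the pipeline's arithmetic and the
induction logic are correct under the stated generative assumptions; they
do not certify performance on real cohorts, where feature correlations,
annotation biases and label noise all bite.

## Problem sizes and numerics

Default test and reproduction sizes — 30,000-variant main cohort, 20,000 ×
20 seeds for induction recovery, 200,000 × 10 random configurations for
oracle agreement — were chosen so every stochastic check sits at ≥ 3
standard errors of headroom while the whole suite runs in about a minute.
Stochastic assertions use 3σ (4σ for loose missingness checks) bands around
closed-form expectations, all with fixed seeds. Percentages are reported at
one decimal in human-readable output and full precision in JSON.

## Known limitations

* Linear chains only; no branching trees, no probabilistic scores (AUROC is
  meaningless for a hard classifier and deliberately absent).
* The generator does not emulate realistic genome positions, sequence
  context, or the marginal distributions of any real database.
* External-cohort numbers (accuracies/rates computed on curated public
  releases) are inputs we do not ship; the package evaluates whatever
  labeled table it is given.
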