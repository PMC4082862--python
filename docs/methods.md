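# Methods

This note records the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Identification filtering

PSMs are consumed as the tabular export of a SEQUEST-style database search;
the package never touches spectra.  The acceptance chain is:

* **Xcorr gate** — thresholds 1.9 / 2.3 / 2.6 for charge 2 / 3 / ≥ 4, all
  comparisons inclusive ("at least" semantics; the Xcorr boundary is taken
  inclusive by symmetry).  Charge-1 PSMs are gated at the charge-2 threshold:
  data-dependent MS/MS acquisition selects z ≥ 2, so this path is defensive,
  not calibrated.
* **Single-peptide rules** — a protein identified by one unique peptide
  additionally needs: peptide length ≥ 7; at least one spectrum with a run of
  ≥ 3 consecutive matched fragment ions (by default in *either* the b- or the
  y-series — the stricter both-series reading is a config switch); and ≥ 3
  PSM occurrences within at least one sample, counted among Xcorr-passing
  PSMs.  Proteins with ≥ 2 unique peptides skip these rules (`strict_paper_mode`,
  default on; off generalizes the rules to every PSM).  Accepted
  single-peptide proteins carry a `blast_confirmation_pending` flag: external
  sequence confirmation is recorded as an obligation, never executed.
* **Group presence** — keep proteins detected (count ≥ 1, evaluated on raw
  counts, before any offset) in ≥ ceil(0.30 · n) samples of at least one
  outcome group.
* Spectral count per protein and sample = number of kept PSMs mapped to the
  accession.  No shared-peptide parsimony is attempted; accessions are taken
  at face value.

## Normalization

Counts are offset by +1 so that "≤ 1 vs > 1" is a detection rule, then each
entry is rescaled by its sample's total offset count relative to the group
mean of those totals.  The formula as published multiplies by
`sample_sum / group_avg`, which scales deep samples *up*; the package
implements this verbatim as mode `as_printed` (the default, for fidelity) and
provides `depth_corrected` with the inverted ratio, which is almost certainly
the intended depth correction — under it, scaling one sample's counts by a
constant leaves its normalized values invariant up to the group-average
recomputation.  The inversion is surfaced as a mode rather than silently
fixed.  Group averages are always computed within the matrix being
normalized, so learning and validation series normalized separately use
their own averages.  "Group average" is read as the group mean of *sample
totals*, the only reading with consistent units.

## PLS-DA, target projection, selectivity ratio

PLS1 (NIPALS, X-only deflation) regresses the centered binary outcome
(regression = 0, persistence = 1) on the column-centered protein matrix.
Columns are centered but not variance-scaled: spectral counts share one
scale; autoscaling is a switch.  The A-component model collapses onto the
target-projection component `w_TP = b/‖b‖`, `t_TP = X_c w_TP`,
`p_TP = X_cᵀ t_TP / (t_TPᵀ t_TP)`; at A = 1 this equals the first PLS
component up to sign.  Orientation is fixed so persistence samples have
positive mean score, making score signs comparable across runs.

Per protein, explained variance is `‖t_TP p_TP,i‖²` and residual variance
`‖x_i − t_TP p_TP,i‖²`; the selectivity ratio is their ratio signed by the
loading.  A protein exactly collinear with `t_TP` has zero residual; this is
reported as a flagged infinite-SR sentinel rather than a large number so that
downstream ranking is explicit about degenerate separability.

## DIVA test

The source literature defines the discriminating-variable test only by its
endpoints (CCR 50 % at chance, 100 % at separation); the computation here is
this package's operationalization.  Per variable, over `n_splits` seeded
stratified Monte-Carlo splits holding out ~25 % of samples (at least one per
group): the training part picks the threshold maximizing direction-free
balanced accuracy among midpoints of consecutive distinct sorted values plus
the two extremes (ties to the lower threshold); the held-out part is scored
with balanced accuracy under the fixed convention "value > threshold predicts
persistence"; CCR = 100 · max(m, 1 − m) over the split mean m, so the
separation direction is irrelevant and both endpoints are realized exactly.
Balanced accuracy makes unequal group sizes unable to inflate CCR.  Defaults:
`n_splits = 200`, holdout fraction 0.25.

The SR significance limit for a CCR objective is the smallest |SR| among
variables reaching the objective (+∞, nothing significant, when none does);
significance is |SR| ≥ limit.  Raising the objective can only raise the limit
and never adds significant variables.

**Input scale.**  The composed screen (`marker_screen`) evaluates CCR on the
*offset counts* while taking SRs from the normalized-data TP model.  The
per-variable classifier asks whether one protein's measured level separates
the groups; for presence/absence markers that question lives on the detection
scale, the same scale on which the single-variable ROC thresholds are defined
("≤ 1" = not detected).  Applying per-sample normalization factors first
turns the constant "absent" level into a sample-dependent value and blurs an
essentially binary pattern with depth noise, measurably weakening the test's
power to recover a planted 95 %/0 % discriminator.  `diva_test` and
`variable_ccr` remain matrix-agnostic for callers who want the CCR of
normalized or otherwise transformed variables.

## Double cross-validation

Outer loop: 5 stratified folds, 20 % held out, every sample out once.  Inner
loop: 4 stratified folds over the retained 80 %.  The only free
hyperparameter in the chain is the number of PLS components A; the inner loop
selects it from the grid 1..5 (capped by rank) by held-out misclassification
of the TP-score sign, ties to the smaller A.  The outer held-out predictions
are pooled into one CCR (never averaged per fold); the final A is the mode
over folds, ties to the smaller value.  Fold assignment that strands a single
class is reshuffled with the next seed (error after 10 attempts).  Identical
data, plan and seed give identical reports.  The supplied matrix is treated
as one pool; callers wanting per-series validation pass each series
separately.

## Threshold classifiers

* **ROC stump** — threshold maximizing Youden's J over midpoints of distinct
  sorted values plus the extremes, ties to the lower threshold; the direction
  makes regression the predicted class on the side with the higher regression
  rate.  Evaluated on offset counts, a pure presence/absence marker yields
  the "≤ 1 vs > 1" rule.  J = 0 marks the rule uninformative.  Youden's J is
  the standard single-number ROC criterion; nothing finer is specified by the
  source analyses.
* **Two-node tree** — exhaustive search over (protein, threshold) pairs
  maximizing Gini impurity decrease (CART's default impurity); ties break to
  the lexicographically lower accession, then the lower threshold.  A child
  stump refines the more impure root branch only if it further reduces
  impurity; depth never exceeds 2.  All proteins are ranked as root
  competitors by their best impurity decrease.  No pruning, surrogate splits
  or cost-complexity.
* **Logistic ranking** — per protein, a one-variable binary logistic fit
  (statsmodels, Newton iterations capped at 25), ranked by likelihood-ratio
  statistic against the intercept-only model.  Complete separation (disjoint
  group ranges, monotone likelihood) is detected up front and reported as a
  flag with infinite rank statistic instead of letting coefficients diverge;
  constant variables score zero.  Degenerate inputs never raise.

## Synthetic data

The generator emulates the study design: 20 regression + 20 persistence
samples, each group split 10/10 into learning and validation halves; 163
background proteins plus two planted discriminators for a 165-protein matrix.
Planted presence probabilities mirror the reported marker patterns: a
ZNF441-like protein present in 95 % of regression and 0 % of persistence
samples, a PLD6-like protein at 60 %/0 %, both with mean count 3 when
present.  Background proteins share a presence probability of 0.7 and mean
count 5 — typical of mid-abundance proteins in shallow single-run spectral
counting, where most catalog proteins are seen in most but not all runs with
single-digit counts.  Counts are negative-binomial with dispersion (size)
parameter 2, overdispersed as empirical spectral counts are; large dispersion
recovers the Poisson limit.  Per-sample depth factors are log-normal with
σ = 0.3, i.e. typical run-to-run total-count variation within roughly ×1.4
and occasional ×2 outliers, which is what makes the two normalization modes
distinguishable in tests.  Presence draws are floored at count 1 so presence
always leaves a detectable count.

What the generator does **not** model: correlated protein abundances
(co-regulation, shared peptides), batch structure beyond a scalar depth,
zero-inflation tied to abundance, or any relation between a protein's
catalog size and its counts.  Passing tests therefore show that the pipeline
recovers planted presence-pattern signal under realistic count noise and
depth variation — not that it would rank real markers identically in the
presence of correlated biology.

The PSM battery enumerates every rule boundary (Xcorr at and 0.01 below each
charge threshold, peptide lengths 6/7, ion runs of k−1/k, occurrences at and
one below the minimum, plus multi-peptide acceptance paths) and embeds the
expected outcome computed by an independent brute-force rule evaluator at
generation time, so filtering is always tested against an oracle that shares
no code with it.

## Numerical choices and problem sizes

Tolerances: unit-norm and identity checks at 1e−10; variance conservation and
SR oracle agreement at 1e−8 relative; CCR endpoint checks exact.  Monte-Carlo
test sizes are chosen to keep the full suite fast while leaving the asserted
margins wide: 50 replicates for the TP-score discrimination median, 100 for
DIVA recovery and the permutation null (40-protein matrices there), 200 for
the SR-ranking property (60 background proteins).  The enumeration oracle for
the DIVA CCR runs at n = 8, where all 16 stratified holdouts can be listed
exactly.

## Known limitations

* Spectral counts are treated per accession; shared peptides inflate multiple
  accessions simultaneously.
* The in-sample TP-score sign match (the score-plot discrimination figure) is
  an optimistic quantity by construction; the double cross-validation CCR is
  the honest counterpart, and on the default synthetic conditions (a single
  ~1-effect-size marker among 163 noisy proteins, n = 40) it is substantially
  lower — a realistic reminder that score plots overstate generalization.
* The exact fraction of correctly signed samples is always reported as
  computed; no rounding conventions are imposed on it.
* The DIVA operationalization is one of several consistent with the stated
  50 %/100 % endpoints; `n_splits`, the holdout fraction and the seed are
  exposed so alternatives can be compared.
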