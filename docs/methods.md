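# Methods

## The two grammars

A stimulus sequence consists of n category-A syllables followed by their n
paired category-B syllables (n = 2, 3 or 4; sequence lengths 4/6/8).
Category is cued by the vowel (A: e/i; B: o/u); pairing is defined by the
20-row lexicon table. The **nested** grammar reverses the pair order in
the B-part (A₁A₂A₃B₃B₂B₁), the **cross-serial** grammar repeats it
(A₁A₂A₃B₁B₂B₃). Pair identity is resolved by table lookup, never from
shared onset letters: the table contains onset-ambiguous entries (sted,
sek, schip all start with s), so an onset rule is unsound even though most
pairs do share a first letter.

Dependency structure is reported with links 1-indexed outermost-first
(nested) or leftmost-first (cross-serial), matching the A₁…Aₙ subscript
convention, while sequence positions are 0-based. "Intervening distance"
counts elements strictly between the linked positions: nested link i spans
2(n−i) elements (4, 2, 0 for n = 3), cross-serial links all span n−1
(2, 2, 2). The sum of distances is n(n−1) for both grammars — the grammars
differ in how distance is distributed, not in its total. An optional dummy
syllable can be inserted at the sequence midpoint, adding 1 to every
distance and removing the nested grammar's adjacent innermost pair; the
recognizer accepts a dummy-aware mode.

Membership recognition does not require the A-part pairs to be distinct
(with repeated pairs the two grammars can coincide), but all *generated*
stimuli use distinct pairs within a sequence: the foil templates index
three distinct pairs and repeats never occur in the printed materials.
This is an interpretation — the source design never states whether
within-sequence repeats were allowed — and is fixed here as a design rule.

## Design generation

**Counterbalance.** The generation algorithm was left open by the source
design; this package constructs, per length class and label cell, one
shuffled multiset per A-position containing each of the 20 A-syllables
exactly count/20 times, then repairs constraint violations (duplicate pair
within a row; sequence already used anywhere in the design) by swapping a
cell with a later row in the same column, which preserves column balance;
if no single swap repairs a row, generation restarts from fresh shuffles
(budget 200 restarts — in practice the first pass almost always succeeds).
This yields *exact* uniformity for A-syllables over positions (4 per
position per length class in learning, 3 per test cell in experiment 1, 6
in experiment-2 correct trials, 2 per foil subset). B-part occupancy is
derived, not targeted, so the nested grammar shows minor positional
imbalance in the B-part — a consequence of the reversal rule, reproduced
rather than corrected. Both phases are counterbalanced; whether the
original test phase was is ambiguous in the source description, and
counterbalancing both is the stricter reading.

**Uniqueness** is enforced on full sequence strings across learning + test
of one design. Since a grammatical sequence is determined by its A-part
and grammar, and nested/cross realizations of the same distinct-pair
A-part always differ for n ≥ 2, this is equivalent to per-grammar A-part
uniqueness, but the string-level set also covers the non-member S2/S3
foils uniformly.

**Foil subsets (experiment 2).** Each trained grammar has six foil
templates, two per subset, given as permutations (a_order, b_order) of a
pair triple. The two templates of a subset turn out to generate the same
string family — the second row is the first with the pair roles renamed —
so alternating them (20 + 20) is a bookkeeping convention, not a
distributional choice. S1 foils are members of the untrained grammar; S2
foils preserve the trained grammar's first dependency pair (position 0 and
its linked B position), S3 its last; all violate the trained grammar.
S2/S3 foils are members of *neither* grammar, so their
`grammar_of_sequence` field is none.

**Orders.** Experiment 1 uses one shared seeded order for all simulated
participants; experiment 2 draws a fresh presentation order per
participant (both matching the original procedures). Repeat probes are
flagged uniformly at random among learning trials at exactly
floor(0.25·240) = 60; probe performance is recorded but not analyzed.

## Simulated participants

The generative model for learners is **equal-variance Gaussian signal
detection**: evidence for a correct trial ~ N(+d/2, 1), for a foil
~ N(−d/2, 1), response yes iff evidence exceeds criterion c, hence
P(yes|correct) = Φ(d/2 − c) and P(yes|foil) = Φ(−d/2 − c), independent
across trials. This is deliberately the model under which the analysis
battery's d′ estimator is the matched estimator, so parameter recovery is
a meaningful end-to-end check of the whole pipeline. An optional
`learning_slope` adds a fixed increment to d per test-phase third,
exercising the block analysis; the default is flat sensitivity.

Strategists are deterministic: yes iff the first (last) link of the
trained grammar's dependency structure is intact in the presented
sequence. Guessers say yes with fixed probability regardless of content;
at yes_rate 0.5 their expected corrected d′ is 0 (chance), and at biased
rates d′ stays 0 while the criterion shifts (c → −Φ⁻¹(yes_rate)).

What the simulants do **not** emulate: trial-by-trial learning dynamics,
reaction times, attention lapses, mixtures within one participant, or any
actual grammar-induction mechanism. Passing tests therefore validate the
*analysis chain and design logic*, not any claim about human learners; no
simulant parameter is fit to human data, and the original human statistics
are not reproduction targets (the raw response data were never deposited).

## Analysis battery

d′ uses the 0.5 cell correction **unconditionally**: 0.5 is added to each
of hits/misses/false alarms/correct rejections for every participant
before rates are formed (not only when a cell is zero). This keeps all
quantiles finite — a perfect responder on 120 + 120 trials scores
d′ = 2·Φ⁻¹(120.5/121) ≈ 5.28 — at the cost of a small shrinkage toward 0
that vanishes with trial count. d′_first (d′_last) keeps the hit rate from
all correct trials and restricts the false-alarm rate to the S2 (S3)
foils, the reading under which only the error rate is strategy-specific.

Block d′ splits each participant's own presentation order into three equal
consecutive thirds (120 trials per block in experiment 1, 80 in
experiment 2); length d′ partitions experiment-1 test trials by sequence
length. One-sample t-tests use Cohen's d = mean/sd; the between-group
test is the pooled-variance t (df = n₁+n₂−2, matching the df conventions
of the original analyses).

The 2 × 3 mixed ANOVA is computed from sums of squares directly (between
factor: dependency group, error = subjects within groups; within factor:
block or length, error = within × subjects); partial η² =
SS_effect/(SS_effect + SS_error). The Greenhouse-Geisser ε is estimated
from the **pooled within-group covariance** of the repeated measures (the
split-plot convention used by SPSS) and applied whenever the within factor
has ≥ 3 levels, reporting ε-corrected dfs and p alongside the uncorrected
ones; with 2 levels sphericity is vacuous and ε ≡ 1, so the 2 × 2
follow-up ANOVAs (block 1 vs 2, 1 vs 3, 2 vs 3; short vs medium, etc.) are
uncorrected and run without multiplicity adjustment. In tests the ANOVA is
cross-checked to 1e-8 against an independently written sums-of-squares
oracle and against pingouin's `mixed_anova` (SS, F, p, η²p; pingouin
estimates ε from the unpooled covariance, so ε is checked against the
independent oracle instead).

Strategy diagnostics follow the exclusion logic of the foil design: per
participant, three one-sided exact binomial tests (excess yes against 0.5)
on the 40-foil subsets; a first-pair (last-pair) flag requires S2 (S3)
significant **and** S1 — the yes-bias control — not significant. One-sided
exact tails are used because the question is directional (did the
participant say yes *more* often than chance on shortcut-compatible
foils?); a pure strategist yields 40/40 yes on its subset, p = 2⁻⁴⁰. For
unbiased guessers the per-strategy false-flag rate is
P(X ≥ 26 | 40, .5)·(1 − P) ≈ 0.039 < α = .05; the *union* rate over both
strategies is ≈ 2α(1−α) and is not controlled at α, so calibration is
stated and tested per strategy.

`full_report` chains these into the published analysis sequence, including
the sensitivity rerun that excludes flagged participants.

## Problem sizes and numerical choices

Calibration checks use 200 simulated guessers (chance level within 3
standard errors of the cohort mean), 400 pooled observers ≈ 10⁵ scored
trials for estimator consistency, 10⁴ replicates for false-flag
calibration (with a 3-σ Monte-Carlo margin on the binomial rate), and
20-per-group cohorts for parameter recovery — sizes chosen so sampling
error is far below the effects being checked while the whole suite runs in
seconds. Degenerate inputs raise typed errors rather than returning NaN:
odd-length sequences, unknown syllables, zero-variance t-tests, unbalanced
ANOVA groups, misaligned response logs, infeasible counterbalance counts.

## Known limitations

- No audio, timing, or presentation-runtime modeling; syllable durations
  are out of scope.
- No trial-by-trial learning model and no mixed-effects / Bayesian
  alternative to the ANOVA battery (a natural extension).
- The guesser/learner/strategist taxonomy is a deliberately small policy
  space; real participants presumably mix strategies within a session.
- ε conventions differ across packages (pooled vs unpooled covariance);
  results for strongly unbalanced group covariances will differ from
  tools using the unpooled estimate.
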