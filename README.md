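# agl

Stimulus designs, simulated observers, and the signal-detection analysis
battery for artificial-grammar-learning (AGL) experiments contrasting
**nested** and **cross-serial** dependencies.

## The scientific problem

In formal language theory, nested dependencies (A₁A₂A₃B₃B₂B₁ — a mirror
language) are context-free, while cross-serial dependencies
(A₁A₂A₃B₁B₂B₃ — a copy language) require mildly context-sensitive power.
Whether this formal complexity difference shows up as a *cognitive*
difference is tested with AGL experiments: participants hear syllable
sequences generated by one of the two grammars, then judge novel sequences
as grammatical or not. The package rebuilds that entire workflow as code,
for researchers who want to generate such designs, pilot analysis
pipelines against simulated responders with known properties, or analyze
their own response logs:

- **Lexicon & grammars** — a 20-pair syllable lexicon (category A syllables
  carry vowels *e/i*, category B *o/u*; pairing is an explicit table
  lookup), sequence constructors, membership recognizers, and
  dependency-distance bookkeeping (the outermost nested link in a 3-pair
  sequence spans 4 intervening elements; every cross-serial link spans 2).
- **Designs** — experiment 1: 240 learning trials (80 per length 4/6/8,
  A-syllables exactly counterbalanced over positions, 25% repeat probes)
  and 360 test trials (180 trained-grammar members, 180 members of the
  untrained grammar, 60 per length per label). Experiment 2: the same
  learning phase, then 240 medium-length test trials whose 120 foils come
  in three subsets of 40 — S1 (untrained-grammar members), S2 (first
  element pair preserved), S3 (last element pair preserved) — built to
  expose single-pair shortcut strategies. Every sequence appears at most
  once per design; generation is seed-deterministic.
- **Simulants** — equal-variance Gaussian signal-detection learners
  (P(yes | correct) = Φ(d′/2 − c), P(yes | foil) = Φ(−d′/2 − c)),
  deterministic first-/last-element-pair strategists, and yes-biased
  guessers, composable into seeded cohorts.
- **Analysis** — per-participant sensitivity d′ = Φ⁻¹(H) − Φ⁻¹(F) with 0.5
  added to all four response classes before rates are formed, criterion
  c = −(Φ⁻¹(H) + Φ⁻¹(F))/2; d′ per test block and per sequence length;
  strategy-restricted d′_first / d′_last; one-sample and pooled-variance
  independent t-tests with Cohen's d; 2 × 3 mixed ANOVAs with
  Greenhouse-Geisser correction and partial η²; per-participant one-sided
  exact binomial strategy diagnostics with the S1 yes-bias control.

## Worked example

`examples/run_study.py` simulates an experiment-2 study — 20
signal-detection learners per group at generating sensitivity d′ = 1.2 —
and runs the full battery:

```text
cross_serial: mean d' = 1.175  t(19) = 30.27, p = 1.5e-17, d = 6.77
      nested: mean d' = 1.199  t(19) = 24.48, p = 7.8e-16, d = 5.47
between groups: t(38) = -0.39, p = 0.70
block effect  : F(1.88,71.46) = 1.36, p_GG = 0.26, partial eta^2 = 0.034 (epsilon = 0.940)
cross_serial: d'_first t = 20.39 (p = 2.2e-14), d'_last t = 26.14 (p = 2.3e-16)
      nested: d'_first t = 19.25 (p = 6.3e-14), d'_last t = 18.64 (p = 1.1e-13)
strategy-flagged participants: none
```

Both simulated groups recover the generating sensitivity (the one-sample
t-tests against zero are the learning-effect tests; Cohen's d is inflated
relative to human data because simulants share identical parameters), the
groups do not differ, there is no block trend (the generating sensitivity
was flat), and nobody is flagged as a strategist — exactly what the
generating model implies. `examples/strategy_leak.py` shows the converse:
a first-pair strategist scores 100% on the experiment-1 test set but false
alarms on all 40 S2 foils in experiment 2, where the binomial diagnostic
flags it at p = 2⁻⁴⁰.

Other examples: `examples/build_design.py` (design audit),
`examples/dependency_distances.py` (intervening-element distances, and the
optional dummy-syllable variant).

## Command line

```sh
agl design   --experiment 2 --group nested --seed 7 --out trials.csv
agl verify   --design trials.csv
agl simulate --experiment 2 --n-per-group 20 --policy sdt_learner \
             --sensitivity 1.2 --seed 7 --out-dir cohort/
agl analyze  --design nested cohort/trials_nested.csv \
             --design cross cohort/trials_cross_serial.csv \
             --responses cohort/responses.csv --out report.json
```

All outputs are deterministic given the seed. Response logs are plain CSV
(`participant_id,group,trial_index,answer`), so logs from real experiments
can be analyzed the same way.

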