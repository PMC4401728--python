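"""Why the foil subsets exist: the single-pair shortcut.

On the experiment-1 test set, a responder who inspects only the first
dependency pair — a regular-language shortcut that involves no nested or
cross-serial processing at all — classifies every trial correctly, because
all foils come from the other grammar and necessarily rearrange every pair.
The experiment-2 foil subsets close this hole: S2 foils keep the first pair
intact, so the shortcut now produces false alarms that an exact binomial
test detects.
"""

import numpy as np

from agl import (DependencyType, binomial_strategy_tests, build_design,
                 simulate_strategist, tally_counts)


def accuracy(log, design):
    by_index = {t.index: t for t in design.test_trials}
    return np.mean([(by_index[r.trial_index].label == "correct") == r.answer
                    for r in log.responses])


exp1 = build_design(1, DependencyType.NESTED, seed=1)
exp2 = build_design(2, DependencyType.NESTED, seed=1)

log1 = simulate_strategist(exp1, "first")
print(f"experiment 1: first-pair strategist accuracy = {accuracy(log1, exp1):.3f}"
      " (perfect, despite knowing nothing of the rule)")

log2 = simulate_strategist(exp2, "first")
print(f"experiment 2: first-pair strategist accuracy = {accuracy(log2, exp2):.3f}")
for subset in ("S1", "S2", "S3"):
    fa = tally_counts(log2, exp2, subset).false_alarms
    print(f"  false alarms on {subset}: {fa}/40")

flags = binomial_strategy_tests(log2, exp2)
print(f"binomial diagnostics: p(S2) = {flags.p_values['S2']:.2e} -> "
      f"first-pair flag = {flags.first_pair_flag}")
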