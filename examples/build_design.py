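"""Build and audit a default experiment-1 trial list.

The learning phase trains one grammar (here: nested dependencies, a mirror
language); the test phase mixes members of the trained grammar (correct
trials) with members of the other grammar (incorrect trials).
"""

from agl import DependencyType, build_design, verify_design

design = build_design(experiment=1, group=DependencyType.NESTED, seed=1)
report = verify_design(design)

print(f"trained grammar : {design.group.value} ({design.group.chomsky_level})")
print(f"phase counts    : {report.tallies['phase_counts']}")
print(f"learning lengths: {report.tallies['learning_per_length']}")
print(f"repeat probes   : {report.tallies['repeat_probes']} (alertness checks)")
print(f"test cells      : {report.tallies['test_cells']}")
print(f"violations      : {len(report.violations)}")
print()
print("first three test trials (label = membership in the trained grammar):")
for t in design.test_trials[:3]:
    print(f"  {' '.join(t.sequence):<42} -> {t.label}")
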