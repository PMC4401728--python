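"""Intervening-element distances for the two dependency types.

Memory-cost accounts of sentence processing predict difficulty from the
number of elements intervening between dependent positions: in a 3-pair
nested sequence A1 A2 A3 B3 B2 B1 the outermost dependency spans four
intervening elements, while in the cross-serial sequence A1 A2 A3 B1 B2 B3
every dependency spans exactly two.
"""

from agl import DependencyType, dependency_structure

for dep in DependencyType:
    s = dependency_structure(3, dep)
    print(f"{dep.value} ({dep.chomsky_level}):")
    for i, ((a, b), d) in enumerate(zip(s.links, s.distances), start=1):
        print(f"  link {i}: positions {a} <-> {b}, {d} intervening element(s)")

print()
print("with a dummy syllable at the midpoint (removes the adjacent innermost"
      " nested pair):")
for dep in DependencyType:
    s = dependency_structure(3, dep, dummy=True)
    print(f"  {dep.value}: distances {list(s.distances)}")
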