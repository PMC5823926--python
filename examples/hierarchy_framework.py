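"""Iterated population-based AND induction: the (2n - 1) domain law.

Plans the hierarchy for n orthogonal signals, runs the discrete 1D induction
dynamics, and prints the resulting domain map.
"""
from hslpattern.hierarchy import (count_domains, plan_hierarchy,
                                  simulate_hierarchy)

for n in (2, 3, 4):
    plan = plan_hierarchy(n)
    dm = simulate_hierarchy(plan)
    print(f"n={n}: planned {len(plan.domains)} domains "
          f"(2x{n}-1), realized {count_domains(dm)}"
          f"{' (incomplete)' if dm.incomplete else ''}")

plan = plan_hierarchy(3)
dm = simulate_hierarchy(plan)
print("\nn=3 domain map (64-cell lattice):")
print(" ".join((l or ".") for l in dm.labels.tolist()))
print("\nA and B are the founder populations (producing morphogens a and b);")
print("'ab' is the AND-induced interface domain producing c; 'ac' and 'bc'")
print("are the third-level domains where c meets each founder signal.")
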