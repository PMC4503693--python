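"""Optimal stratum boundaries for re-sampling a known population.

Exhaustive search over all midpoint cut sets finds the 4-stratum
partition of persons-per-residence minimising the design variance of
the stratified Horvitz-Thompson total at each sample size, under Neyman
allocation.  The coefficient-of-variation search inverts the problem:
the smallest n whose optimised CV meets a target.
"""

import numpy as np

from stratpop import (
    GeneratorConfig,
    design_cv,
    generate_residences,
    load_section_table,
    optimize_boundaries_for_cv,
    optimize_boundaries_for_n,
)

sections = load_section_table()
frame = generate_residences(sections, GeneratorConfig(seed=1))
occ = frame.occupancies()

print("Neyman-optimal 4-stratum boundaries (persons per residence):")
print(f"{'n':>5}  boundaries           n_h                 pi_h")
for n in (330, 660, 990):
    sf, plan = optimize_boundaries_for_n(occ, L=4, n=n, rule="neyman")
    b = np.array2string(sf.boundaries, precision=1)
    print(f"{n:>5}  {b:<20} {np.array2string(plan.n_h):<19} "
          f"{np.array2string(np.round(plan.pi_h, 2))}")

# Boundaries tighten as n grows and the top (high-occupancy) stratum is
# enumerated completely (pi = 1): rare large residences carry so much of
# the variance that Neyman allocation takes them all.

result = optimize_boundaries_for_cv(occ, L=4, c_target=0.01, rule="neyman")
print(f"\nsmallest n with CV <= 1%: {result.n_min} "
      f"(boundaries {np.round(result.boundaries, 1)}, CV {result.cv:.4f})")
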