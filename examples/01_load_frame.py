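"""Load the packaged Bo City section table and inspect the frame.

The frame is the basis of every analysis in this package: 20 named city
sections with counts of residential structures, households and persons.
"""

from stratpop import load_section_table

sections = load_section_table()

print(f"sections:               {len(sections)}")
print(f"residential structures: {sum(s.n_residential for s in sections)}")
print(f"persons:                {sum(s.n_persons for s in sections)}")

print("\nthree smallest and largest sections by residential structures:")
for s in sections[:3] + sections[-3:]:
    print(f"  {s.name:<15} {s.n_residential:>4} structures, "
          f"{s.n_persons:>5} persons, mean occupancy {s.mean_occupancy:5.2f}")

# The totals (20 / 1,979 / 25,954) are the ground truth every estimator
# below tries to recover from partial samples.
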