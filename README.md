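# stratpop

Stratified sampling designs for small-area population estimation.

`stratpop` studies how well different survey designs would recover the
population of a small city whose true total is known from a complete
enumeration. It ships a 20-section census frame (Bo City, Sierra Leone,
2010–11: 1,979 residential structures, 25,954 persons), a synthetic
record generator that expands the section table into per-residence
occupancies with exact margins, an exhaustive-search optimal
stratification engine, Horvitz–Thompson estimators with a finite
population bootstrap, and Monte-Carlo simulation drivers that replay
thousands of hypothetical surveys against the known truth.

## The statistical problem

A population of `N` units (residences, or whole city sections) carries
values `y_i` (persons per residence, or persons per section). A sample
of `n` units is drawn without replacement and the total
`Y = Σ y_i` is estimated by the Horvitz–Thompson expansion
`Ŷ = Σ_{i∈s} y_i / π_i`, where `π_i` is the unit's inclusion
probability.

Partitioning the units into `L` strata by their size and sampling
independently within each stratum leaves `Ŷ` unbiased but can shrink
its variance dramatically, because the design variance

```
V(Ŷ) = Σ_h N_h² (1 − n_h/N_h) S_h² / n_h
```

depends only on the within-stratum spreads `S_h`. The package searches
every way of cutting the sorted values into `L` right-closed intervals
`(b_{h−1}, b_h]`, allocates `n` across strata by a power rule
(Neyman `n_h ∝ N_h S_h`, proportional `n_h ∝ N_h`, or any exponent
triple on `N_h`, `Ȳ_h`, `S_h`), and keeps the partition minimising
`V`. Strata whose allocation reaches `N_h` become take-all (census)
strata and drop out of the variance.

Two sampling modes are covered:

- **record mode** — residences are sampled directly and `y_i` is the
  occupancy of residence `i`;
- **cluster mode** — whole sections are sampled (one per stratum when
  stratified) and `y_i` is the section's person total.

## Quick start

```python
from stratpop import (GeneratorConfig, generate_residences,
                      load_section_table, optimize_boundaries_for_n,
                      stratify_sections)

sections = load_section_table()          # bundled 20-section frame
frame = generate_residences(sections, GeneratorConfig(seed=1))
print(frame.total_residences, frame.total_persons)   # 1979 25954

# optimal 4-stratum record-level design at n = 990, Neyman allocation
sf, plan = optimize_boundaries_for_n(frame.occupancies(), L=4, n=990,
                                     rule="neyman")
print(sf.boundaries)   # [ 6.5  9.5 13.5 86. ]
print(plan.n_h)        # [105  97 117 671]  — top stratum taken in full

# optimal 4-stratum cluster design over the 20 sections
sf, plan = stratify_sections(sections, "structures", L=4, draws=4)
print(sf.boundaries)   # [ 51.  110.5 175.5 208. ]
print(sf.N_h, plan.n_h)  # [6 5 6 3] [1 1 1 1]
```

A 1,000-trial design comparison (`examples/05_design_comparison.py`)
on the bundled frame:

```
record-level designs, n = 990 of 1,979, 1,000 trials:
  control (SRSWOR)  mean    25956  SD  420.98  SEM  9.46
  proportional      mean    25956  SD  143.56  SEM  3.23
  neyman            mean    25951  SD   63.22  SEM  1.42
  Levene neyman vs control: variance ratio 0.023, p = 2.20e-217
```

All three designs are unbiased; optimal stratification with Neyman
allocation cuts the standard deviation of the estimate by a factor of
almost seven relative to unstratified simple random sampling at the
same cost.

## Package layout

| module | contents |
| --- | --- |
| `stratpop.frame` | section/residence records, frame validation, CSV I/O, bundled fixture, margin checks |
| `stratpop.synthetic` | exact-margin per-residence occupancy generator with a single dispersion knob |
| `stratpop.stratification` | boundary candidates, stratified frames, power-rule allocation, design variance/CV, exhaustive optimisers |
| `stratpop.estimation` | Horvitz–Thompson totals (record and cluster), FPC standard errors, finite population bootstrap |
| `stratpop.simulation` | Monte-Carlo drivers for record, cluster and section-inherited designs; balanced-draw probability |
| `stratpop.reporting` | trial summaries, Levene variance comparisons, IQR ratios, one-call `reproduce_tables` bundle |

The `examples/` directory holds seven short narrative scripts, one per
capability, each runnable as `python examples/NN_name.py`.

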