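# Methods

This document records the statistical model, the algorithms, the
numerical conventions and the known limitations of `stratpop`. The
notation matches the code: `N` population units, values `y_i`, `L`
strata, stratum sizes `N_h`, stratum means `Ȳ_h`, stratum standard
deviations `S_h`, allocations `n_h`, inclusion probabilities
`π_h = n_h / N_h`.

## 1. The census frame

The bundled fixture (`stratpop/data/bo_sections.csv`, loaded by
`load_section_table()`) is the 2010–11 complete enumeration of the 20
sections of Bo City, Sierra Leone: per section, the land area, counts
of residential and total structures, households and persons, and the
mean persons per residential structure. Totals: 1,979 residential
structures, 25,954 persons.

`SurveyFrame` validates invariants on load (non-negative counts,
unique section names, residential ≤ total structures, mean occupancy
consistent with the counts to printed precision) and raises
`FrameValidationError` naming the offending row and field.
`check_margins` compares a residence table against its section table
and flags any section whose structure or person margin disagrees.

## 2. Synthetic residence records

Only section margins are known; per-residence occupancies are not. The
generator (`generate_residences`) fabricates them under three hard
constraints: every residence has at least one occupant, each section's
occupancies sum exactly to its census person total, and the number of
records equals the census residential-structure count.

Construction, per section with `m` residences and `P` persons:

1. give every residence 1 occupant, leaving `E = P − m` extra persons;
2. draw weights `w_j = exp(σ Z_j)` with `Z_j` i.i.d. standard normal —
   occupancies are therefore approximately lognormal around the
   section mean;
3. apportion the `E` extras proportionally to `w_j` by the
   largest-remainder method, which reproduces the margins exactly by
   construction (no rejection or iterative repair of sums);
4. if any occupancy exceeds `max_occupancy` (default 86, the largest
   single-residence occupancy the frame must accommodate), clip it and
   reassign the surplus greedily to the least-occupied residences.

Design properties this buys:

- **exact margins always** — apportionment, unlike multinomial
  sampling followed by repair, cannot miss the section total;
- **σ = 0 degenerates to the even split** — weights are all equal, so
  a section with mean 8.45 yields only occupancies 8 and 9;
- **monotone dispersion** — `Z_j` is drawn unconditionally (common
  random numbers), so for a fixed seed the per-section occupancy
  variance is non-decreasing in σ, which the tests assert on a σ grid.

**Calibration.** `DEFAULT_DISPERSION = 0.6` was fixed once, offline,
so that the pooled occupancy standard deviation on the fixture
(≈ 9.3–9.6 depending on seed) matches the value implied by the
reference design-variance of unstratified record sampling at
n = 990 (pooled SD ≈ 9.27). It is a frozen constant, not fitted at
run time, and no other parameter was adjusted after tests were
written.

**What the generator does not emulate:** household structure within
residences (every synthetic record has one household), spatial
autocorrelation between neighbouring residences, and any covariates
beyond occupancy. It is a marginal-preserving occupancy model, nothing
more.

## 3. Stratification and allocation

**Strata** are right-closed intervals `(b_{h−1}, b_h]` over the
stratification variable. Candidate cut points are the midpoints
between consecutive distinct sorted values, plus the maximum as the
terminal bound; this candidate set provably contains an optimal cut
set, because the objective only changes when a cut crosses a data
value. `stratify` assigns units by binary search and rejects empty
strata and out-of-range values.

**Allocation** follows a power rule with exponent triple
`(q1, q2, q3)`:

```
γ_h = N_h^{2·q1} · Ȳ_h^{2·q2} · S_h^{2·q3},   n_h ∝ √γ_h … (normalised shares)
```

- `NEYMAN = (0.5, 0, 0.5)` gives `n_h ∝ N_h S_h`;
- `PROPORTIONAL = (0.5, 0, 0)` gives `n_h ∝ N_h`.

Real-valued shares are rounded to integers by the largest-remainder
method (ties resolved to the lower stratum index), every take-some
stratum receives at least 1, and any stratum whose allocation exceeds
`N_h` is frozen as take-all (largest overflow first) with the
remainder re-allocated among the others until the assignment is
feasible.

**Objective.** For a boundary set and allocation, the design variance
of the stratified expansion total is

```
V = Σ_h N_h² (1 − n_h/N_h) S_h² / n_h        (S_h with ddof = 1),
```

take-all strata contributing zero. `design_cv` is `√V / Y`.

**Optimisers.**

- `optimize_boundaries_for_n(values, L, n, rule)` enumerates all
  `C(d−1, L−1)` cut combinations over the `d` distinct values
  (lexicographic order; strictly-better updates, so ties resolve to
  the first combination) using prefix sums of counts, sums and squared
  sums over the distinct values, making each combination O(L).
- `optimize_boundaries_for_cv(values, L, c_target, rule)` finds the
  smallest `n` whose optimised CV meets the target by bisection on
  `n`; the optimised CV is non-increasing in `n` (census gives CV 0),
  so bisection is valid.
- `stratify_sections(sections, variable, L, draws, rule)` applies the
  same machinery to the 20 sections, stratifying by residential
  structures or person totals, and supports a scalar number of
  clusters (allocated across strata) for the cluster designs.
  `min_records_per_sample` reports the smallest number of residential
  structures any realised sample can span (the `n_h` smallest section
  counts per stratum, summed).

On the fixture these exactly reproduce the reference cluster-design
optima: 4 clusters by structures → boundaries 51.0/110.5/175.5/208.0,
stratum sizes 6, 5, 6, 3, one section each, minimum 373 structures;
10 clusters → 40.0/84.0/175.5/208.0, sizes 5, 4, 8, 3, allocation
2, 1, 6, 1, minimum 986.

## 4. Estimation

- `ht_total_stratified` computes `Ŷ = Σ y_i/π_i` with
  `π_i = n_h/N_h` of the unit's stratum.
- `ht_total_cluster` treats a selected section as one unit whose value
  is its person total, with `π` = clusters drawn in its stratum over
  `N_h`; the unstratified case is `π = n/20`.
- `sem_fpc(sd, n, N) = sd/√n · √((N−n)/(N−1))` is the
  finite-population-corrected standard error of a mean.
- `fpb_resample` is the stratified finite population bootstrap: within
  each stratum, resample the drawn values with replacement at the
  original `n_h` and recompute the expansion total
  `Σ_h (N_h/n_h) Σ y*`; `BootstrapResult.ci` is the percentile
  interval. Because with-replacement resampling carries no finite
  population correction, the bootstrap interval is wider than the true
  without-replacement sampling spread by roughly `1/√(1−n/N)` — at
  n = 990 of 1,979 the Horvitz–Thompson normal interval is ≈ 0.70 of
  the bootstrap width, which the simulations confirm.

## 5. Simulation

`DesignSpec` freezes a design (mode, n, allocation rule,
stratification variable, trial count, seed, optionally fixed
boundaries); the drivers return a `TrialSet` of per-trial estimates
plus coverage tallies.

Per-trial randomness uses
`np.random.default_rng(np.random.SeedSequence(entropy=seed,
spawn_key=(trial,)))`, so trial `t` is identical regardless of how
many trials are run — extending an experiment preserves its prefix.

- `run_record_design` draws residences without replacement within
  strata (a single stratum for the SRSWOR control) and applies the
  stratified Horvitz–Thompson estimator. Boundaries are re-optimised
  for the spec's `n` unless frozen in the spec.
- `run_cluster_design` draws whole sections (one per stratum when
  stratified; SRSWOR of 4 when not) and records, per trial, the
  residences covered and — against a reference stratification — how
  many strata the draw touched, which measures how often an
  unstratified draw happens to be balanced.
- `run_section_noncluster_design` has residences inherit the stratum
  of their section (from the 4-cluster partition) and allocates `n`
  proportionally across those strata: stratification with no
  within-section occupancy information, which buys almost nothing
  over SRSWOR (variance ratio ≈ 1).
- `balanced_probability(sizes, draw)` returns the exact probability
  that an SRSWOR draw of `draw` sections touches every stratum,
  `Π N_h / C(ΣN_h, draw)` as a `Fraction` (36/323 ≈ 0.111 for the
  structures partition; 8·6·4·2/C(20,4) = 384/4845 ≈ 0.079 for the
  persons partition); `count_balanced` tallies the realised count in a
  trial set.

Default problem sizes — 1,000 trials for illustrative runs, 10,000
where a mean or variance is being certified, n = 990 (half the frame)
for record designs, 4-section cluster draws — are this package's own
choices, balancing Monte-Carlo error against runtime (every bundled
experiment completes in seconds).

## 6. Reporting

`summarize` reduces a `TrialSet` to mean, SD, variance,
FPC-corrected SEM, quartiles and a normal 95% half-width.
`levene_compare` wraps `scipy.stats.levene` (`center="mean"` for the
classical test, `"median"` for Brown–Forsythe) and reports the
variance ratio alongside the p-value. `iqr_ratio` compares the
interquartile ranges of two summaries — a robust analogue of the SD
ratio. `reproduce_tables(seed, out_dir)` recomputes every headline
artifact (cluster allocation table for 4–20 clusters, per-section
stratum assignments under both variables, balanced probabilities,
record- and cluster-design simulations) and, given `out_dir`, writes
them as CSVs with a JSON manifest of all seeds and parameters.

## 7. Numerical conventions

- `S_h` always uses `ddof = 1`; single-unit strata have `S_h = 0`.
- Optimiser comparisons use a relative tolerance of
  `1e-9·(1+|V|)` so floating-point ties resolve to the first
  (lexicographically smallest) cut set deterministically.
- Quartiles use NumPy's default linear interpolation, as do the
  bootstrap percentile intervals.
- Exact probabilities are `fractions.Fraction` built from
  `math.comb`, never floats.
- All derived seeds stay below 2³¹.

## 8. Limitations

- The generator is calibrated to one pooled-SD target; within-section
  dispersion is not separately validated, so per-section spreads are
  plausible rather than authoritative.
- The exhaustive optimiser is `O(C(d−1, L−1) · L)` over `d` distinct
  values — fine for occupancies (d ≈ 70) and sections (d = 20), not
  for large continuous frames; no approximate (e.g. cumulative-√f)
  search is provided.
- Cluster-mode estimates use single-stage whole-section totals only;
  two-stage (sections, then residences within) designs are out of
  scope.
- The finite population bootstrap is implemented in its basic
  with-replacement form; corrections that restore the FPC (mirror-
  match, rescaling) are not implemented, and the documented ≈ 1.4×
  width inflation at 50% sampling fractions is inherent to it.
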