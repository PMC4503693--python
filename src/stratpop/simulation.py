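"""Monte-Carlo engines for comparing sampling designs.

Three experiment families:

* **record** — stratified (or unstratified control) SRSWOR of individual
  residences, stratified on persons per residence, with the stratified
  Horvitz-Thompson total computed per trial;
* **cluster** — single-stage cluster sampling of whole sections, either
  one section per stratum (stratified) or an SRSWOR of sections
  (control), every selected section completely enumerated;
* **section_noncluster** — residences stratified by their *section's*
  stratum (a deliberately coarse partition) and subsampled
  proportionally, the negative-control experiment showing that
  section-level stratification does not help non-cluster sampling.

Each trial draws from an independent child RNG stream derived from the
master seed, so extending the trial count never reshuffles earlier
trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, prod
from typing import Sequence

import numpy as np

from .frame import SurveyFrame
from .stratification import (
    AllocationPlan,
    StratifiedFrame,
    allocate,
    optimize_boundaries_for_n,
    stratify,
    stratify_sections,
)


@dataclass
class DesignSpec:
    """One simulated design.

    mode
        ``"record"``, ``"cluster"`` or ``"section_noncluster"``.
    variable
        ``"occupancy"`` for record mode; ``"structures"`` or
        ``"persons"`` (section-level) for the other modes.
    rule
        ``"neyman"``, ``"proportional"``, or ``None`` for the
        unstratified control.
    n
        Total records to draw (record / section_noncluster modes) or
        sections to draw (cluster mode).
    """

    mode: str
    n: int
    rule: str | None = "neyman"
    variable: str = "occupancy"
    L: int = 4
    n_trials: int = 1000
    seed: int = 0
    boundaries: Sequence[float] | None = None  # freeze instead of re-optimizing

    def __post_init__(self) -> None:
        if self.mode not in ("record", "cluster", "section_noncluster"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TrialSet:
    """Per-trial outcomes of a simulated design."""

    estimates: np.ndarray
    residences_covered: np.ndarray
    strata_represented: np.ndarray
    spec: DesignSpec | None = None
    stratification: StratifiedFrame | None = None
    plan: AllocationPlan | None = None

    def __len__(self) -> int:
        return len(self.estimates)


def _trial_rng(seed: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(trial,))
    )


def draw_stratified_indices(
    membership: np.ndarray, n_h: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """SRSWOR of ``n_h[h]`` unit indices within each stratum ``h``."""
    picks = []
    for h, k in enumerate(n_h):
        pool = np.flatnonzero(membership == h)
        if k > len(pool):
            raise ValueError(f"stratum {h}: cannot draw {k} of {len(pool)} units")
        picks.append(rng.choice(pool, size=int(k), replace=False))
    return np.concatenate(picks)


def _record_setup(
    frame: SurveyFrame, spec: DesignSpec
) -> tuple[np.ndarray, StratifiedFrame, AllocationPlan]:
    occ = frame.occupancies()
    if spec.rule is None:
        # control: one stratum, plain SRSWOR of n from N
        sframe = stratify(occ, [occ.max()], variable="occupancy")
        plan = allocate(sframe, spec.n, "proportional")
    elif spec.boundaries is not None:
        sframe = stratify(occ, spec.boundaries, variable="occupancy")
        plan = allocate(sframe, spec.n, spec.rule)
    else:
        sframe, plan = optimize_boundaries_for_n(
            occ, spec.L, spec.n, spec.rule, variable="occupancy"
        )
    return occ, sframe, plan


def run_record_design(frame: SurveyFrame, spec: DesignSpec) -> TrialSet:
    """Stratified SRSWOR of residences with Horvitz-Thompson estimation.

    Boundaries are re-optimised for the spec's sample size (pass
    ``spec.boundaries`` to freeze them); the control (``rule=None``)
    places every residence in a single stratum.
    """
    if spec.mode != "record":
        raise ValueError("spec.mode must be 'record'")
    occ, sframe, plan = _record_setup(frame, spec)
    weights = sframe.N_h / plan.n_h  # 1/pi per stratum
    est = np.empty(spec.n_trials)
    for t in range(spec.n_trials):
        rng = _trial_rng(spec.seed, t)
        tot = 0.0
        for h in range(sframe.L):
            pool = np.flatnonzero(sframe.membership == h)
            k = int(plan.n_h[h])
            drawn = pool if k == len(pool) else rng.choice(pool, size=k, replace=False)
            tot += weights[h] * occ[drawn].sum()
        est[t] = tot
    return TrialSet(
        estimates=est,
        residences_covered=np.full(spec.n_trials, spec.n),
        strata_represented=np.full(spec.n_trials, sframe.L),
        spec=spec,
        stratification=sframe,
        plan=plan,
    )


def run_cluster_design(
    frame: SurveyFrame,
    spec: DesignSpec,
    reference: StratifiedFrame | None = None,
) -> TrialSet:
    """Single-stage cluster sampling of whole sections.

    Stratified: sections are partitioned on ``spec.variable`` and
    ``n_h`` sections drawn per stratum (the allocation for ``spec.n``
    total sections).  Control (``rule=None``): ``spec.n`` sections
    SRSWOR from all sections; ``reference`` may supply a partition for
    tallying how many strata each control draw touches.
    """
    if spec.mode != "cluster":
        raise ValueError("spec.mode must be 'cluster'")
    persons = frame.section_values("persons")
    structures = frame.section_values("structures")
    M = frame.n_sections

    if spec.rule is None:
        est = np.empty(spec.n_trials)
        covered = np.empty(spec.n_trials, int)
        represented = np.empty(spec.n_trials, int)
        expansion = M / spec.n
        for t in range(spec.n_trials):
            rng = _trial_rng(spec.seed, t)
            drawn = rng.choice(M, size=spec.n, replace=False)
            est[t] = expansion * persons[drawn].sum()
            covered[t] = int(structures[drawn].sum())
            if reference is not None:
                represented[t] = len(set(reference.membership[drawn]))
            else:
                represented[t] = 1
        return TrialSet(est, covered, represented, spec=spec,
                        stratification=reference, plan=None)

    sframe, plan = stratify_sections(
        frame.sections, spec.variable, spec.L, spec.n, spec.rule
    )
    weights = sframe.N_h / plan.n_h
    est = np.empty(spec.n_trials)
    covered = np.empty(spec.n_trials, int)
    for t in range(spec.n_trials):
        rng = _trial_rng(spec.seed, t)
        tot = 0.0
        cov = 0
        for h in range(sframe.L):
            pool = np.flatnonzero(sframe.membership == h)
            drawn = rng.choice(pool, size=int(plan.n_h[h]), replace=False)
            tot += weights[h] * persons[drawn].sum()
            cov += int(structures[drawn].sum())
        est[t] = tot
        covered[t] = cov
    return TrialSet(
        estimates=est,
        residences_covered=covered,
        strata_represented=np.full(spec.n_trials, sframe.L),
        spec=spec,
        stratification=sframe,
        plan=plan,
    )


def run_section_noncluster_design(frame: SurveyFrame, spec: DesignSpec) -> TrialSet:
    """Residence-level SRSWOR with strata inherited from whole sections.

    Sections are partitioned on ``spec.variable``; every residence of a
    section joins the section's stratum; ``spec.n`` residences are drawn
    under proportional allocation (each stratum's share proportional to
    its residence count, largest-remainder rounded).
    """
    if spec.mode != "section_noncluster":
        raise ValueError("spec.mode must be 'section_noncluster'")
    occ = frame.occupancies()
    sframe, _ = stratify_sections(frame.sections, spec.variable, spec.L, spec.L)
    # residence membership inherited from sections
    stratum_of = {
        name: int(sframe.membership[i]) for i, name in enumerate(sframe.labels)
    }
    membership = np.array([stratum_of[s] for s in frame.residence_sections()])
    N_h = np.bincount(membership, minlength=sframe.L)
    # proportional allocation of spec.n residences over the strata
    real = spec.n * N_h / N_h.sum()
    n_h = np.floor(real).astype(int)
    rem = real - n_h
    short = spec.n - int(n_h.sum())
    order = np.lexsort((np.arange(len(N_h)), -rem))
    n_h[order[:short]] += 1
    n_h = np.minimum(np.maximum(n_h, 1), N_h)
    if n_h.sum() != spec.n:  # rebalance after clamping
        diff = spec.n - int(n_h.sum())
        while diff != 0:
            if diff > 0:
                room = np.flatnonzero(n_h < N_h)
                n_h[room[np.argmax((N_h - n_h)[room])]] += 1
                diff -= 1
            else:
                room = np.flatnonzero(n_h > 1)
                n_h[room[np.argmax(n_h[room])]] -= 1
                diff += 1
    plan = AllocationPlan(
        n=spec.n, rule=(0.5, 0.0, 0.0), n_h=n_h, N_h=N_h,
        gamma_h=N_h.astype(float), a_h=N_h / N_h.sum(),
        take_all=(n_h == N_h),
    )
    weights = N_h / n_h
    est = np.empty(spec.n_trials)
    for t in range(spec.n_trials):
        rng = _trial_rng(spec.seed, t)
        tot = 0.0
        for h in range(sframe.L):
            pool = np.flatnonzero(membership == h)
            k = int(n_h[h])
            drawn = pool if k == len(pool) else rng.choice(pool, size=k, replace=False)
            tot += weights[h] * occ[drawn].sum()
        est[t] = tot
    return TrialSet(
        estimates=est,
        residences_covered=np.full(spec.n_trials, spec.n),
        strata_represented=np.full(spec.n_trials, sframe.L),
        spec=spec,
        stratification=sframe,
        plan=plan,
    )


def balanced_probability(
    stratum_sizes: Sequence[int], draw: int, exact: bool = False
) -> float | Fraction:
    """Probability that an SRSWOR of ``draw`` clusters touches every stratum.

    For one section per stratum this is ``prod(N_h) / C(sum(N_h), draw)``,
    computed in exact rational arithmetic.
    """
    sizes = [int(s) for s in stratum_sizes]
    if draw != len(sizes):
        raise ValueError(
            "the balanced-draw formula assumes exactly one cluster per stratum"
        )
    p = Fraction(prod(sizes), comb(sum(sizes), draw))
    return p if exact else float(p)


def count_balanced(trials: TrialSet, L: int) -> int:
    """Number of trials in which all ``L`` strata were represented."""
    return int((trials.strata_represented == L).sum())
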