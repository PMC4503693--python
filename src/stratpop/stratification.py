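"""Optimal stratum boundaries and sample allocation.

Units (residences or whole sections) are partitioned into ``L``
mutually-exclusive, exhaustive strata by right-closed intervals
``(b_{h-1}, b_h]`` on a single stratification variable.  Boundaries are
found by exhaustive search over all midpoint cut sets, minimising the
design variance of the stratified estimator of the population total

    V(b, n) = sum_h  N_h^2 (1 - n_h/N_h) S_h^2 / n_h

under a chosen allocation rule.  Frames here are small (tens of
sections, a couple of thousand residences with < 100 distinct values),
so exhaustive search is exact and cheap; no iterative boundary
heuristics are used.

Allocation rules are encoded as exponents ``(q1, q2, q3)`` giving
per-stratum weights ``gamma_h = N_h^{2 q1} * ybar_h^{2 q2} * S_h^{2 q3}``:
``(0.5, 0, 0.5)`` is Neyman allocation (``n_h`` proportional to
``N_h S_h``, variance-minimising), ``(0.5, 0, 0)`` is proportional
allocation.  A stratum whose allocation reaches its size becomes
*take-all* (fully enumerated, inclusion probability 1) and the surplus
is re-allocated among the remaining take-some strata until stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .frame import SectionRecord

#: Allocation-rule exponents (q1, q2, q3).
NEYMAN = (0.5, 0.0, 0.5)
PROPORTIONAL = (0.5, 0.0, 0.0)

_RULES = {"neyman": NEYMAN, "proportional": PROPORTIONAL}


def _as_rule(rule) -> tuple[float, float, float]:
    if isinstance(rule, str):
        try:
            return _RULES[rule]
        except KeyError:
            raise ValueError(f"unknown allocation rule {rule!r}") from None
    q = tuple(float(x) for x in rule)
    if len(q) != 3:
        raise ValueError("allocation rule must be a name or three exponents")
    return q  # type: ignore[return-value]


@dataclass
class StratifiedFrame:
    """A partition of units into L strata with per-stratum statistics.

    ``S_h`` uses the ``N_h - 1`` denominator (sample SD), the convention
    entering the design-variance formula; singleton strata get S_h = 0.
    """

    variable: str
    boundaries: np.ndarray          # ascending upper bounds b_1..b_L
    values: np.ndarray              # unit-level stratification variable
    membership: np.ndarray          # 0-based stratum index per unit
    N_h: np.ndarray
    W_h: np.ndarray
    ybar_h: np.ndarray
    S_h: np.ndarray
    labels: list[str] | None = None  # optional unit labels (section names)

    @property
    def L(self) -> int:
        return len(self.boundaries)

    @property
    def N(self) -> int:
        return int(self.N_h.sum())

    def units_in(self, h: int) -> np.ndarray:
        """Indices of the units in stratum ``h`` (0-based)."""
        return np.flatnonzero(self.membership == h)

    def stratum_of_label(self, label: str) -> int:
        if self.labels is None:
            raise ValueError("frame carries no unit labels")
        return int(self.membership[self.labels.index(label)])


@dataclass
class AllocationPlan:
    """Per-stratum sample sizes under an allocation rule.

    ``a_h`` are the final allocation proportions over take-some strata
    (zero for take-all strata); ``pi_h = n_h / N_h`` is the inclusion
    probability shared by every unit of stratum h.
    """

    n: int
    rule: tuple[float, float, float]
    n_h: np.ndarray
    N_h: np.ndarray
    gamma_h: np.ndarray
    a_h: np.ndarray
    take_all: np.ndarray
    pi_h: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pi_h = self.n_h / self.N_h


@dataclass(frozen=True)
class CvTargetResult:
    """Smallest sample size meeting a coefficient-of-variation target."""

    c_target: float
    n_min: int
    boundaries: np.ndarray
    cv: float


def candidate_boundaries(values: Sequence[float]) -> np.ndarray:
    """Candidate cut points: midpoints between consecutive distinct values,
    plus the maximum value as the terminal bound.

    All-identical input yields an empty candidate list (with a warning),
    since no cut can separate anything.
    """
    distinct = np.unique(np.asarray(values, float))
    if len(distinct) < 2:
        import warnings

        warnings.warn("all values identical; no candidate boundaries", stacklevel=2)
        return np.array([])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.append(mids, distinct[-1])


def stratify(
    values: Sequence[float],
    boundaries: Sequence[float],
    variable: str = "y",
    labels: list[str] | None = None,
) -> StratifiedFrame:
    """Assign each unit to the stratum ``h`` with ``b_{h-1} < x <= b_h``."""
    x = np.asarray(values, float)
    b = np.asarray(boundaries, float)
    if len(b) == 0 or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly ascending and nonempty")
    if x.max() > b[-1]:
        raise ValueError(
            f"value {x.max()} exceeds the terminal boundary {b[-1]}"
        )
    membership = np.searchsorted(b, x, side="left")
    L = len(b)
    N_h = np.array([(membership == h).sum() for h in range(L)])
    if (N_h == 0).any():
        empty = np.flatnonzero(N_h == 0).tolist()
        raise ValueError(f"empty stratum(ta) at index {empty}")
    ybar = np.array([x[membership == h].mean() for h in range(L)])
    S = np.array(
        [x[membership == h].std(ddof=1) if N_h[h] > 1 else 0.0 for h in range(L)]
    )
    return StratifiedFrame(
        variable=variable,
        boundaries=b,
        values=x,
        membership=membership,
        N_h=N_h,
        W_h=N_h / N_h.sum(),
        ybar_h=ybar,
        S_h=S,
        labels=labels,
    )


def _allocate_arrays(
    N_h: np.ndarray,
    ybar_h: np.ndarray,
    S_h: np.ndarray,
    n: int,
    q: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core allocation with take-all resolution; returns (n_h, gamma, a, take_all)."""
    L = len(N_h)
    if not L <= n <= N_h.sum():
        raise ValueError(f"need L={L} <= n={n} <= N={int(N_h.sum())}")
    q1, q2, q3 = q
    gamma_full = N_h ** (2 * q1) * np.abs(ybar_h) ** (2 * q2) * S_h ** (2 * q3)
    take_all = np.zeros(L, bool)
    n_h = np.zeros(L, np.int64)
    a_h = np.zeros(L, float)
    n_rem = n
    while True:
        idx = np.flatnonzero(~take_all)
        gamma = gamma_full[idx]
        if gamma.sum() == 0:  # e.g. all S_h = 0 under Neyman: fall back to size
            gamma = N_h[idx].astype(float)
        a = gamma / gamma.sum()
        real = n_rem * a
        base = np.floor(real).astype(np.int64)
        rem = real - base
        short = n_rem - int(base.sum())
        order = np.lexsort((np.arange(len(idx)), -rem))
        base[order[:short]] += 1
        # every take-some stratum draws at least one unit
        while (base == 0).any():
            z = int(np.flatnonzero(base == 0)[0])
            donor = int(np.argmax(base))
            if base[donor] <= 1:
                break
            base[donor] -= 1
            base[z] += 1
        over = base - N_h[idx]
        if (over < 0).all():
            n_h[idx] = base
            a_h[:] = 0.0
            a_h[idx] = a
            break
        # largest overflow becomes take-all; re-allocate the rest
        worst = idx[int(np.argmax(over))]
        take_all[worst] = True
        n_h[worst] = N_h[worst]
        n_rem -= int(N_h[worst])
        if not (~take_all).any():
            break
    return n_h, gamma_full, a_h, take_all


def allocate(frame: StratifiedFrame, n: int, rule=NEYMAN) -> AllocationPlan:
    """Allocate a total sample of ``n`` units across the frame's strata.

    Real-valued allocations are rounded by the largest-remainder method
    (ties toward the lower stratum index) so that ``sum(n_h) == n``
    exactly; strata whose allocation meets their size become take-all
    and the surplus is re-spread until stable.
    """
    q = _as_rule(rule)
    n_h, gamma, a_h, take_all = _allocate_arrays(
        frame.N_h, frame.ybar_h, frame.S_h, n, q
    )
    return AllocationPlan(
        n=n, rule=q, n_h=n_h, N_h=frame.N_h.copy(),
        gamma_h=gamma, a_h=a_h, take_all=take_all,
    )


def design_variance(frame: StratifiedFrame, plan: AllocationPlan) -> float:
    """Variance of the stratified SRSWOR estimator of the total,
    ``sum_h N_h^2 (1 - n_h/N_h) S_h^2 / n_h`` (take-all strata contribute 0)."""
    V = 0.0
    for N, n_h, S in zip(frame.N_h, plan.n_h, frame.S_h):
        if n_h < N:
            V += N * N * (1 - n_h / N) * S * S / n_h
    return float(V)


def design_cv(frame: StratifiedFrame, plan: AllocationPlan) -> float:
    """Coefficient of variation (RRMSE) of the estimated total."""
    total = float((frame.N_h * frame.ybar_h).sum())
    return float(np.sqrt(design_variance(frame, plan))) / total


class _Grouped:
    """Prefix sums over the distinct sorted values, for fast stratum stats."""

    def __init__(self, values: np.ndarray):
        x = np.asarray(values, float)
        self.distinct, counts = np.unique(x, return_counts=True)
        sums = self.distinct * counts
        sq = self.distinct ** 2 * counts
        self.ccount = np.concatenate([[0], np.cumsum(counts)])
        self.csum = np.concatenate([[0.0], np.cumsum(sums)])
        self.csq = np.concatenate([[0.0], np.cumsum(sq)])

    def stats(self, cuts: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
        """Stats for strata split after distinct-value positions ``cuts``.

        ``cuts`` are indices j meaning "stratum ends after distinct[j]".
        Returns (N_h, ybar_h, S_h), or None if a stratum is empty.
        """
        edges = (0,) + tuple(c + 1 for c in cuts) + (len(self.distinct),)
        N = np.diff(self.ccount[list(edges)])
        if (N == 0).any():
            return None
        s = np.diff(self.csum[list(edges)])
        sq = np.diff(self.csq[list(edges)])
        ybar = s / N
        ss = np.maximum(sq - N * ybar ** 2, 0.0)
        S = np.where(N > 1, np.sqrt(ss / np.maximum(N - 1, 1)), 0.0)
        return N, ybar, S


def _boundaries_from_cuts(grouped: _Grouped, cuts: tuple[int, ...]) -> np.ndarray:
    d = grouped.distinct
    mids = [(d[j] + d[j + 1]) / 2.0 for j in cuts]
    return np.array(mids + [d[-1]])


def optimize_boundaries_for_n(
    values: Sequence[float],
    L: int,
    n: int,
    rule=NEYMAN,
    variable: str = "y",
    labels: list[str] | None = None,
) -> tuple[StratifiedFrame, AllocationPlan]:
    """Exhaustive search for the L-stratum partition minimising the
    allocated design variance of the estimated total at sample size ``n``.

    Every choice of ``L - 1`` cut points between consecutive distinct
    values is evaluated; ties go to the lexicographically smallest
    boundary vector.
    """
    x = np.asarray(values, float)
    q = _as_rule(rule)
    grouped = _Grouped(x)
    n_distinct = len(grouped.distinct)
    if n_distinct < L:
        raise ValueError(
            f"cannot form {L} nonempty strata from {n_distinct} distinct values"
        )
    best_V = np.inf
    best_cuts: tuple[int, ...] | None = None
    for cuts in combinations(range(n_distinct - 1), L - 1):
        out = grouped.stats(cuts)
        if out is None:
            continue
        N_h, ybar, S = out
        if not L <= n <= N_h.sum():
            raise ValueError(f"need L={L} <= n={n} <= N={len(x)}")
        n_h, _, _, _ = _allocate_arrays(N_h, ybar, S, n, q)
        V = float(
            np.sum(
                np.where(
                    n_h < N_h,
                    N_h ** 2 * (1 - n_h / N_h) * S ** 2 / np.maximum(n_h, 1),
                    0.0,
                )
            )
        )
        if best_cuts is None or V < best_V - 1e-9 * (1 + abs(best_V)):
            best_V = V
            best_cuts = cuts
    assert best_cuts is not None
    boundaries = _boundaries_from_cuts(grouped, best_cuts)
    frame = stratify(x, boundaries, variable=variable, labels=labels)
    plan = allocate(frame, n, q)
    return frame, plan


def optimize_boundaries_for_cv(
    values: Sequence[float],
    L: int,
    c_target: float,
    rule=NEYMAN,
    variable: str = "y",
) -> CvTargetResult:
    """Smallest total sample size whose optimised CV is <= ``c_target``.

    Searches every candidate boundary vector; for each, the minimal
    feasible ``n`` is found by bisection (the allocated CV is
    nonincreasing in ``n``, and is exactly 0 at the census ``n = N``).
    """
    if not 0 < c_target < 1:
        raise ValueError("c_target must lie in (0, 1)")
    x = np.asarray(values, float)
    q = _as_rule(rule)
    grouped = _Grouped(x)
    n_distinct = len(grouped.distinct)
    if n_distinct < L:
        raise ValueError(
            f"cannot form {L} nonempty strata from {n_distinct} distinct values"
        )
    N = len(x)
    total = float(x.sum())

    def cv_at(stats, n: int) -> float:
        N_h, ybar, S = stats
        n_h, _, _, _ = _allocate_arrays(N_h, ybar, S, n, q)
        V = float(
            np.sum(
                np.where(
                    n_h < N_h,
                    N_h ** 2 * (1 - n_h / N_h) * S ** 2 / np.maximum(n_h, 1),
                    0.0,
                )
            )
        )
        return np.sqrt(V) / total

    best: tuple[int, tuple[int, ...], float] | None = None
    for cuts in combinations(range(n_distinct - 1), L - 1):
        stats = grouped.stats(cuts)
        if stats is None:
            continue
        lo, hi = L, N
        if cv_at(stats, lo) <= c_target:
            hi = lo
        while lo < hi:
            mid = (lo + hi) // 2
            if cv_at(stats, mid) <= c_target:
                hi = mid
            else:
                lo = mid + 1
        n_min = hi
        if best is None or n_min < best[0]:
            best = (n_min, cuts, cv_at(stats, n_min))
    assert best is not None
    n_min, cuts, cv = best
    return CvTargetResult(
        c_target=c_target,
        n_min=n_min,
        boundaries=_boundaries_from_cuts(grouped, cuts),
        cv=cv,
    )


def stratify_sections(
    sections: list[SectionRecord],
    variable: str,
    L: int,
    draws: int | Sequence[int],
    rule=NEYMAN,
) -> tuple[StratifiedFrame, AllocationPlan]:
    """Optimal L-stratum partition of whole sections.

    ``variable`` is ``"structures"`` (residential structures per section)
    or ``"persons"`` (persons per section).  ``draws`` is the total
    number of sections to sample, or a per-stratum sequence whose sum is
    used.  Every residence of a section inherits the section's stratum.
    """
    if variable == "structures":
        values = [float(s.n_residential) for s in sections]
    elif variable == "persons":
        values = [float(s.n_persons) for s in sections]
    else:
        raise ValueError(f"unknown section variable {variable!r}")
    n = int(draws) if np.isscalar(draws) else int(sum(draws))
    labels = [s.name for s in sections]
    return optimize_boundaries_for_n(
        values, L, n, rule, variable=variable, labels=labels
    )


def min_records_per_sample(
    frame: StratifiedFrame,
    plan: AllocationPlan,
    structure_counts: Sequence[float],
) -> int:
    """Minimum residential structures a drawn sample can span: the sum over
    strata of the ``n_h`` smallest section structure counts."""
    counts = np.asarray(structure_counts, float)
    total = 0.0
    for h in range(frame.L):
        in_h = np.sort(counts[frame.membership == h])
        total += in_h[: plan.n_h[h]].sum()
    return int(round(total))
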