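"""Design-based estimators of the population total and their uncertainty.

All estimators are Horvitz-Thompson expansions: each observed value is
weighted by the inverse of its inclusion probability, giving an unbiased
estimate of the finite-population total as long as every inclusion
probability is positive.  Uncertainty is quantified either across
simulated trials (see :mod:`stratpop.simulation`) or, within one drawn
sample, by a stratified finite population bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frame import SectionRecord
from .stratification import StratifiedFrame


@dataclass
class DrawnSample:
    """One realised sample, record- or cluster-mode.

    ``y`` are observed values (persons per residence, or whole-section
    person totals in cluster mode); ``pi`` the matching inclusion
    probabilities; ``strata`` the 0-based stratum index of each drawn
    unit; ``n_h``/``N_h`` the per-stratum drawn and population sizes.
    """

    mode: str  # "record" | "cluster"
    y: np.ndarray
    pi: np.ndarray
    strata: np.ndarray
    n_h: np.ndarray
    N_h: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.pi = np.asarray(self.pi, float)
        if (self.pi <= 0).any() or (self.pi > 1).any():
            raise ValueError("inclusion probabilities must lie in (0, 1]")


@dataclass
class BootstrapResult:
    """Replicate totals from a stratified finite population bootstrap."""

    replicates: np.ndarray
    point_estimate: float

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval (linear-interpolation quantiles)."""
        alpha = (1 - level) / 2
        lo, hi = np.quantile(self.replicates, [alpha, 1 - alpha])
        return float(lo), float(hi)

    def ci_width(self, level: float = 0.95) -> float:
        lo, hi = self.ci(level)
        return hi - lo


def ht_total_stratified(sample: DrawnSample) -> float:
    """Stratified Horvitz-Thompson estimate of the total:
    ``sum_h sum_{i in n_h} y_i / pi_i``.

    With every ``pi_i = 1`` (a census) this is exactly the sum of the
    drawn values.
    """
    return float(np.sum(sample.y / sample.pi))


def ht_total_cluster(
    selected_sections: list[SectionRecord],
    frame: StratifiedFrame,
    draws_per_stratum: np.ndarray | None = None,
) -> float:
    """Single-stage cluster Horvitz-Thompson estimate of the total.

    Each selected section contributes its whole person total ``y_i``
    weighted by ``1 / pi_i`` where ``pi_i = (sections drawn from its
    stratum) / N_h``.  ``frame`` must be a stratification of sections
    (unit labels = section names).  ``draws_per_stratum`` defaults to
    the per-stratum counts of the selection itself.
    """
    if frame.labels is None:
        raise ValueError("frame must carry section labels")
    strata = np.array([frame.stratum_of_label(s.name) for s in selected_sections])
    if draws_per_stratum is None:
        draws_per_stratum = np.bincount(strata, minlength=frame.L)
    total = 0.0
    for s, h in zip(selected_sections, strata):
        pi = draws_per_stratum[h] / frame.N_h[h]
        if pi <= 0:
            raise ValueError(f"section {s.name!r}: nonpositive inclusion probability")
        total += s.n_persons / pi
    return float(total)


def sem_fpc(sd: float, n: int, N: int) -> float:
    """Standard error of the mean with finite population correction:
    ``sd / sqrt(n) * sqrt((N - n) / (N - 1))``."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if not 1 <= n <= N:
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    return float(sd / np.sqrt(n) * np.sqrt((N - n) / (N - 1)))


def fpb_resample(sample: DrawnSample, B: int, seed: int) -> BootstrapResult:
    """Stratified finite population bootstrap of the estimated total.

    Per replicate, each stratum's drawn values are resampled with
    replacement at their original size ``n_h``; the strata are combined
    and the expansion total ``sum_h (N_h / n_h) sum y*`` formed.  The
    scheme assumes the sample was drawn with within-stratum SRSWOR
    (proportional-style expansion); it is isolated here so alternative
    finite-population bootstrap variants can be swapped in.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if (np.asarray(sample.n_h) == 0).any():
        raise ValueError("every stratum must contain at least one drawn unit")
    rng = np.random.default_rng(seed)
    L = len(sample.n_h)
    groups = [sample.y[sample.strata == h] for h in range(L)]
    for h, g in enumerate(groups):
        if len(g) != sample.n_h[h]:
            raise ValueError(
                f"stratum {h}: sample carries {len(g)} values but n_h={sample.n_h[h]}"
            )
    weights = sample.N_h / sample.n_h
    reps = np.empty(B)
    for b in range(B):
        tot = 0.0
        for h in range(L):
            star = rng.choice(groups[h], size=sample.n_h[h], replace=True)
            tot += weights[h] * star.sum()
        reps[b] = tot
    return BootstrapResult(
        replicates=reps, point_estimate=ht_total_stratified(sample)
    )


def ci_ratio(width_a: float, width_b: float) -> float:
    """Ratio of two confidence-interval widths, ``width_a / width_b``."""
    if width_a < 0 or width_b < 0:
        raise ValueError("interval widths must be nonnegative")
    if width_b == 0:
        raise ValueError("denominator interval has zero width")
    return width_a / width_b
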