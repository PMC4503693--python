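"""Summaries, variance-equality tests, and end-to-end table reproduction.

Turns :class:`~stratpop.simulation.TrialSet` objects into the summary
artifacts of the analysis: per-design summary rows (mean, SD, variance,
FPC-corrected SEM, quartiles), Levene variance comparisons between
designs, interquartile-width ratios, and an orchestrated bundle
reproducing the section-level allocation tables and the simulated
design comparisons from the packaged Bo City data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimation import sem_fpc
from .frame import load_section_table
from .simulation import (
    DesignSpec,
    TrialSet,
    balanced_probability,
    run_cluster_design,
    run_record_design,
)
from .stratification import min_records_per_sample, stratify_sections
from .synthetic import GeneratorConfig, generate_residences


@dataclass(frozen=True)
class SimulationSummary:
    """Summary statistics of a trial distribution (Table-row shape)."""

    n_trials: int
    mean: float
    sd: float
    variance: float
    sem: float
    q25: float
    median: float
    q75: float
    ci_half_width: float  # normal-theory 0.95 half-width, 1.96 * sd

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


@dataclass(frozen=True)
class VarianceComparison:
    statistic: float
    pvalue: float
    variance_ratio: float
    labels: tuple[str, str]
    degenerate: bool = False


def summarize(trials: TrialSet, n: int, N: int) -> SimulationSummary:
    """Summary row for a TrialSet; SEM is FPC-corrected at (n, N)."""
    est = np.asarray(trials.estimates, float)
    if len(est) == 0:
        raise ValueError("cannot summarise an empty trial set")
    sd = float(est.std(ddof=1)) if len(est) > 1 else 0.0
    q25, med, q75 = np.quantile(est, [0.25, 0.5, 0.75])
    return SimulationSummary(
        n_trials=len(est),
        mean=float(est.mean()),
        sd=sd,
        variance=sd * sd,
        sem=sem_fpc(sd, n, N),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        ci_half_width=1.96 * sd,
    )


def levene_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    center: str = "mean",
    labels: tuple[str, str] = ("A", "B"),
) -> VarianceComparison:
    """Levene test of variance equality between two trial distributions.

    ``center="mean"`` is the classical Levene test; ``center="median"``
    is the Brown-Forsythe variant.  The reported ratio is
    ``var(group_a) / var(group_b)``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return VarianceComparison(0.0, 1.0, 1.0, labels, degenerate=True)
    stat, p = sps.levene(a, b, center=center)
    return VarianceComparison(
        statistic=float(stat),
        pvalue=float(p),
        variance_ratio=float(va / vb) if vb > 0 else np.inf,
        labels=labels,
    )


def iqr_ratio(summary_a: SimulationSummary, summary_b: SimulationSummary) -> float:
    """Ratio of interquartile widths ``(q75 - q25)_A / (q75 - q25)_B``."""
    if summary_b.iqr == 0:
        raise ValueError("denominator summary has zero interquartile width")
    return summary_a.iqr / summary_b.iqr


def paired_width_test(widths_a, widths_b):
    """Paired t-test on matched interval widths (e.g. across sample sizes)."""
    return sps.ttest_rel(np.asarray(widths_a, float), np.asarray(widths_b, float))


def reproduce_tables(
    seed: int,
    out_dir: str | Path | None = None,
    n_trials: int = 1000,
    record_sample_size: int = 990,
) -> dict:
    """Recompute the analysis artifacts from the packaged Bo City table.

    Exact, section-level artifacts: the cluster allocation table (4-20
    sections, Neyman by structures), the per-section stratum assignments
    for both stratification variables, and the balanced-draw
    probability.  Stochastic artifacts, from synthetic residence
    records seeded by ``seed``: record-level design comparison at
    ``record_sample_size`` records and the three cluster designs, each
    over ``n_trials`` trials.  Identical seeds give identical bundles.
    """
    sections = load_section_table()
    structures = [s.n_residential for s in sections]
    names = [s.name for s in sections]

    # -- cluster allocation table (exact) --------------------------------
    rows = []
    for n_clusters in range(4, 21):
        sframe, plan = stratify_sections(sections, "structures", 4, n_clusters)
        rows.append(
            {
                "clusters": n_clusters,
                "min_records": min_records_per_sample(sframe, plan, structures),
                **{f"n_h{h + 1}": int(plan.n_h[h]) for h in range(4)},
                **{f"N_h{h + 1}": int(sframe.N_h[h]) for h in range(4)},
                **{f"b{h + 1}": float(sframe.boundaries[h]) for h in range(4)},
            }
        )
    cluster_allocation = pd.DataFrame(rows)

    # -- per-section stratum assignments (exact) -------------------------
    assign = {"section": names}
    for variable in ("structures", "persons"):
        for n_sections in (4, 10):
            sframe, _ = stratify_sections(sections, variable, 4, n_sections)
            assign[f"{variable}_n{n_sections}"] = [
                int(h) + 1 for h in sframe.membership
            ]
    assignments = pd.DataFrame(assign)

    sframe_str, _ = stratify_sections(sections, "structures", 4, 4)
    p_balanced = balanced_probability(sframe_str.N_h.tolist(), 4, exact=True)

    # -- stochastic artifacts --------------------------------------------
    frame = generate_residences(sections, GeneratorConfig(seed=seed))
    N = frame.total_residences

    record_rows = []
    for label, rule in (("control", None), ("proportional", "proportional"),
                        ("neyman", "neyman")):
        spec = DesignSpec(
            mode="record", n=record_sample_size, rule=rule,
            n_trials=n_trials, seed=seed,
        )
        s = summarize(run_record_design(frame, spec), record_sample_size, N)
        record_rows.append({"design": label, **asdict(s)})
    record_designs = pd.DataFrame(record_rows)

    cluster_rows = []
    for label, rule, variable in (
        ("unstratified", None, "structures"),
        ("by_structures", "neyman", "structures"),
        ("by_persons", "neyman", "persons"),
    ):
        spec = DesignSpec(
            mode="cluster", n=4, rule=rule, variable=variable,
            n_trials=n_trials, seed=seed,
        )
        trials = run_cluster_design(frame, spec, reference=sframe_str)
        s = summarize(trials, 4, frame.n_sections)
        cluster_rows.append(
            {
                "design": label,
                "mean_residences": float(trials.residences_covered.mean()),
                **asdict(s),
            }
        )
    cluster_designs = pd.DataFrame(cluster_rows)

    bundle = {
        "cluster_allocation": cluster_allocation,
        "assignments": assignments,
        "balanced_probability": p_balanced,
        "record_designs": record_designs,
        "cluster_designs": cluster_designs,
        "manifest": {
            "seed": seed,
            "n_trials": n_trials,
            "record_sample_size": record_sample_size,
            "frame_totals": {
                "sections": frame.n_sections,
                "residences": N,
                "persons": frame.total_persons,
            },
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("cluster_allocation", "assignments", "record_designs",
                    "cluster_designs"):
            bundle[key].to_csv(out / f"{key}.csv", index=False)
        manifest = dict(bundle["manifest"])
        manifest["balanced_probability"] = {
            "numerator": p_balanced.numerator,
            "denominator": p_balanced.denominator,
            "value": float(p_balanced),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
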