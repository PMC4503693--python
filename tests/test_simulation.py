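"""Monte-Carlo design engines and balanced-sample combinatorics."""

from fractions import Fraction

import numpy as np
import pytest

from stratpop import (
    DesignSpec,
    balanced_probability,
    count_balanced,
    draw_stratified_indices,
    run_cluster_design,
    run_record_design,
    run_section_noncluster_design,
    stratify_sections,
)


class TestRecordDesign:
    def test_census_is_exact(self, bo_frame):
        spec = DesignSpec(mode="record", n=1979, rule=None, n_trials=5, seed=0)
        trials = run_record_design(bo_frame, spec)
        assert np.all(trials.estimates == 25954)

    def test_control_variance_matches_srswor_closed_form(self, bo_frame):
        occ = bo_frame.occupancies()
        N, n = len(occ), 990
        spec = DesignSpec(mode="record", n=n, rule=None, n_trials=1000, seed=3)
        trials = run_record_design(bo_frame, spec)
        closed = N * N * (1 - n / N) * occ.var(ddof=1) / n
        assert trials.estimates.var(ddof=1) == pytest.approx(closed, rel=0.15)

    def test_seed_determinism(self, bo_frame):
        spec = DesignSpec(mode="record", n=330, rule="neyman", n_trials=20,
                          seed=5)
        a = run_record_design(bo_frame, spec)
        b = run_record_design(bo_frame, spec)
        assert np.array_equal(a.estimates, b.estimates)

    def test_extending_trials_preserves_prefix(self, bo_frame):
        short = DesignSpec(mode="record", n=330, rule=None, n_trials=10, seed=5)
        long = DesignSpec(mode="record", n=330, rule=None, n_trials=25, seed=5)
        a = run_record_design(bo_frame, short)
        b = run_record_design(bo_frame, long)
        assert np.array_equal(a.estimates, b.estimates[:10])

    def test_frozen_boundaries_respected(self, bo_frame):
        occ = bo_frame.occupancies()
        bnds = [6.5, 10.5, 14.5, occ.max()]
        spec = DesignSpec(mode="record", n=660, rule="neyman", n_trials=5,
                          seed=0, boundaries=bnds)
        trials = run_record_design(bo_frame, spec)
        np.testing.assert_allclose(trials.stratification.boundaries, bnds)

    def test_without_replacement_within_strata(self, bo_frame):
        occ = bo_frame.occupancies()
        rng = np.random.default_rng(0)
        membership = (occ > 9).astype(int)
        idx = draw_stratified_indices(membership, np.array([50, 60]), rng)
        assert len(idx) == len(set(idx.tolist()))


class TestClusterDesign:
    def test_persons_strata_mean_residences(self, bo_frame):
        """Average structures covered per balanced draw matches the
        analytic expectation 506.125 (sum of mean section size per
        stratum) within Monte-Carlo error."""
        spec = DesignSpec(mode="cluster", n=4, rule="neyman",
                          variable="persons", n_trials=1000, seed=2)
        trials = run_cluster_design(bo_frame, spec)
        cov = trials.residences_covered
        se = cov.std(ddof=1) / np.sqrt(len(cov))
        assert abs(cov.mean() - 506.125) < 4 * se

    def test_unstratified_variance_matches_closed_form(self, bo_frame,
                                                       person_totals):
        spec = DesignSpec(mode="cluster", n=4, rule=None, n_trials=1000,
                          seed=2)
        trials = run_cluster_design(bo_frame, spec)
        closed = 20 ** 2 * (1 - 4 / 20) * person_totals.var(ddof=1) / 4
        assert trials.estimates.var(ddof=1) == pytest.approx(closed, rel=0.15)

    def test_stratified_draw_touches_every_stratum(self, bo_frame):
        spec = DesignSpec(mode="cluster", n=4, rule="neyman",
                          variable="structures", n_trials=50, seed=1)
        trials = run_cluster_design(bo_frame, spec)
        assert np.all(trials.strata_represented == 4)
        assert count_balanced(trials, 4) == 50

    def test_control_tallies_reference_strata(self, bo_frame, bo_sections):
        ref, _ = stratify_sections(bo_sections, "structures", 4, 4)
        spec = DesignSpec(mode="cluster", n=4, rule=None, n_trials=1000,
                          seed=9)
        trials = run_cluster_design(bo_frame, spec, reference=ref)
        count = count_balanced(trials, 4)
        p = 540 / 4845
        sigma = np.sqrt(1000 * p * (1 - p))
        assert abs(count - 1000 * p) < 4 * sigma

    def test_design_variance_ordering(self, bo_frame):
        """Uncertainty: persons-stratified < structures-stratified <
        unstratified cluster sampling."""
        runs = {}
        for label, rule, var in (("un", None, "structures"),
                                 ("str", "neyman", "structures"),
                                 ("per", "neyman", "persons")):
            spec = DesignSpec(mode="cluster", n=4, rule=rule, variable=var,
                              n_trials=1000, seed=4)
            runs[label] = run_cluster_design(bo_frame, spec).estimates.var(
                ddof=1
            )
        assert runs["per"] < runs["str"] < runs["un"]


class TestSectionNonclusterDesign:
    def test_census_is_exact(self, bo_frame):
        spec = DesignSpec(mode="section_noncluster", n=1979,
                          variable="structures", n_trials=3, seed=0)
        trials = run_section_noncluster_design(bo_frame, spec)
        assert np.all(trials.estimates == 25954)

    def test_allocation_proportional_to_stratum_residences(self, bo_frame):
        spec = DesignSpec(mode="section_noncluster", n=990,
                          variable="persons", n_trials=1, seed=0)
        trials = run_section_noncluster_design(bo_frame, spec)
        sf = trials.stratification
        stratum_of = dict(zip(sf.labels, sf.membership))
        names = np.array(bo_frame.residence_sections())
        membership = np.array([stratum_of[n] for n in names])
        N_h = np.bincount(membership)
        # largest-remainder proportionality: within one unit of exact shares
        shares = 990 * N_h / N_h.sum()
        assert trials.plan.n_h.sum() == 990
        assert np.all(np.abs(trials.plan.n_h - shares) < 1.0)


class TestBalancedProbability:
    def test_published_partition(self):
        p = balanced_probability([6, 5, 6, 3], 4, exact=True)
        assert p == Fraction(540, 4845)
        assert float(p) == pytest.approx(0.1115, abs=5e-5)

    def test_persons_partition(self):
        assert balanced_probability([8, 6, 4, 2], 4, exact=True) == Fraction(
            384, 4845
        )

    def test_single_stratum(self):
        assert balanced_probability([20], 1) == 1.0

    def test_draw_mismatch_rejected(self):
        with pytest.raises(ValueError):
            balanced_probability([6, 5, 6, 3], 3)

    def test_count_matches_binomial_expectation(self, bo_frame, bo_sections):
        ref, _ = stratify_sections(bo_sections, "structures", 4, 4)
        spec = DesignSpec(mode="cluster", n=4, rule=None, n_trials=2000,
                          seed=13)
        trials = run_cluster_design(bo_frame, spec, reference=ref)
        p = balanced_probability([6, 5, 6, 3], 4)
        expected = 2000 * p
        sigma = np.sqrt(2000 * p * (1 - p))
        assert abs(count_balanced(trials, 4) - expected) < 4 * sigma
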