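"""Weighted Lin-Ying additive-hazards estimator with delayed entry."""

import numpy as np
import pytest

import medhaz as mh
from medhaz.exceptions import DomainError, RankError
from medhaz.hazard import estimate_baseline, cluster_sandwich_vcov
from tests.conftest import random_survival_design


class TestOracleEquivalence:
    def test_fuzz_against_brute_force(self):
        rng = np.random.default_rng(2024)
        for rep in range(40):
            n = int(rng.integers(5, 21))
            p = int(rng.integers(1, 4))
            design = random_survival_design(rng, n, p=p)
            fast = mh.fit_additive_hazard(design).beta
            slow = mh.brute_force_estimating_equation(design)
            assert fast == pytest.approx(slow, abs=1e-10), f"rep {rep}"

    def test_minimal_one_by_one_system(self):
        # two subjects, one event: the smallest nonsingular 1x1 system
        design = mh.SurvivalDesign(
            entry=[0.0, 0.0], exit=[2.0, 3.0], event=[1, 0],
            Z=np.array([[1.0], [0.0]]), names=["z"],
        )
        fast = mh.fit_additive_hazard(design).beta
        slow = mh.brute_force_estimating_equation(design)
        assert fast == pytest.approx(slow, abs=1e-14)

    def test_single_subject_is_degenerate_in_both_solvers(self):
        # with one subject the covariate is centered away entirely;
        # both routes must refuse identically
        design = mh.SurvivalDesign(
            entry=[0.0], exit=[2.0], event=[1], Z=np.array([[1.0]]), names=["z"]
        )
        with pytest.raises(RankError):
            mh.fit_additive_hazard(design)
        with pytest.raises(RankError):
            mh.brute_force_estimating_equation(design)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(7)
        design = random_survival_design(rng, 15, p=2)
        beta1 = mh.fit_additive_hazard(design).beta
        design.weights = design.weights * 2.0
        beta2 = mh.fit_additive_hazard(design).beta
        assert beta2 == pytest.approx(beta1, abs=1e-12)

    def test_brute_force_row_limit(self):
        rng = np.random.default_rng(8)
        design = random_survival_design(rng, 60, p=1)
        with pytest.raises(DomainError):
            mh.brute_force_estimating_equation(design)


class TestFitBehaviour:
    def test_zero_column_raises_rank_error(self):
        rng = np.random.default_rng(3)
        design = random_survival_design(rng, 20, p=2)
        design.Z[:, 1] = 0.0
        with pytest.raises(RankError, match="z1"):
            mh.fit_additive_hazard(design)

    def test_no_events_raises(self):
        design = mh.SurvivalDesign(
            entry=[0.0, 0.0], exit=[1.0, 2.0], event=[0, 0],
            Z=np.array([[1.0], [0.0]]), names=["z"],
        )
        with pytest.raises(DomainError):
            mh.fit_additive_hazard(design)

    def test_two_group_constant_hazard_difference(self):
        # lambda0 and lambda0 + b, no censoring: the group coefficient
        # estimates b
        rng = np.random.default_rng(11)
        n, lam0, b = 40_000, 0.02, 0.01
        grp = (np.arange(n) % 2).astype(float)
        t = rng.exponential(1.0 / (lam0 + b * grp))
        design = mh.SurvivalDesign(
            entry=np.zeros(n), exit=t, event=np.ones(n, dtype=int),
            Z=grp[:, None], names=["group"], cluster=np.arange(n),
        )
        fit = mh.fit_additive_hazard(design)
        se = np.sqrt(fit.vcov_naive[0, 0])
        assert abs(fit.beta[0] - b) < 3 * se

    def test_affine_equivariance(self):
        rng = np.random.default_rng(5)
        design = random_survival_design(rng, 30, p=2)
        design2 = random_survival_design(rng, 30, p=2)
        design2.entry, design2.exit, design2.event = design.entry, design.exit, design.event
        design2.weights = design.weights
        base = mh.fit_additive_hazard(design).beta
        # shift leaves beta unchanged
        design2.Z = design.Z + np.array([5.0, -3.0])
        shifted = mh.fit_additive_hazard(design2).beta
        assert shifted == pytest.approx(base, abs=1e-9)
        # scaling divides beta
        design2.Z = design.Z * np.array([2.0, 0.5])
        scaled = mh.fit_additive_hazard(design2).beta
        assert scaled == pytest.approx(base / np.array([2.0, 0.5]), abs=1e-9)

    def test_left_truncation_risk_sets(self):
        # a late entrant must not influence estimation before entry:
        # brute force (which builds risk sets explicitly) agrees
        design = mh.SurvivalDesign(
            entry=[0.0, 0.0, 3.0], exit=[2.0, 5.0, 6.0], event=[1, 1, 1],
            Z=np.array([[0.0], [1.0], [1.0]]), names=["z"],
        )
        fast = mh.fit_additive_hazard(design).beta
        slow = mh.brute_force_estimating_equation(design)
        assert fast == pytest.approx(slow, abs=1e-12)


class TestBaseline:
    def test_reduces_to_nelson_aalen_when_beta_zero(self):
        from lifelines import NelsonAalenFitter

        rng = np.random.default_rng(21)
        n = 400
        entry = rng.uniform(0, 2, n)
        exit_ = entry + rng.exponential(2.0, n)
        event = (rng.random(n) < 0.7).astype(int)
        design = mh.SurvivalDesign(
            entry=entry, exit=exit_, event=event,
            Z=rng.normal(size=(n, 1)), names=["z"], cluster=np.arange(n),
        )
        fit = mh.fit_additive_hazard(design)
        fit.beta = np.zeros(1)
        base = estimate_baseline(fit, design)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(durations=exit_, event_observed=event, entry=entry)
        na = naf.cumulative_hazard_
        ages = na.index.to_numpy()[1:]  # skip the t=0 anchor
        ours = base(ages)
        assert ours == pytest.approx(na.iloc[1:, 0].to_numpy(), abs=1e-10)

    def test_no_events_gives_zero_function(self):
        design = mh.SurvivalDesign(
            entry=[0.0, 0.0], exit=[1.0, 2.0], event=[0, 0],
            Z=np.array([[1.0], [0.0]]), names=["z"],
        )
        fit = mh.AdditiveHazardFit(
            beta=np.zeros(1), names=["z"], A=np.eye(1), b=np.zeros(1),
            vcov_naive=np.eye(1), n_events=0, person_years=3.0,
        )
        base = estimate_baseline(fit, design)
        assert np.all(base.values == 0.0)

    def test_constant_hazard_slope(self):
        rng = np.random.default_rng(31)
        n, lam = 20_000, 0.05
        t = rng.exponential(1.0 / lam, n)
        design = mh.SurvivalDesign(
            entry=np.zeros(n), exit=t, event=np.ones(n, dtype=int),
            Z=rng.normal(size=(n, 1)), names=["z"], cluster=np.arange(n),
        )
        fit = mh.fit_additive_hazard(design)
        base = estimate_baseline(fit, design)
        t1, t2 = np.quantile(t, [0.1, 0.6])
        slope = (base(t2) - base(t1)) / (t2 - t1)
        # MC tolerance: the NA estimator slope has SE ~ sqrt(lam^2 / events)
        assert slope == pytest.approx(lam, rel=0.05)


class TestClusterSandwich:
    def test_requires_clusters(self):
        rng = np.random.default_rng(41)
        design = random_survival_design(rng, 20, p=2)
        design.cluster = None
        fit = mh.fit_additive_hazard(design)
        with pytest.raises(DomainError):
            cluster_sandwich_vcov(fit, design)
        design.cluster = np.zeros(20)
        with pytest.raises(DomainError):
            cluster_sandwich_vcov(fit, design)

    def test_row_splitting_invariance(self):
        # duplicating every row with half weight changes neither beta nor
        # the clustered variance
        rng = np.random.default_rng(42)
        design = random_survival_design(rng, 25, p=2)
        fit = mh.fit_additive_hazard(design)
        V = cluster_sandwich_vcov(fit, design)
        double = mh.SurvivalDesign(
            entry=np.repeat(design.entry, 2),
            exit=np.repeat(design.exit, 2),
            event=np.repeat(design.event, 2),  # both halves carry the event mark
            Z=np.repeat(design.Z, 2, axis=0),
            names=design.names,
            weights=np.repeat(design.weights, 2) / 2.0,
            cluster=np.repeat(design.cluster, 2),
        )
        fit2 = mh.fit_additive_hazard(double)
        V2 = cluster_sandwich_vcov(fit2, double)
        assert fit2.beta == pytest.approx(fit.beta, abs=1e-10)
        assert V2 == pytest.approx(V, abs=1e-8)

    def test_ci_coverage_two_group_exponential(self):
        # 95% sandwich CIs for the hazard difference cover the truth at
        # close to nominal rate
        rng = np.random.default_rng(4242)
        lam0, b, n, reps = 0.05, 0.02, 3000, 250
        hits = 0
        for _ in range(reps):
            grp = (np.arange(n) % 2).astype(float)
            t = rng.exponential(1.0 / (lam0 + b * grp))
            cens = rng.uniform(5, 40, n)
            exit_ = np.minimum(t, cens)
            event = (t <= cens).astype(int)
            design = mh.SurvivalDesign(
                entry=np.zeros(n), exit=exit_, event=event,
                Z=grp[:, None], names=["g"], cluster=np.arange(n),
            )
            fit = mh.fit_additive_hazard(design)
            V = cluster_sandwich_vcov(fit, design)
            se = np.sqrt(V[0, 0])
            if abs(fit.beta[0] - b) < 1.959963984540054 * se:
                hits += 1
        assert 0.92 <= hits / reps <= 0.98
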