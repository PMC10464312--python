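"""End-to-end decomposition: design construction, additivity, bootstrap,
reporting, and the vectorized engine's parity with the public path."""

import copy

import numpy as np
import pandas as pd
import pytest

import medhaz as mh
from medhaz._fast import StratumEngine
from medhaz.cohort import MEDIATORS
from medhaz.decompose import (
    DecompositionConfig,
    _component_lincombs,
    _decompose_stratum,
    component_names,
    report_table,
)
from medhaz.exceptions import DomainError
from medhaz.expand import compute_weights, expand_cohort
from medhaz.mediators import PredictorSpec, fit_mediator_model
from medhaz.published import PUBLISHED_DECOMPOSITION, additivity_discrepancies


@pytest.fixture(scope="module")
def weighted_expanded(binary_cohort):
    stratum = binary_cohort.main_analysis().stratum("men")
    spec = PredictorSpec(race_levels=("black",))
    models = {m: fit_mediator_model(stratum, m, spec) for m in MEDIATORS}
    return compute_weights(expand_cohort(stratum, ["white", "black"]), models)


class TestDesign:
    def test_column_count_full(self, weighted_expanded):
        design = mh.build_msm_design(weighted_expanded, "full")
        assert len(design.names) == 1 + 4 + 4 + 2 + 1 + 1  # 13

    def test_column_count_without_education(self, weighted_expanded):
        design = mh.build_msm_design(weighted_expanded, "no_education")
        assert len(design.names) == 11

    def test_unknown_covariate_set(self, weighted_expanded):
        with pytest.raises(DomainError):
            mh.build_msm_design(weighted_expanded, "everything")

    def test_age_absent_from_design(self, weighted_expanded):
        design = mh.build_msm_design(weighted_expanded, "full")
        assert not any("age" in n for n in design.names)  # age is the timescale


@pytest.fixture(scope="module")
def result(binary_cohort, binary_config):
    return mh.run_decomposition(binary_cohort, binary_config)


class TestRunDecomposition:
    def test_additivity_exact(self, result):
        for comps in result.estimates.values():
            indirect = sum(
                v for k, v in comps.items() if k.startswith(("exposure_", "vulnerability_"))
            )
            assert comps["net_indirect"] == pytest.approx(indirect, abs=1e-9)
            assert comps["total"] == pytest.approx(comps["direct"] + indirect, abs=1e-9)

    def test_metadata_records_run_conditions(self, result):
        md = result.metadata
        assert md["covariate_set"] == "full"
        assert md["exposure_levels"] == ["white", "black"]
        assert "men" in md["n"] and "men" in md["weights"]
        assert md["weights"]["men"]["effective_sample_size"] > 0
        assert "black" in md["marginal_total"]["men"]

    def test_education_sensitivity_changes_only_estimates(self, binary_cohort, result):
        cfg = DecompositionConfig(
            exposure_levels=["white", "black"], covariate_set="no_education"
        )
        sens = mh.run_decomposition(binary_cohort, cfg)
        assert sens.metadata["covariate_set"] == "no_education"
        assert set(sens.estimates) == set(result.estimates)
        for key in sens.estimates:
            assert set(sens.estimates[key]) == set(result.estimates[key])
        assert sens.estimates != result.estimates

    def test_mediator_order_invariance(self, binary_cohort, result):
        cfg = DecompositionConfig(
            exposure_levels=["white", "black"], mediators=list(reversed(MEDIATORS))
        )
        perm = mh.run_decomposition(binary_cohort, cfg)
        for key, comps in result.estimates.items():
            for name, v in comps.items():
                assert perm.estimates[key][name] == pytest.approx(v, rel=1e-9)

    def test_single_sex_cohort_supported(self, binary_params):
        cohort = mh.generate_cohort(binary_params, seed=5)
        res = mh.run_decomposition(
            cohort, DecompositionConfig(exposure_levels=["white", "black"])
        )
        assert list(res.estimates) == [("men", "black")]


class TestEngineParity:
    @pytest.mark.parametrize("races", [["white", "black"], ["white", "black", "hispanic"]])
    def test_engine_reproduces_public_pipeline(self, races):
        p = mh.default_params(n=2500, races=races)
        p.sex_probs = {"men": 1.0}
        cohort = mh.generate_cohort(p, seed=17)
        cfg = DecompositionConfig(exposure_levels=races)
        df = cohort.main_analysis().data
        fit, _, _, _, design = _decompose_stratum(df, cfg, races)
        engine = StratumEngine(df, cfg, races)
        assert engine.names == design.names
        beta = engine.fit(np.arange(len(df)))
        assert beta == pytest.approx(fit.beta, abs=1e-10)

    def test_engine_parity_under_config_variants(self, binary_cohort):
        df = binary_cohort.main_analysis().stratum("men").data
        for cfg in (
            DecompositionConfig(exposure_levels=["white", "black"], covariate_set="no_education"),
            DecompositionConfig(exposure_levels=["white", "black"], truncation_percentile=95.0),
            DecompositionConfig(exposure_levels=["white", "black"], normalize_weights=True),
        ):
            fit, _, _, _, design = _decompose_stratum(df, cfg, ["white", "black"])
            engine = StratumEngine(df, cfg, ["white", "black"])
            beta = engine.fit(np.arange(len(df)))
            assert beta == pytest.approx(fit.beta, abs=1e-10), cfg


@pytest.fixture(scope="module")
def small():
    p = mh.default_params(n=1200)
    p.sex_probs = {"men": 1.0}
    return mh.generate_cohort(p, seed=23)


class TestBootstrap:
    def test_deterministic_given_seed(self, small, binary_config):
        a = mh.bootstrap_ci(small, binary_config, B=50, seed=9)
        b = mh.bootstrap_ci(small, binary_config, B=50, seed=9)
        assert a.ci == b.ci
        c = mh.bootstrap_ci(small, binary_config, B=50, seed=10)
        assert a.ci != c.ci

    def test_cis_contain_point_estimates(self, small, binary_config):
        res = mh.bootstrap_ci(small, binary_config, B=50, seed=9)
        for key, comps in res.estimates.items():
            for name, est in comps.items():
                lo, hi = res.ci[key][name]
                assert lo <= est <= hi, (key, name)

    def test_minimum_replicates_enforced(self, small, binary_config):
        with pytest.raises(DomainError):
            mh.bootstrap_ci(small, binary_config, B=10, seed=1)


class TestReportTable:
    def test_rounding_half_away_from_zero(self):
        from medhaz._util import round_half_away

        assert round_half_away(1.45, 1) == 1.5
        assert round_half_away(-1.45, 1) == -1.5
        assert round_half_away(2.249, 1) == 2.2

    def test_layout_and_consistency(self, binary_cohort, binary_config):
        res = mh.run_decomposition(binary_cohort, binary_config)
        df, text = report_table(res)
        assert df.index[0].startswith("Effect of race/ethnicity")
        assert df.index[1].startswith("'Direct'")
        assert df.index[2].startswith("Net indirect")
        assert df.index[3].startswith("Alcohol use: differential exposure")
        # text rendering carries the same numbers as the frame
        for label in df.index:
            cell = df.loc[label].iloc[0]
            assert cell.split(" ")[0] in text


class TestPublishedTable:
    def test_reconstructed_identities_hold_to_printed_precision(self):
        disc = additivity_discrepancies()
        assert set(disc) == set(PUBLISHED_DECOMPOSITION)
        for key, d in disc.items():
            assert d["total_identity"] <= 0.1 + 1e-9, key
            assert d["net_indirect_identity"] <= 0.1 + 1e-9, key


class TestSimulationStudy:
    def test_reproducible_and_schema(self, binary_params, binary_config):
        p = copy.deepcopy(binary_params)
        p.n = 1500
        kw = dict(n_reps=3, seed=5, config=binary_config, ci_method="sandwich", truth_size=20_000)
        a = mh.simulation_study(p, **kw)
        b = mh.simulation_study(p, **kw)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["component"]) == set(component_names(["white", "black"]))
        for col in ("true", "bias", "rmse", "ci_coverage"):
            assert np.isfinite(a[col]).all()

    def test_rmse_shrinks_with_n(self, binary_params, binary_config):
        small = copy.deepcopy(binary_params)
        small.n = 1500
        big = copy.deepcopy(binary_params)
        big.n = 6000
        kw = dict(n_reps=8, seed=6, config=binary_config, ci_method="sandwich", truth_size=50_000)
        r_small = mh.simulation_study(small, **kw)
        r_big = mh.simulation_study(big, **kw)
        assert r_big["rmse"].mean() < r_small["rmse"].mean()
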