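"""Counterfactual expansion and marginal-structural weights."""

import numpy as np
import pytest

import medhaz as mh
from medhaz.cohort import MEDIATORS
from medhaz.exceptions import DomainError, SchemaError
from medhaz.expand import RSTAR_COLUMNS
from medhaz.mediators import PredictorSpec, fit_mediator_model
from tests.conftest import toy_cohort_frame


@pytest.fixture(scope="module")
def stratum(binary_cohort):
    return binary_cohort.main_analysis().stratum("men")


@pytest.fixture(scope="module")
def models(stratum):
    spec = PredictorSpec(race_levels=("black",))
    return {m: fit_mediator_model(stratum, m, spec) for m in MEDIATORS}


class TestExpansion:
    def test_binary_replicate_count(self):
        df = toy_cohort_frame(3)
        df["race_ethnicity"] = ["white", "black", "white"]
        expanded = mh.expand_cohort(mh.Cohort(df), ["white", "black"])
        assert len(expanded.data) == 3 * 2**4 == 48

    def test_three_level_replicate_count(self):
        df = toy_cohort_frame(2)
        df["race_ethnicity"] = ["white", "hispanic"]
        expanded = mh.expand_cohort(mh.Cohort(df), ["white", "black", "hispanic"])
        assert len(expanded.data) == 2 * 3**4 == 162

    def test_identity_replicate_present_exactly_once(self, stratum):
        expanded = mh.expand_cohort(stratum.data.head(50), ["white", "black"])
        d = expanded.data
        ident = np.ones(len(d), dtype=bool)
        for col in RSTAR_COLUMNS:
            ident &= (d[col] == d["race_ethnicity"]).to_numpy()
        assert ident.sum() == 50
        assert d.loc[ident, "subject_id"].nunique() == 50

    def test_survival_fields_copied_unchanged(self, stratum):
        head = stratum.data.head(10)
        expanded = mh.expand_cohort(head, ["white", "black"]).data
        for col in ("entry_age", "exit_age", "event"):
            assert np.array_equal(np.repeat(head[col].to_numpy(), 16), expanded[col].to_numpy())

    def test_unknown_exposure_level_rejected(self):
        df = toy_cohort_frame(3)
        df["race_ethnicity"] = ["white", "black", "white"]
        with pytest.raises(SchemaError):
            mh.expand_cohort(mh.Cohort(df), ["white"])  # black rows present


class TestWeights:
    def test_identity_weight_exactly_one(self, stratum, models):
        expanded = mh.expand_cohort(stratum.data.head(200), ["white", "black"])
        weighted = mh.compute_weights(expanded, models)
        d = weighted.data
        ident = np.ones(len(d), dtype=bool)
        for col in RSTAR_COLUMNS:
            ident &= (d[col] == d["race_ethnicity"]).to_numpy()
        assert np.all(d.loc[ident, "w"].to_numpy() == 1.0)  # exact, not approx
        assert np.all(d["w"].to_numpy() > 0)

    def test_exposure_independent_models_give_unit_weights(self, stratum, models):
        null_models = {}
        for med, m in models.items():
            coef = m.coef.copy()
            coef[:, 1] = 0.0  # remove the race dummy from the fitted model
            null_models[med] = mh.MediatorModel(
                m.mediator_name, m.levels, coef, m.spec, True, 0.0
            )
        expanded = mh.expand_cohort(stratum.data.head(200), ["white", "black"])
        weighted = mh.compute_weights(expanded, null_models)
        assert np.all(weighted.data["w"].to_numpy() == 1.0)

    def test_hand_computed_single_mediator_weight(self):
        # one subject, one binary mediator with observed-level probability
        # 0.3 under the observed exposure and 0.6 under the counterfactual:
        # the counterfactual replicate carries weight 2
        df = toy_cohort_frame(1)
        df["race_ethnicity"] = ["white"]
        df["smoking_category"] = "former"
        spec = PredictorSpec(race_levels=("black",))
        coef = np.zeros((1, 7))
        coef[0, 0] = np.log(0.3 / 0.7)
        coef[0, 1] = np.log(0.6 / 0.4) - np.log(0.3 / 0.7)
        model = mh.MediatorModel("smoking_category", ["never", "former"], coef, spec, True, 0.0)
        expanded = mh.expand_cohort(mh.Cohort(df), ["white", "black"], ["smoking_category"])
        weighted = mh.compute_weights(expanded, {"smoking_category": model})
        d = weighted.data.set_index("rstar_smoking")
        assert d.loc["white", "w"] == 1.0
        assert d.loc["black", "w"] == pytest.approx(2.0, rel=1e-12)

    def test_weight_sum_invariant_to_mediator_order(self, stratum, models):
        head = stratum.data.head(100)
        order1 = list(MEDIATORS)
        order2 = list(reversed(MEDIATORS))
        sums = []
        for order in (order1, order2):
            expanded = mh.expand_cohort(head, ["white", "black"], order)
            weighted = mh.compute_weights(expanded, models)
            sums.append(weighted.data.groupby("subject_id")["w"].sum().sort_index())
        assert sums[0].to_numpy() == pytest.approx(sums[1].to_numpy(), rel=1e-12)

    def test_weighted_replicates_match_counterfactual_law(self, binary_params):
        # under the generator, weighting level-r* replicates reproduces
        # the mediator law under exposure r*
        import copy

        p = copy.deepcopy(binary_params)
        p.n = 40_000
        cohort = mh.generate_cohort(p, seed=2718)
        stratum = cohort.main_analysis().stratum("men")
        spec = p.predictor_spec
        models = {m: fit_mediator_model(stratum, m, spec) for m in MEDIATORS}
        expanded = mh.compute_weights(
            mh.expand_cohort(stratum, ["white", "black"]), models
        )
        d = expanded.data
        law = p.laws_for("men")[3]  # activity
        # white subjects, auxiliary exposure black for activity only
        mask = (
            (d["race_ethnicity"] == "white")
            & (d["rstar_activity"] == "black")
            & (d["rstar_alcohol"] == "white")
            & (d["rstar_smoking"] == "white")
            & (d["rstar_bmi"] == "white")
        )
        sub = d[mask]
        w = sub["w"].to_numpy()
        # weighted level frequencies vs the true law at exposure black
        X1 = p.predictor_spec.build(sub, race_override="black")
        P_true = law.probs(X1).mean(axis=0)
        for j, lev in enumerate(law.levels):
            obs = np.average((sub["activity_category"] == lev).to_numpy(), weights=w)
            mc_se = np.sqrt(P_true[j] * (1 - P_true[j]) / len(sub))
            assert abs(obs - P_true[j]) < 4 * mc_se, lev


class TestTruncation:
    def test_identity_at_100(self, stratum, models):
        expanded = mh.compute_weights(
            mh.expand_cohort(stratum.data.head(100), ["white", "black"]), models
        )
        out = mh.truncate_weights(expanded, 100.0)
        assert np.array_equal(out.data["w"].to_numpy(), expanded.data["w"].to_numpy())
        assert out.truncation["n_clipped"] == 0

    def test_equal_weights_unchanged(self, stratum):
        expanded = mh.expand_cohort(stratum.data.head(10), ["white", "black"])
        expanded.data["w"] = 1.0
        out = mh.truncate_weights(expanded, 90.0)
        assert np.all(out.data["w"] == 1.0)

    def test_hand_percentile(self):
        # weights {1 x 9, 100}: the 90th percentile by linear interpolation
        # sits at sorted position 8.1, i.e. 1 + 0.1 * 99 = 10.9
        import pandas as pd

        from medhaz.expand import ExpandedData

        toy = ExpandedData(
            pd.DataFrame({"w": [1.0] * 9 + [100.0]}), ["white", "black"]
        )
        out = mh.truncate_weights(toy, 90.0)
        assert out.truncation["cap"] == pytest.approx(10.9)
        assert out.data["w"].max() == pytest.approx(10.9)
        assert out.truncation["n_clipped"] == 1
        assert out.truncation["mass_removed"] == pytest.approx(100.0 - 10.9)

    def test_percentile_domain(self, stratum, models):
        expanded = mh.compute_weights(
            mh.expand_cohort(stratum.data.head(10), ["white", "black"]), models
        )
        for bad in (50.0, 101.0, 0.0):
            with pytest.raises(DomainError):
                mh.truncate_weights(expanded, bad)

    def test_effective_sample_size(self):
        assert mh.effective_sample_size(np.ones(10)) == pytest.approx(10.0)
        assert mh.effective_sample_size(np.array([1.0, 0.0])) == pytest.approx(1.0)
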