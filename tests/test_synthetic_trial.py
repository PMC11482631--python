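"""Design balance, generative identities and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from feedsid import prediction as pred
from feedsid import synthetic_trial as st


class TestDesign:
    def test_default_balance(self):
        design = st.build_design(seed=0)
        df = design.assignments
        assert len(df) == 66
        assert (df["diet_id"].value_counts() == 6).all()
        per_cell = df.groupby(["square", "period"])["diet_id"].nunique()
        assert (per_cell == 11).all()
        assert (df.groupby("pig_id")["diet_id"].nunique() == 3).all()

    def test_deterministic_for_seed(self):
        a = st.build_design(seed=123).assignments
        b = st.build_design(seed=123).assignments
        pd.testing.assert_frame_equal(a, b)
        c = st.build_design(seed=124).assignments
        assert not a.equals(c)

    @given(seed=hst.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_balance_for_any_seed(self, seed):
        design = st.build_design(seed=seed)
        design.validate()  # raises on any balance violation

    def test_incompatible_counts(self):
        with pytest.raises(ValueError):
            st.build_design(n_pigs=20, n_diets=11)
        with pytest.raises(ValueError):
            st.build_design(n_pigs=6, n_diets=3, n_periods=3)


class TestGenerate:
    def test_noise_free_chain_recovers_truth_exactly(self, bundle,
                                                     noise_free_trial):
        est = st.run_estimation(noise_free_trial)
        truth = noise_free_trial.truth
        for (diet_id, comp), true_sid in truth.true_sid.items():
            assert est.sid_means.loc[comp, diet_id] == \
                pytest.approx(true_sid, abs=1e-9)
        for comp, true_loss in truth.true_endogenous.items():
            assert est.endogenous[comp] == pytest.approx(true_loss, abs=1e-12)

    def test_noise_free_replicates_identical(self, noise_free_trial):
        est = st.run_estimation(noise_free_trial)
        spread = est.replicates.groupby(["diet_id", "component"])["sid_pct"] \
                               .agg(lambda v: v.max() - v.min())
        assert (spread < 1e-9).all()

    def test_marker_mass_balance(self, noise_free_trial):
        for obs in noise_free_trial.digesta:
            diet = noise_free_trial.diets[obs.diet_id]
            from feedsid import digestibility as dig
            assert obs.marker_dm >= dig.diet_marker_dm(diet)

    def test_sid_above_aid_in_every_replicate(self, bundle, diet_ids):
        truth = st.default_ground_truth(
            bundle.ingredients, bundle.sid, bundle.endogenous,
            noise_cv=0.05, seed=21)
        sim = st.generate_trial(
            bundle.ingredients, truth, st.build_design(seed=21,
                                                       diet_ids=diet_ids))
        est = st.run_estimation(sim)
        assert (est.replicates["sid_pct"] > est.replicates["aid_pct"]).all()

    def test_same_seed_reproduces_digesta(self, bundle, diet_ids):
        def make():
            truth = st.default_ground_truth(
                bundle.ingredients, bundle.sid, bundle.endogenous,
                noise_cv=0.08, seed=5)
            return st.generate_trial(
                bundle.ingredients, truth,
                st.build_design(seed=5, diet_ids=diet_ids))
        a, b = make(), make()
        for oa, ob in zip(a.digesta, b.digesta):
            assert oa.conc_dm == ob.conc_dm

    def test_negative_implied_flow_floored_with_warning(self, bundle, diet_ids):
        truth = st.TrialGroundTruth(
            true_sid={(i.sample_id, "Lys"): 105.0 for i in bundle.ingredients},
            true_endogenous={"Lys": 0.0},
            noise_cv=0.0, seed=1)
        design = st.build_design(seed=1, diet_ids=diet_ids)
        with pytest.warns(UserWarning, match="floored"):
            sim = st.generate_trial(bundle.ingredients, truth, design)
        for obs in sim.test_observations:
            assert obs.conc_dm["Lys"] == 0.0

    def test_unknown_design_diet(self, bundle):
        truth = st.TrialGroundTruth(true_sid={}, true_endogenous={"CP": 1.0})
        design = st.build_design(seed=0)  # generic D01..D11 labels
        with pytest.raises(ValueError, match="without an ingredient"):
            st.generate_trial(bundle.ingredients, truth, design)


class TestRecovery:
    def test_noise_free_bias_is_zero(self, noise_free_trial):
        est = st.run_estimation(noise_free_trial)
        report = st.recovery_report(noise_free_trial.truth, est)
        assert report["bias"].abs().max() < 1e-9
        assert report["rmse"].max() < 1e-9

    def test_missing_component_raises(self, bundle, noise_free_trial):
        est = st.run_estimation(noise_free_trial)
        truth = st.TrialGroundTruth(
            true_sid={("RSC1", "CP"): 80.0, ("NOPE", "CP"): 80.0},
            true_endogenous={"CP": 21.0})
        with pytest.raises(KeyError):
            st.recovery_report(truth, est)

    def test_noise_increases_rmse(self, bundle, diet_ids):
        """Average RMSE over seeds does not decrease when assay noise doubles."""
        def mean_rmse(noise_cv):
            vals = []
            for seed in range(8):
                truth = st.default_ground_truth(
                    bundle.ingredients, bundle.sid, bundle.endogenous,
                    noise_cv=noise_cv, seed=seed)
                sim = st.generate_trial(
                    bundle.ingredients, truth,
                    st.build_design(seed=seed, diet_ids=diet_ids))
                report = st.recovery_report(truth, st.run_estimation(sim))
                vals.append(report.loc["CP", "rmse"])
            return np.mean(vals)
        assert mean_rmse(0.10) >= mean_rmse(0.05)

    def test_planted_slope_recovered(self, bundle, diet_ids):
        ndf = {i.sample_id: i.proximate["NDF"] for i in bundle.ingredients}
        truth = st.TrialGroundTruth(
            true_sid={(s, "Lys"): 100.0 - 1.2 * v for s, v in ndf.items()},
            true_endogenous={"Lys": 0.08}, noise_cv=0.05, seed=3)
        sim = st.generate_trial(bundle.ingredients, truth,
                                st.build_design(seed=3, diet_ids=diet_ids))
        est = st.run_estimation(sim)
        x = pd.DataFrame({"NDF": [ndf[d] for d in est.sid_means.columns]},
                         index=est.sid_means.columns)
        model = pred.ols_fit(x, est.sid_means.loc["Lys", x.index],
                             response="SID_Lys")
        report = st.recovery_report(truth, est, models={"Lys": model},
                                    planted_slopes={"Lys": ("NDF", -1.2)})
        assert abs(report.loc["Lys", "slope_bias"]) < 0.2
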