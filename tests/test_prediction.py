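"""BLUP prediction and the cross-validation scenario machinery."""

import numpy as np
import pandas as pd
import pytest

from tetragp.prediction import (
    PredictionResult,
    ScenarioSpec,
    _partition,
    blup_predict,
    environment_dropout,
    prediction_ability,
    run_scenario1,
    run_scenario2,
    run_scenario3,
)
from tetragp.reml_core import reml_fit_multienv

from conftest import henderson_blup


class TestPredictionAbility:
    def test_perfect_and_inverted_prediction(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert prediction_ability(x, x) == pytest.approx(1.0)
        assert prediction_ability(x, -x) == pytest.approx(-1.0)

    def test_toy_vectors_match_hand_computation(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # hand computation: cov = 2.0, sd_p = sqrt(2), sd_o = sqrt(2.96)
        expect = 2.0 / (np.sqrt(2.0) * np.sqrt(2.96))
        assert prediction_ability(pred, obs) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(prediction_ability(np.ones(5), np.arange(5.0)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prediction_ability(np.ones(3), np.ones(4))


class TestScenarioSpec:
    def test_invalid_scenario_and_model_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario=4, target="NL.18")
        with pytest.raises(ValueError):
            ScenarioSpec(scenario=2, target="NL.18", model="XX")


class TestPartition:
    def test_partitions_depend_only_on_seed_and_rep(self):
        ids = [f"g{i}" for i in range(20)]
        a = _partition(ids, 12, seed=3, rep=5)
        b = _partition(ids, 12, seed=3, rep=5)
        c = _partition(ids, 12, seed=3, rep=6)
        assert a == b
        assert a != c
        assert len(a[0]) == 12 and len(a[1]) == 8
        assert not set(a[0]) & set(a[1])


class TestBlupPredict:
    def test_matches_henderson_mixed_model_equations(self, small_us_panel):
        blues = small_us_panel["blues"]
        gr = small_us_panel["gr"]
        # MME oracle inverts G (x) Sigma_E, so use a well-conditioned G on
        # both sides of the comparison
        import pandas as pd_

        Gc = gr.G + 0.05 * np.eye(gr.G.shape[0])
        Gdf = pd_.DataFrame(Gc, index=gr.genotype_ids, columns=gr.genotype_ids)
        fit = reml_fit_multienv(blues, Gdf, "US", n_restarts=1)
        recs = blues[["genotype_id", "env", "value"]]
        ids = list(gr.genotype_ids)
        target = fit.env_labels[1]
        ghat = blup_predict(fit, Gdf, recs, ids, target)
        # independent oracle: Henderson's MME on the same fitted components
        pos = {g: i for i, g in enumerate(ids)}
        e_pos = {e: j for j, e in enumerate(fit.env_labels)}
        g_idx = recs["genotype_id"].map(pos).to_numpy()
        e_idx = recs["env"].map(e_pos).to_numpy()
        y = recs["value"].to_numpy() - fit.env_means[e_idx]
        _, u = henderson_blup(
            y, g_idx, e_idx, Gc, fit.sigma_e, fit.residual_vars
        )
        np.testing.assert_allclose(ghat, u[:, 1], atol=1e-6)

    def test_unrelated_genotype_shrunk_to_zero(self, small_us_panel):
        blues, gr = small_us_panel["blues"], small_us_panel["gr"]
        fit = reml_fit_multienv(blues, gr.to_frame(), "CS", n_restarts=0)
        Gx = gr.to_frame().copy()
        stranger = "STRANGER"
        Gx[stranger] = 0.0
        Gx.loc[stranger] = 0.0
        Gx.loc[stranger, stranger] = 1.0
        recs = blues[["genotype_id", "env", "value"]]
        ghat = blup_predict(fit, Gx, recs, [stranger], fit.env_labels[0])
        assert ghat[0] == pytest.approx(0.0, abs=1e-10)

    def test_main_effects_predictions_identical_across_environments(self, small_us_panel):
        blues, gr = small_us_panel["blues"], small_us_panel["gr"]
        fit = reml_fit_multienv(blues, gr.to_frame(), "ME", n_restarts=0)
        recs = blues[["genotype_id", "env", "value"]]
        ids = gr.genotype_ids[:10]
        per_env = [
            blup_predict(fit, gr.to_frame(), recs, ids, env) for env in fit.env_labels
        ]
        for other in per_env[1:]:
            np.testing.assert_allclose(other, per_env[0], atol=1e-10)

    def test_unknown_target_environment_rejected(self, small_us_panel):
        blues, gr = small_us_panel["blues"], small_us_panel["gr"]
        fit = reml_fit_multienv(blues, gr.to_frame(), "CS", n_restarts=0)
        with pytest.raises(ValueError, match="target environment"):
            blup_predict(
                fit, gr.to_frame(), blues[["genotype_id", "env", "value"]],
                gr.genotype_ids[:3], "XX.99",
            )


class TestScenarioRunners:
    def test_repetition_count_and_held_out_size(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        spec = ScenarioSpec(scenario=2, target="NL.18", model="CS", n_reps=4, seed=1)
        res = run_scenario2(blues, gr, spec)
        assert len(res.abilities) == 4
        assert res.n_test == [42] * 4  # 147 - 105 held out every repetition

    def test_single_environment_baseline_runs(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        spec = ScenarioSpec(scenario=2, target="NL.18", model="SE", n_reps=3, seed=1)
        res = run_scenario2(blues, gr, spec)
        assert np.isfinite(res.abilities).all()

    def test_scenario1_noise_free_identical_years_gives_ability_one(self):
        # two "years" with identical genetics and no residual noise
        rng = np.random.default_rng(0)
        n = 40
        ids = [f"g{i}" for i in range(n)]
        G = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        g = rng.normal(size=n)
        rows = []
        for year in (2017, 2018):
            for loc in ("NL", "PL"):
                for i, gid in enumerate(ids):
                    rows.append((gid, loc, year, g[i]))
        blues = pd.DataFrame(rows, columns=["genotype_id", "location", "year", "value"])
        spec = ScenarioSpec(scenario=1, target=("NL", 2018), model="ME",
                            n_train=30, n_reps=2, seed=0)
        res = run_scenario1(blues, G, spec)
        assert res.mean_ability > 0.999

    def test_scenario3_unrelated_test_genotypes_have_no_signal(self):
        rng = np.random.default_rng(1)
        n = 60
        ids = [f"g{i}" for i in range(n)]
        # near-identity G: tiny off-diagonal noise, as for an unrelated panel
        E = rng.normal(0, 0.01, size=(n, n))
        G = pd.DataFrame(np.eye(n) + 0.5 * (E + E.T), index=ids, columns=ids)
        rows = []
        for year in (2017, 2018):
            for loc in ("NL", "PL"):
                g = rng.normal(size=n)
                for i, gid in enumerate(ids):
                    rows.append((gid, loc, year, g[i] + rng.normal(0, 0.3)))
        blues = pd.DataFrame(rows, columns=["genotype_id", "location", "year", "value"])
        spec = ScenarioSpec(scenario=3, target=("NL", 2018), model="ME",
                            n_train=45, n_reps=10, seed=0)
        res = run_scenario3(blues, G, spec)
        assert abs(res.mean_ability) < 0.25

    def test_scenario3_exactly_unrelated_abilities_flagged_undefined(self):
        # with G = I the held-out predictions are constant zero: every
        # repetition's correlation is undefined and must be flagged, not faked
        rng = np.random.default_rng(2)
        n = 30
        ids = [f"g{i}" for i in range(n)]
        G = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        rows = []
        for year in (2017, 2018):
            for loc in ("NL", "PL"):
                g = rng.normal(size=n)
                for i, gid in enumerate(ids):
                    rows.append((gid, loc, year, g[i] + rng.normal(0, 0.3)))
        blues = pd.DataFrame(rows, columns=["genotype_id", "location", "year", "value"])
        spec = ScenarioSpec(scenario=3, target=("NL", 2018), model="ME",
                            n_train=22, n_reps=3, seed=0)
        res = run_scenario3(blues, G, spec)
        assert res.n_undefined == 3

    def test_ability_invariant_to_environment_level_shift(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        spec = ScenarioSpec(scenario=2, target="NL.18", model="CS", n_reps=2, seed=3)
        base = run_scenario2(blues, gr, spec)
        shifted = blues.copy()
        mask = shifted["env"] == "PL.17" if "env" in shifted else None
        shifted["env"] = shifted["location"] + "." + shifted["year"].astype(str).str[-2:]
        shifted.loc[shifted["env"] == "PL.17", "value"] += 50.0
        res = run_scenario2(shifted, gr, spec)
        np.testing.assert_allclose(res.abilities, base.abilities, atol=2e-3)

    def test_missing_target_rejected(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        with pytest.raises(ValueError, match="target"):
            run_scenario2(blues, gr, ScenarioSpec(scenario=2, target="XX.99", model="CS"))
        with pytest.raises(ValueError):
            run_scenario1(
                blues, gr, ScenarioSpec(scenario=1, target=("XX", 2018), model="ME", n_reps=1)
            )


class TestEnvironmentDropout:
    def test_excluding_nothing_reproduces_full_run(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        spec = ScenarioSpec(scenario=2, target="NL.18", model="CS", n_reps=2, seed=5)
        full = run_scenario2(blues, gr, spec)
        noop = environment_dropout(blues, gr, spec, excluded_trials=[])
        np.testing.assert_allclose(noop.abilities, full.abilities, atol=1e-12)

    def test_excluding_target_rejected(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        spec = ScenarioSpec(scenario=2, target="NL.18", model="CS", n_reps=1, seed=5)
        with pytest.raises(ValueError, match="target"):
            environment_dropout(blues, gr, spec, excluded_trials=["NL.18"])

    def test_dropout_reduces_training_environments(self, study_tw_panel):
        blues, gr = study_tw_panel["blues"], study_tw_panel["gr"]
        spec = ScenarioSpec(scenario=2, target="NL.18", model="CS", n_reps=1, seed=5)
        res = environment_dropout(blues, gr, spec, excluded_trials=["PL.18", "SP.17"])
        assert np.isfinite(res.abilities).all()


class TestModelChoiceUnderKnownTruth:
    """Scenario behaviour under purpose-built generative truths."""

    def _panel(self, cfg):
        from tetragp.genomics import compute_grm
        from tetragp.synthetic_data import simulate_dosages, simulate_multienv_blues

        dosages = simulate_dosages(cfg)
        gr = compute_grm(dosages, ridge=1e-6)
        blues, _ = simulate_multienv_blues(dosages, cfg, G=gr.G)
        return gr, blues

    def test_dropping_uncorrelated_trial_does_not_hurt(self):
        # one training trial with ~zero genetic correlation to the target:
        # excluding it from ME training must not decrease ability (paired)
        from tetragp.reml_core import CovStructureSpec
        from tetragp.synthetic_data import STUDY_ENVS, SimConfig

        corr = np.full((4, 4), 0.7)
        corr[3, :] = corr[:, 3] = 0.02
        np.fill_diagonal(corr, 1.0)
        cfg = SimConfig(
            n_genotypes=150, n_markers=1500, env_labels=STUDY_ENVS[:4],
            sigma_e_spec=CovStructureSpec(
                "US", 4, {"variances": np.ones(4), "correlations": corr}
            ),
            residual_vars=np.full(4, 0.3), seed=21, family_size=5,
        )
        gr, blues = self._panel(cfg)
        target, noise_trial = cfg.labels[0], cfg.labels[3]
        spec = ScenarioSpec(scenario=2, target=target, model="ME",
                            n_train=105, n_reps=20, seed=3)
        full = run_scenario2(blues, gr, spec)
        dropped = environment_dropout(blues, gr, spec, [noise_trial])
        assert dropped.mean_ability >= full.mean_ability

    def test_zero_cross_region_correlation_makes_single_region_best(self):
        # genetic correlation 0.8 within a region across years, 0 between
        # regions: pooling regions with an ME model can only dilute
        from tetragp.reml_core import CovStructureSpec
        from tetragp.synthetic_data import STUDY_ENVS, SimConfig

        C = np.eye(6)
        for i in range(6):
            for j in range(6):
                if i != j and STUDY_ENVS[i][0] == STUDY_ENVS[j][0]:
                    C[i, j] = 0.8
        cfg = SimConfig(
            n_genotypes=150, n_markers=1500,
            sigma_e_spec=CovStructureSpec(
                "US", 6, {"variances": np.ones(6), "correlations": C}
            ),
            residual_vars=np.full(6, 0.3), seed=22, family_size=5,
        )
        gr, blues = self._panel(cfg)
        se = run_scenario1(blues, gr, ScenarioSpec(
            scenario=1, target=("NL", 2018), model="SE", n_reps=20, seed=4))
        me = run_scenario1(blues, gr, ScenarioSpec(
            scenario=1, target=("NL", 2018), model="ME", n_reps=20, seed=4))
        assert me.mean_ability <= se.mean_ability

    def test_homogeneous_trait_needs_no_multienvironment_model(self):
        # near-unit correlations and equal variances (dry-matter-like):
        # the single-environment baseline is within 0.03 of the best model
        from tetragp.synthetic_data import dry_matter_config

        cfg = dry_matter_config(seed=23, n_markers=1500)
        gr, blues = self._panel(cfg)
        abilities = {
            m: run_scenario2(blues, gr, ScenarioSpec(
                scenario=2, target="NL.18", model=m, n_reps=10, seed=5
            )).mean_ability
            for m in ("SE", "ME", "CS", "UN_HET", "US")
        }
        best_multi = max(v for k, v in abilities.items() if k != "SE")
        assert abs(abilities["SE"] - best_multi) < 0.03


class TestPredictionResult:
    def test_out_of_range_ability_rejected(self):
        with pytest.raises(ValueError):
            PredictionResult(scenario=2, target="t", model="CS", abilities=np.array([1.5]))

    def test_nan_handling_in_mean(self):
        res = PredictionResult(
            scenario=2, target="t", model="CS", abilities=np.array([0.5, np.nan, 0.7])
        )
        assert res.mean_ability == pytest.approx(0.6)
        assert res.n_undefined == 1
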