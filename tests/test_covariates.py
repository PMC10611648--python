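"""Stage-2 design matrices, logit fitting, stepwise selection, ROC, marginals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from camtrigger import (
    DEFAULT_DETECTION_SPEC,
    TriggerGLM,
    backward_stepwise,
    build_design_matrix,
    collinearity_check,
    combined_detection_probability,
    default_simulation_config,
    fit_logit,
    marginal_effects,
    predict_probability,
    roc_auc,
    simulate_trials,
)
from camtrigger.covariates import LogitFit


class TestBuildDesignMatrix:
    def test_distance_model_column_is_stage1_probability(self, sim_frame, true_detfun):
        X, term_map = build_design_matrix(sim_frame, ["distance_model"], true_detfun)
        expected = true_detfun.detection_probability(sim_frame["distance_m"].to_numpy())
        np.testing.assert_allclose(X["distance_model"], expected)
        assert term_map["distance_model"] == ["distance_model"]
        assert (X["Intercept"] == 1.0).all()

    def test_reference_levels_code_to_zero(self, sim_frame, true_detfun):
        X, _ = build_design_matrix(sim_frame, ["body_size", "camera_model"], true_detfun)
        hp2x = sim_frame["camera_model"] == "HP2X"
        assert (X.loc[hp2x.to_numpy(), "camera_model[PC900]"] == 0).all()
        lu = sim_frame["body_size"] == "large_ungulate"
        assert (X.loc[lu.to_numpy(), ["body_size[medium]", "body_size[large]"]] == 0).all().all()

    def test_interaction_column_is_elementwise_product(self, sim_frame, true_detfun):
        X, term_map = build_design_matrix(
            sim_frame, ["body_size", "distance_model", "body_size:distance_model"], true_detfun)
        col = "body_size[medium]:distance_model"
        assert col in term_map["body_size:distance_model"]
        np.testing.assert_allclose(
            X[col], X["body_size[medium]"] * X["distance_model"], atol=1e-15)
        # a medium-proxy row with p-hat = 0.8 yields an interaction entry of 0.8
        medium = (sim_frame["body_size"] == "medium").to_numpy()
        idx = np.flatnonzero(medium)[0]
        assert X[col].iloc[idx] == pytest.approx(X["distance_model"].iloc[idx])

    def test_unseen_level_rejected_by_name(self, sim_frame, true_detfun):
        frame = sim_frame.copy()
        frame.loc[frame.index[0], "body_size"] = "enormous"
        with pytest.raises(ValueError, match="enormous"):
            build_design_matrix(frame, ["body_size"], true_detfun)


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 18 + [0] * 12, dtype=float)
        X = pd.DataFrame({"Intercept": np.ones(30)})
        fit = fit_logit(X, y)
        assert fit.params["Intercept"] == pytest.approx(logit(0.6), abs=1e-6)

    def test_binary_covariate_recovers_log_odds_ratio(self):
        # 2x2 contingency oracle: cells (x=0: 30/50 success), (x=1: 10/40)
        x = np.array([0] * 50 + [1] * 40, dtype=float)
        y = np.array([1] * 30 + [0] * 20 + [1] * 10 + [0] * 30, dtype=float)
        X = pd.DataFrame({"Intercept": np.ones(90), "x": x})
        fit = fit_logit(X, y)
        log_or = math.log((10 / 30) / (30 / 20))
        assert fit.params["x"] == pytest.approx(log_or, abs=1e-6)
        assert fit.zvalues["x"] == pytest.approx(fit.params["x"] / fit.bse["x"])

    def test_matches_direct_likelihood_maximization(self, rng):
        n = 40
        X = pd.DataFrame({
            "Intercept": np.ones(n),
            "a": rng.normal(size=n),
            "b": rng.uniform(-1, 1, n),
        })
        eta = 0.4 + 0.8 * X["a"] - 1.1 * X["b"]
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = fit_logit(X, y)

        A = X.to_numpy()

        def nll(beta):
            e = A @ beta
            return -np.sum(y * e - np.log1p(np.exp(e)))

        direct = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(fit.params.to_numpy(), direct.x, atol=1e-6)

    def test_rank_deficiency_names_collinear_column(self):
        n = 20
        rng = np.random.default_rng(0)
        a = rng.normal(size=n)
        X = pd.DataFrame({"Intercept": np.ones(n), "a": a, "twice_a": 2 * a})
        with pytest.raises(ValueError, match="collinear") as excinfo:
            fit_logit(X, rng.integers(0, 2, n).astype(float))
        named = str(excinfo.value).split(":")[-1]
        assert "a" in named or "twice_a" in named

    def test_complete_separation_flagged(self):
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(float)
        X = pd.DataFrame({"Intercept": np.ones(30), "x": x})
        fit = fit_logit(X, y)
        assert fit.converged is False
        assert "separation" in (fit.diagnostic or "")


class TestBackwardStepwise:
    TERMS = ("body_size", "camera_model", "distance_model", "speed", "sun_azimuth",
             "body_size:distance_model", "camera_model:distance_model")

    def test_all_significant_model_is_fixed_point(self):
        frame = simulate_trials(default_simulation_config(seed=3, replicates=5))
        y = frame["outcome"].to_numpy(dtype=float)
        fit, kept = backward_stepwise(
            frame, y, ["distance_model", "speed"], DEFAULT_DETECTION_SPEC)
        assert kept == ["distance_model", "speed"]
        assert (fit.pvalues.drop("Intercept") <= 0.05).all()

    def test_pure_noise_covariate_usually_removed(self):
        # sun_altitude enters the generator with no effect; over 50 seeded
        # runs stepwise should drop it at least 90% of the time
        removed = 0
        for seed in range(50):
            frame = simulate_trials(default_simulation_config(seed=200 + seed, replicates=5))
            _, kept = backward_stepwise(
                frame, frame["outcome"].to_numpy(dtype=float),
                list(self.TERMS) + ["sun_altitude"], DEFAULT_DETECTION_SPEC)
            removed += int("sun_altitude" not in kept)
        assert removed >= 45

    def test_marginality_protects_parent_of_significant_interaction(self):
        # interaction strong, parent main effect null: the parent must stay
        cfg = default_simulation_config(seed=5, replicates=5)
        cfg.coefficients = {
            "Intercept": -2.0, "distance_model": 5.0, "speed": -1.0,
            "body_size[medium]:distance_model": 3.0,
        }
        frame = simulate_trials(cfg)
        fit, kept = backward_stepwise(
            frame, frame["outcome"].to_numpy(dtype=float),
            ["body_size", "distance_model", "speed", "body_size:distance_model"],
            DEFAULT_DETECTION_SPEC)
        if "body_size:distance_model" in kept:
            assert "body_size" in kept
        assert "body_size:distance_model" in kept  # the interaction is real

    def test_removal_strictly_shrinks_term_count(self, sim_frame):
        y = sim_frame["outcome"].to_numpy(dtype=float)
        _, kept = backward_stepwise(
            sim_frame, y, list(self.TERMS) + ["sun_altitude"], DEFAULT_DETECTION_SPEC)
        assert len(kept) <= len(self.TERMS) + 1
        assert all(t in list(self.TERMS) + ["sun_altitude"] for t in kept)


def _manual_fit(params: dict, term_map: dict, cov=None) -> LogitFit:
    labels = list(params)
    s = pd.Series(params)
    V = pd.DataFrame(cov if cov is not None else np.eye(len(labels)) * 1e-4,
                     index=labels, columns=labels)
    bse = pd.Series(np.sqrt(np.diag(V)), index=labels)
    from scipy import stats
    z = s / bse
    return LogitFit(params=s, bse=bse, zvalues=z,
                    pvalues=pd.Series(2 * stats.norm.sf(np.abs(z)), index=labels),
                    cov_params=V, log_likelihood=0.0, converged=True, n=0,
                    term_map=term_map)


class TestPrediction:
    def test_zero_coefficients_predict_one_half(self, sim_frame, true_detfun):
        fit = _manual_fit({"Intercept": 0.0, "distance_model": 0.0},
                          {"distance_model": ["distance_model"]})
        p = predict_probability(fit, sim_frame, true_detfun)
        np.testing.assert_allclose(p, 0.5)

    def test_inverse_logit_arithmetic(self, sim_frame, true_detfun):
        # a linear predictor of 6.803 alone maps to ~0.9989
        fit = _manual_fit({"Intercept": 6.803}, {})
        p = predict_probability(fit, sim_frame.head(5), true_detfun)
        np.testing.assert_allclose(p, 1 / (1 + math.exp(-6.803)))

    def test_matches_hand_computed_rows(self, sim_frame, true_detfun):
        fit = _manual_fit({"Intercept": 0.2, "speed": -0.9, "distance_model": 2.0},
                          {"speed": ["speed"], "distance_model": ["distance_model"]})
        sub = sim_frame.head(5)
        phat = true_detfun.detection_probability(sub["distance_m"].to_numpy())
        expected = expit(0.2 - 0.9 * sub["speed_mps"].to_numpy() + 2.0 * phat)
        np.testing.assert_allclose(predict_probability(fit, sub, true_detfun), expected)


class TestMarginalEffects:
    def test_intercept_only_constant_across_grid(self, sim_frame, true_detfun):
        fit = _manual_fit({"Intercept": 0.7}, {})
        table = marginal_effects(fit, sim_frame, true_detfun, "speed", [0.5, 1.0, 2.0])
        assert table["probability"].nunique() == 1

    def test_closed_form_average_of_predictions(self, sim_frame, true_detfun):
        fit = _manual_fit({"Intercept": 0.3, "speed": -0.7, "sun_azimuth": 0.4},
                          {"speed": ["speed"], "sun_azimuth": ["sun_azimuth"]})
        g = 1.3
        table = marginal_effects(fit, sim_frame, true_detfun, "speed", [g])
        z = sim_frame["sun_azimuth_rad"].to_numpy()
        expected = expit(0.3 - 0.7 * g + 0.4 * z).mean()
        assert table["probability"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_categorical_grid_outside_levels_rejected(self, sim_frame, true_detfun):
        fit = _manual_fit({"Intercept": 0.0, "body_size[medium]": 1.0, "body_size[large]": 0.5},
                          {"body_size": ["body_size[medium]", "body_size[large]"]})
        with pytest.raises(ValueError, match="levels"):
            marginal_effects(fit, sim_frame, true_detfun, "body_size", ["huge"])

    def test_level_frequency_weighted_group_means_recover_overall_mean(
            self, sim_frame, true_detfun):
        model = TriggerGLM(terms=("body_size", "distance_model", "speed"),
                           detection_function=true_detfun).fit(sim_frame)
        p = model.predict_proba(sim_frame)[:, 1]
        groups = pd.Series(p).groupby(sim_frame["body_size"].to_numpy())
        weights = sim_frame["body_size"].value_counts(normalize=True)
        weighted = sum(weights[lvl] * groups.mean()[lvl] for lvl in weights.index)
        assert weighted == pytest.approx(p.mean(), abs=1e-10)

    def test_delta_method_se_close_to_bootstrap(self):
        rng = np.random.default_rng(9)
        n = 600
        frame = simulate_trials(default_simulation_config(seed=21, replicates=2)).head(n)
        model = TriggerGLM(terms=("distance_model", "speed"),
                           detection_function=DEFAULT_DETECTION_SPEC).fit(frame)
        grid = [1.0]
        delta_se = model.marginal_effects(frame, "speed", grid)["se"].iloc[0]

        boots = []
        y = frame["outcome"].to_numpy(dtype=float)
        for _ in range(500):
            idx = rng.integers(0, n, n)
            bframe = frame.iloc[idx].reset_index(drop=True)
            try:
                bm = TriggerGLM(terms=("distance_model", "speed"),
                                detection_function=DEFAULT_DETECTION_SPEC).fit(bframe)
            except ValueError:
                continue
            boots.append(bm.marginal_effects(frame, "speed", grid)["probability"].iloc[0])
        boot_se = np.std(boots, ddof=1)
        assert delta_se == pytest.approx(boot_se, rel=0.15)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        roc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        roc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert roc.auc == pytest.approx(0.5)

    def test_known_pair_count_example(self):
        roc = roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2])
        assert roc.auc == pytest.approx(0.75)

    def test_curve_endpoints(self):
        roc = roc_auc([0, 1, 1, 0, 1], [0.2, 0.6, 0.9, 0.5, 0.3])
        assert (roc.sensitivities[0], 1 - roc.specificities[0]) == (0.0, 0.0)
        assert (roc.sensitivities[-1], 1 - roc.specificities[-1]) == (1.0, 1.0)

    def test_equals_mann_whitney_probability(self, rng):
        # exhaustive pair-count oracle, ties counted one half
        for _ in range(5):
            n = 120
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse scores force ties
            pos = scores[y == 1]
            neg = scores[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert roc_auc(y, scores).auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.2, 0.5, 0.9])


class TestCollinearityAndCombined:
    def _frame_with(self, angle, height):
        n = len(angle)
        return pd.DataFrame({
            "outcome": 1, "distance_m": 5.0, "body_size": "large",
            "camera_model": "HP2X", "lens_height_cm": height,
            "aiming_distance_m": 10.0, "vertical_angle_deg": angle,
            "speed_mps": 1.0, "sun_altitude_rad": 0.4, "sun_azimuth_rad": 1.2,
            "first_x_m": np.nan, "first_y_m": np.nan,
        })

    def test_perfect_monotone_and_antitone(self):
        f = self._frame_with([1, 2, 3, 4], [10, 20, 30, 40])
        assert collinearity_check(f, ("vertical_angle", "lens_height")) == pytest.approx(1.0)
        f2 = self._frame_with([1, 2, 3, 4], [40, 30, 20, 10])
        assert collinearity_check(f2, ("vertical_angle", "lens_height")) == pytest.approx(-1.0)

    def test_tied_values_match_midrank_oracle(self):
        angle = [1.0, 2.0, 2.0, 3.0, 3.0, 3.0]
        height = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0]

        def midranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), float)
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        ra, rh = midranks(angle), midranks(height)
        expected = np.corrcoef(ra, rh)[0, 1]
        f = self._frame_with(angle, height)
        assert collinearity_check(f, ("vertical_angle", "lens_height")) == pytest.approx(
            expected, abs=1e-12)

    def test_constant_covariate_rejected(self):
        f = self._frame_with([1, 1, 1], [10, 20, 30])
        with pytest.raises(ValueError):
            collinearity_check(f, ("vertical_angle", "lens_height"))

    @pytest.mark.parametrize("re_, rt, rp, n, expected", [
        (1.0, 1.0, 1.0, 1, 1.0),
        (0.9, 0.8, 0.7, 0, 0.0),
        (0.5, 0.5, 1.0, 2, 0.4375),
    ])
    def test_combined_probability_closed_form(self, re_, rt, rp, n, expected):
        assert combined_detection_probability(re_, rt, rp, n) == pytest.approx(expected)

    def test_combined_probability_domain_errors(self):
        with pytest.raises(ValueError):
            combined_detection_probability(1.2, 0.5, 0.5, 1)
        with pytest.raises(ValueError):
            combined_detection_probability(0.5, 0.5, 0.5, -1)
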