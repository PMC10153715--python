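"""Input scaling, hierarchical-model sampling, and threshold derivation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import contextmod as cm
from contextmod import fit as fit_mod
from contextmod import observers


class TestScaleInputs:
    def test_zero_mean_unit_sd_per_task(self, population8, eye_design):
        trials = cm.run_eye_matching_session(population8[0], eye_design, 1)
        scaled = cm.scale_inputs(trials)
        for _, sub in scaled.frame.groupby("task"):
            assert sub["x"].mean() == pytest.approx(0.0, abs=1e-9)
            assert sub["x"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_design_weighted_range_within_three(self, population8, eye_design):
        """With the design's trial weights, scaled dissimilarity stays in
        the -3..3 band."""
        trials = cm.run_eye_matching_session(population8[0], eye_design, 1)
        scaled = cm.scale_inputs(trials)
        assert scaled.frame["x"].abs().max() <= 3.0

    def test_round_trip_inversion(self):
        trials = pd.DataFrame(dict(
            participant=0, task="Grating", context="Same",
            x_raw=[0.001, 0.01, 0.3, 1.0], response=[0, 0, 1, 1]))
        scaled = cm.scale_inputs(trials)
        scaler = scaled.scalers["Grating"]
        raw = np.array([0.002, 0.05, 0.7])
        assert np.allclose(scaler.inverse(scaler.transform(raw)), raw)

    def test_guess_indicator_constant_within_task(self, population8,
                                                  eye_design):
        trials = cm.run_eye_matching_session(population8[0], eye_design, 1)
        scaled = cm.scale_inputs(trials)
        assert (scaled.frame.groupby("task")["guess"].nunique() == 1).all()
        assert set(scaled.frame["guess"]) == {0}

    def test_rejects_nonpositive_contrast(self):
        trials = pd.DataFrame(dict(participant=0, task="Grating",
                                   context="Same", x_raw=[0.0, 0.1],
                                   response=[0, 1]))
        with pytest.raises(ValueError):
            cm.scale_inputs(trials)


class TestSamplerBookkeeping:
    def test_retained_draw_counts(self):
        assert fit_mod.SamplerConfig.paper_profile().retained_draws == 12000
        cfg = fit_mod.SamplerConfig(chains=3, iterations=500, warmup=200)
        assert cfg.retained_draws == 900

    def test_fit_retains_chains_times_kept(self, grating_fit):
        fitted, _ = grating_fit
        assert fitted.retained_draws == fitted.config.retained_draws
        assert fitted.beta.shape == (2, 400, 6)


class TestFitRecovery:
    def test_convergence_diagnostics(self, grating_fit):
        fitted, _ = grating_fit
        assert fitted.diagnostics["rhat_max"] < 1.05
        assert fitted.diagnostics["divergences"] == 0

    def test_fixed_effect_slope_within_two_sd(self, grating_fit, population8):
        """The population-level slope estimate brackets the generating mean
        slope for the reference (Isolated) cell."""
        fitted, scaled = grating_fit
        k = fitted.n_cells
        slope_draws = fitted.beta[:, :, k].reshape(-1)  # reference-cell slope
        # generating slope on the scaled axis: logit/decade * decades-per-x
        true_b1 = np.mean([obs.coef[("Grating", "Isolated")][1]
                           for obs in population8])
        true_scaled = true_b1 * scaled.scalers["Grating"].sd
        err = abs(slope_draws.mean() - true_scaled)
        assert err < 2 * slope_draws.std()

    def test_guess_rate_asymptote(self, grating_fit):
        """The fitted detection curve tends to 0.5, not 0, at eta -> -inf."""
        fitted, _ = grating_fit
        b0, b1 = cm.cell_coefficients(fitted, 0, "Grating", "Isolated")
        p_low = 0.5 + 0.5 * expit(b0 + b1 * (-30.0))
        assert np.allclose(p_low, 0.5, atol=1e-9)


class TestCellCoefficients:
    def test_reference_cell_is_global_plus_deviation(self, grating_fit):
        fitted, _ = grating_fit
        k = fitted.n_cells
        s = int(np.flatnonzero(fitted.participants == 0)[0])
        b0, b1 = cm.cell_coefficients(fitted, 0, "Grating", "Isolated")
        beta = fitted.beta.reshape(-1, 2 * k)
        sigma = np.exp(fitted.tau.reshape(-1, 2 * k))
        z = fitted.z_re.reshape(-1, fitted.participants.size, 2 * k)[:, s, :]
        assert np.allclose(b0, beta[:, 0] + sigma[:, 0] * z[:, 0], atol=1e-12)
        assert np.allclose(b1, beta[:, k] + sigma[:, k] * z[:, k], atol=1e-12)

    def test_unknown_cell_rejected(self, grating_fit):
        fitted, _ = grating_fit
        with pytest.raises(KeyError):
            cm.cell_coefficients(fitted, 999, "Grating", "Isolated")
        with pytest.raises(ValueError):
            cm.cell_coefficients(fitted, 0, "Grating", "Sideways")


def _guess_adjusted_mle(x, y):
    def nll(theta):
        p = np.clip(0.5 + 0.5 * expit(theta[0] + theta[1] * x), 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    res = minimize(nll, [0.0, 1.0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9})
    return res.x


class TestOracleEquivalence:
    def test_posterior_matches_mle_when_random_effects_vanish(self):
        """With random-effect SDs pinned near zero and identical
        participants, posterior-mean cell coefficients agree with a plain
        guess-adjusted maximum-likelihood logistic fit."""
        rng = np.random.default_rng(5)
        x_grid = np.linspace(-2.0, 2.0, 9)
        b0_true, b1_true = -0.8, 2.2
        rows = []
        x_all, y_all = [], []
        for cond in observers.CONDITIONS:
            x = np.repeat(x_grid, 90)
            p = 0.5 + 0.5 * expit(b0_true + b1_true * x)
            y = (rng.random(x.size) < p).astype(int)
            for participant in (0, 1):     # identical data for both
                for xi, yi in zip(x, y):
                    rows.append(dict(participant=participant, task="Grating",
                                     condition=cond, x=xi, y=yi, guess=1))
            if cond == "Isolated":
                x_all, y_all = x, y
        scaled = fit_mod.ScaledDataset(
            frame=pd.DataFrame(rows),
            scalers={"Grating": fit_mod.InputScaler(True, 0.0, 1.0)})
        cfg = fit_mod.SamplerConfig(chains=2, iterations=600, warmup=300,
                                    n_leapfrog=16, seed=3,
                                    prior_sd_mu=-6.0, prior_sd_sigma=0.01)
        fitted = cm.fit_model(scaled, cfg)
        mle = _guess_adjusted_mle(np.asarray(x_all), np.asarray(y_all))
        b0, b1 = cm.cell_coefficients(fitted, 0, "Grating", "Isolated")
        assert abs(b0.mean() - mle[0]) < 0.1
        assert abs(b1.mean() - mle[1]) < 0.1
        # shrinkage symmetry: identical data -> near-identical posteriors
        c0 = cm.cell_coefficients(fitted, 0, "Grating", "Different")
        c1 = cm.cell_coefficients(fitted, 1, "Grating", "Different")
        assert abs(c0[0].mean() - c1[0].mean()) < 0.05
        assert abs(c0[1].mean() - c1[1].mean()) < 0.05


class TestThresholds:
    def test_threshold_is_per_draw_ratio(self, grating_fit):
        fitted, _ = grating_fit
        table = cm.derive_thresholds(fitted)
        row = table[(table.participant == 0)
                    & (table.condition == "Same")].iloc[0]
        b0, b1 = cm.cell_coefficients(fitted, 0, "Grating", "Same")
        assert row["threshold"] == pytest.approx((-b0 / b1).mean(), rel=1e-12)
        assert row["hdi_lower"] <= row["threshold"] <= row["hdi_upper"]
        assert not row["unstable"]

    def test_back_transform_inverts_scaling(self, grating_fit):
        fitted, scaled = grating_fit
        table = cm.derive_thresholds(fitted)
        scaler = scaled.scalers["Grating"]
        assert np.allclose(table["threshold_native"],
                           scaler.inverse(table["threshold"]))

    def test_table_covers_all_cells(self, mixed_fit):
        fitted, _, pop = mixed_fit
        table = cm.derive_thresholds(fitted)
        assert len(table) == len(pop) * 9
        assert set(table["task"]) == set(observers.TASKS)


class TestConditionContrasts:
    def test_same_condition_difference_is_zero(self, grating_fit):
        fitted, _ = grating_fit
        c = cm.condition_contrasts(fitted, "Grating", "Same", "Same")
        assert np.allclose(c.posterior, 0.0)
        assert not c.excludes_zero

    def test_large_gap_excludes_zero(self, grating_fit):
        """Same-context detection thresholds sit well above Different-context
        ones in the generating population; the HDI must exclude zero."""
        fitted, _ = grating_fit
        c = cm.condition_contrasts(fitted, "Grating", "Same", "Different")
        assert c.excludes_zero
        assert c.mean > 0

    def test_hdi_brackets_mean(self, grating_fit):
        fitted, _ = grating_fit
        c = cm.condition_contrasts(fitted, "Grating", "Isolated", "Different")
        assert c.hdi_lower <= c.mean <= c.hdi_upper


class TestHdi:
    def test_matches_central_interval_for_symmetric_draws(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200_000)
        lo, hi = fit_mod.hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_skewed_draws_shorter_than_quantile_interval(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=100_000)
        lo, hi = fit_mod.hdi(x, 0.95)
        q = np.quantile(x, [0.025, 0.975])
        assert hi - lo < q[1] - q[0]
        assert lo == pytest.approx(0.0, abs=0.01)
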