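import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wqsmix._solver import reduce_problem
from wqsmix.simulate import EffectTruth, generate_cohort
from wqsmix.wqs import (
    AnalysisData,
    BootstrapResult,
    WQSConfig,
    aggregate_weights,
    compute_wqs_index,
    fit_weights_once,
    repeated_holdout,
    select_direction,
    train_weights,
    validate_model,
    wqs_significance,
)


def _profiled_objective(prob, w, n, lam, direction):
    u = prob.a @ w
    v = w @ prob.B @ w
    rss = prob.rss_a - (u * u / v if direction * u > 0 else 0.0)
    return 0.5 * n * np.log(rss) + lam * float(w @ w)


class TestComputeIndex:
    def test_hand_arithmetic(self):
        Q = pd.DataFrame([[0, 9], [5, 5], [9, 0]], columns=["a", "b"])
        S = compute_wqs_index(Q, [0.25, 0.75])
        assert np.allclose(S, [6.75, 5.0, 2.25])

    def test_one_hot_recovers_column(self, null_cohort):
        ranks = null_cohort.deciles.ranks
        S = compute_wqs_index(
            ranks[["As", "Cd", "Sb", "Hg", "Pb", "Ni"]], [0, 1, 0, 0, 0, 0]
        )
        assert np.array_equal(S, ranks["Cd"].to_numpy())

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_index_bounded_for_any_simplex_weights(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.integers(0, 10, size=(25, 6)).astype(float)
        w = rng.dirichlet(np.ones(6))
        S = compute_wqs_index(Q, w)
        assert S.min() >= 0 and S.max() <= 9

    def test_mismatch_and_bad_weights_rejected(self):
        Q = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            compute_wqs_index(Q, [0.5, 0.5])
        with pytest.raises(ValueError):
            compute_wqs_index(Q, [0.5, 0.4, 0.4])


class TestTrainWeights:
    def _noiseless_cd_problem(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        Q = rng.integers(0, 10, size=(n, 6)).astype(float)
        C = rng.standard_normal((n, 3))
        y = 50.0 - Q[:, 1] + C @ [1.0, 0.5, -0.2]  # pure Cd signal
        return Q, y, C

    def test_noiseless_one_hot_recovery(self):
        Q, y, C = self._noiseless_cd_problem()
        cfg = WQSConfig(n_boot=10, penalty=0.0, seed=0)
        rng = np.random.default_rng(1)
        boot = train_weights(Q, y, C, cfg, direction=-1, rng=rng)
        assert boot.converged.all()
        assert (boot.weights[:, 1] >= 0.95).all()
        assert np.allclose(boot.beta1, -1.0, atol=0.05)

    def test_huge_penalty_drives_weights_uniform(self):
        Q, y, C = self._noiseless_cd_problem()
        cfg = WQSConfig(n_boot=5, penalty=1e7, seed=0)
        boot = train_weights(Q, y, C, cfg, direction=-1, rng=np.random.default_rng(2))
        assert np.abs(boot.weights - 1.0 / 6).max() < 1e-3

    def test_direction_constraint_respected(self):
        rng = np.random.default_rng(3)
        Q = rng.integers(0, 10, size=(200, 6)).astype(float)
        C = rng.standard_normal((200, 2))
        y = rng.normal(size=200)  # null: many bootstraps hit the constraint
        cfg = WQSConfig(n_boot=30, seed=0)
        boot = train_weights(Q, y, C, cfg, direction=-1, rng=rng)
        assert (boot.beta1[boot.converged] <= 0).all()
        sums = boot.weights[boot.converged].sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-8

    def test_matches_profile_grid_search_two_metals(self):
        """Oracle: 1001-point profile-least-squares sweep of the 1-simplex."""
        rng = np.random.default_rng(4)
        n = 150
        Q = rng.integers(0, 10, size=(n, 2)).astype(float)
        C = rng.standard_normal((n, 2))
        y = -(0.6 * Q[:, 0] + 0.4 * Q[:, 1]) + C @ [0.5, 1.0] + rng.normal(0, 1, n)
        w, b1, _ = fit_weights_once(Q, y, C, penalty=0.0, direction=-1)
        prob = reduce_problem(Q, y, np.column_stack([np.ones(n), C]))
        grid = np.linspace(0, 1, 1001)
        objs = [
            _profiled_objective(prob, np.array([g, 1 - g]), n, 0.0, -1) for g in grid
        ]
        gbest = grid[int(np.argmin(objs))]
        mine = _profiled_objective(prob, w, n, 0.0, -1)
        assert mine <= min(objs) + 1e-6
        assert abs(w[0] - gbest) <= 0.02

    def test_matches_simplex_grid_search_three_metals(self):
        """Coarser 2-simplex grid oracle for a 3-metal problem."""
        rng = np.random.default_rng(5)
        n = 200
        Q = rng.integers(0, 10, size=(n, 3)).astype(float)
        C = rng.standard_normal((n, 2))
        y = -(0.5 * Q[:, 0] + 0.3 * Q[:, 1] + 0.2 * Q[:, 2]) + C @ [0.3, -0.4]
        y = y + rng.normal(0, 1, n)
        w, _, _ = fit_weights_once(Q, y, C, penalty=0.0, direction=-1)
        prob = reduce_problem(Q, y, np.column_stack([np.ones(n), C]))
        best = (np.inf, None)
        for i in np.arange(0, 1.0001, 0.01):
            for j in np.arange(0, 1.0001 - i, 0.01):
                wv = np.array([i, j, 1 - i - j])
                f = _profiled_objective(prob, wv, n, 0.0, -1)
                if f < best[0]:
                    best = (f, wv)
        assert _profiled_objective(prob, w, n, 0.0, -1) <= best[0] + 1e-6
        assert np.abs(w - best[1]).max() <= 0.02

    def test_unresolved_direction_rejected(self):
        Q, y, C = self._noiseless_cd_problem()
        with pytest.raises(ValueError):
            train_weights(Q, y, C, WQSConfig(), direction=None, rng=np.random.default_rng(0))


class TestAggregateWeights:
    def _boot(self, W, t):
        W = np.asarray(W, float)
        return BootstrapResult(
            weights=W,
            beta1=-np.ones(len(W)),
            tstat=np.asarray(t, float),
            converged=np.ones(len(W), bool),
        )

    def test_identical_rows_are_fixed_point(self):
        row = np.array([0.2, 0.3, 0.5])
        out = aggregate_weights(self._boot([row, row, row], [1, 2, 3]))
        assert np.allclose(out, row)

    def test_squared_t_mixing_proportions(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = aggregate_weights(self._boot(W, [1.0, 2.0]), "squared_t")
        assert np.allclose(out, [0.2, 0.8])

    def test_uniform_signal_is_plain_mean(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = aggregate_weights(self._boot(W, [1.0, 5.0]), "uniform")
        assert np.allclose(out, [0.5, 0.5])

    def test_zero_signal_falls_back_to_uniform(self, caplog):
        W = np.array([[0.8, 0.2], [0.2, 0.8]])
        out = aggregate_weights(self._boot(W, [0.0, 0.0]), "squared_t")
        assert np.allclose(out, [0.5, 0.5])

    def test_no_converged_rows_rejected(self):
        b = self._boot([[0.5, 0.5]], [1.0])
        b.converged[:] = False
        with pytest.raises(ValueError):
            aggregate_weights(b)


class TestValidateModel:
    def test_noiseless_recovery_is_exact(self):
        truth = EffectTruth(
            weights_toxic=(0.1, 0.4, 0.3, 0.1, 0.05, 0.05),
            beta1_tox=-1.2,
            beta1_ess=0.4,
            beta2_ess=-0.05,
            covariate_coefs=(0.3, -0.1, 1.0, 0.0, 0.2, -0.5, 0.1),
            intercept=95.0,
            resid_sd=0.0,
        )
        cohort = generate_cohort(n=300, truth=truth, seed=6)
        weights = {
            "essential": np.asarray(truth.weights_essential),
            "toxic": np.asarray(truth.weights_toxic),
        }
        est = validate_model(
            cohort.deciles.ranks,
            cohort.outcomes["FSIQ"].to_numpy(),
            cohort.covariates,
            weights,
            quadratic=("essential",),
        )
        assert est.params["wqs_toxic"] == pytest.approx(-1.2, abs=1e-8)
        assert est.params["wqs_essential"] == pytest.approx(0.4, abs=1e-8)
        assert est.params["wqs_essential_sq"] == pytest.approx(-0.05, abs=1e-8)
        assert est.params["beta0"] == pytest.approx(95.0, abs=1e-6)

    def test_quadratic_flag_improves_aic_on_quadratic_data(self):
        truth = EffectTruth(beta1_ess=9.0, beta2_ess=-1.0, resid_sd=5.0)
        cohort = generate_cohort(n=400, truth=truth, seed=7)
        weights = {
            "essential": np.asarray(truth.weights_essential),
            "toxic": np.asarray(truth.weights_toxic),
        }
        args = (
            cohort.deciles.ranks,
            cohort.outcomes["FSIQ"].to_numpy(),
            cohort.covariates,
            weights,
        )
        aic_quad = validate_model(*args, quadratic=("essential",)).aic
        aic_lin = validate_model(*args, quadratic=()).aic
        assert aic_quad < aic_lin

    def test_rank_deficiency_names_column(self, null_cohort):
        cov = null_cohort.covariates.copy()
        cov["bmi"] = 2 * cov["age"]  # exact collinearity
        weights = {
            "essential": np.full(8, 1 / 8),
            "toxic": np.full(6, 1 / 6),
        }
        with pytest.raises(ValueError, match="rank deficient"):
            validate_model(
                null_cohort.deciles.ranks,
                null_cohort.outcomes["FSIQ"].to_numpy(),
                cov,
                weights,
            )

    def test_too_small_validation_set_rejected(self, null_cohort):
        weights = {"essential": np.full(8, 1 / 8), "toxic": np.full(6, 1 / 6)}
        with pytest.raises(ValueError, match="validation"):
            validate_model(
                null_cohort.deciles.ranks.iloc[:10],
                null_cohort.outcomes["FSIQ"].to_numpy()[:10],
                null_cohort.covariates.iloc[:10],
                weights,
            )


class TestRepeatedHoldout:
    def _fit(self, cohort, seed=0, **kw):
        cfg = WQSConfig(
            n_boot=10,
            n_holdout=10,
            direction_essential="negative",
            direction_toxic="negative",
            seed=seed,
            **kw,
        )
        return repeated_holdout(AnalysisData.from_cohort(cohort), "FSIQ", cfg)

    def test_same_seed_gives_identical_fit(self, null_cohort):
        a = self._fit(null_cohort, seed=5)
        b = self._fit(null_cohort, seed=5)
        pd.testing.assert_frame_equal(a.terms, b.terms)
        for k in a.final_weights:
            pd.testing.assert_series_equal(a.final_weights[k], b.final_weights[k])
        c = self._fit(null_cohort, seed=6)
        assert not a.terms.equals(c.terms)

    def test_simplex_and_interval_invariants(self, null_cohort):
        fit = self._fit(null_cohort)
        for w in fit.final_weights.values():
            assert w.sum() == pytest.approx(1.0, abs=1e-8)
            assert (w >= 0).all()
        t = fit.terms
        assert (t["lower"] <= t["estimate"] + 1e-12).all()
        assert (t["estimate"] <= t["upper"] + 1e-12).all()

    def test_strong_toxic_signal_recovered(self, toxic_signal_truth):
        cohort = generate_cohort(n=500, truth=toxic_signal_truth, seed=8)
        cfg = WQSConfig(
            n_boot=20,
            n_holdout=20,
            direction_essential="negative",
            direction_toxic="negative",
            seed=0,
        )
        fit = repeated_holdout(AnalysisData.from_cohort(cohort), "FSIQ", cfg)
        assert fit.terms.loc["wqs_toxic", "significant"]
        top2 = set(fit.final_weights["toxic"].nlargest(2).index)
        assert top2 == {"Cd", "Sb"}

    def test_validation_split_sizes(self, null_cohort):
        fit = self._fit(null_cohort)
        n_train = int(round(0.6 * null_cohort.n))
        assert n_train == 121 and null_cohort.n - n_train == 80
        assert np.isfinite(fit.terms["estimate"]).all()

    def test_excess_holdout_failures_abort(self, null_cohort):
        cfg = WQSConfig(
            n_boot=5,
            n_holdout=5,
            direction_essential="negative",
            direction_toxic="negative",
            min_validation_n=100,  # validation has 80 rows: every holdout fails
            seed=0,
        )
        with pytest.raises(RuntimeError, match="holdouts failed"):
            repeated_holdout(AnalysisData.from_cohort(null_cohort), "FSIQ", cfg)

    def test_unresolved_auto_direction_rejected(self, null_cohort):
        cfg = WQSConfig(n_boot=5, n_holdout=5, seed=0)  # both auto_aic
        with pytest.raises(ValueError, match="auto_aic"):
            repeated_holdout(AnalysisData.from_cohort(null_cohort), "FSIQ", cfg)


class TestSelectDirection:
    def test_four_combinations_evaluated(self, null_cohort):
        cfg = WQSConfig(seed=0, direction_n_holdout=3, direction_n_boot=3)
        dirs, table = select_direction(
            AnalysisData.from_cohort(null_cohort), "FSIQ", cfg
        )
        assert len(table) == 4
        assert set(dirs) == {"essential", "toxic"}
        assert dirs["essential"] in (-1, 1) and dirs["toxic"] in (-1, 1)

    def test_strong_negative_signal_selects_negative(self, toxic_signal_truth):
        cohort = generate_cohort(n=500, truth=toxic_signal_truth, seed=9)
        cfg = WQSConfig(seed=0, direction_n_holdout=10, direction_n_boot=10)
        dirs, _ = select_direction(AnalysisData.from_cohort(cohort), "FSIQ", cfg)
        assert dirs["toxic"] == -1

    def test_fixed_directions_skip_the_pre_pass(self, null_cohort):
        cfg = WQSConfig(
            seed=0, direction_essential="positive", direction_toxic="negative"
        )
        dirs, table = select_direction(AnalysisData.from_cohort(null_cohort), "FSIQ", cfg)
        assert dirs == {"essential": 1, "toxic": -1}
        assert table.empty


class TestSignificance:
    def _fit_with_holdouts(self, values):
        est = pd.DataFrame({i: {"wqs_toxic": v} for i, v in enumerate(values)})
        from wqsmix.wqs import WQSFit

        return WQSFit(
            terms=pd.DataFrame(),
            final_weights={},
            weights_iqr={},
            directions={},
            holdout_estimates=est,
            n_failed=0,
            aic_mean=0.0,
        )

    def test_interval_excluding_zero_is_significant(self):
        fit = self._fit_with_holdouts(np.linspace(-0.38, -0.03, 41))
        assert wqs_significance(fit)["wqs_toxic"]

    def test_interval_spanning_zero_is_not(self):
        fit = self._fit_with_holdouts(np.linspace(-1.18, 0.42, 41))
        assert not wqs_significance(fit)["wqs_toxic"]

    def test_degenerate_zero_interval_is_not(self):
        fit = self._fit_with_holdouts(np.zeros(20))
        assert not wqs_significance(fit)["wqs_toxic"]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"split_fraction": 1.2},
            {"n_boot": 0},
            {"n_holdout": 0},
            {"penalty": -1.0},
            {"signal": "magic"},
            {"direction_toxic": "sideways"},
        ],
    )
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            WQSConfig(**kw)
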