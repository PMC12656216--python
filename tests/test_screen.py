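import numpy as np
import pytest

from wqsmix.screen import (
    _build_smooth_basis,
    _penalized_fit,
    _reml_score,
    fit_gam_smooth,
    fit_rcs,
    run_screen,
)
from wqsmix.simulate import EffectTruth, generate_cohort


def _sim(n, kind, seed, noise=None):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 10, n).astype(float)
    C = rng.standard_normal((n, 2))
    if kind == "linear":
        y = 2 * x + C @ [0.5, -0.3] + rng.normal(0, 0.1 if noise is None else noise, n)
    elif kind == "quadratic":
        y = -((x - 4.5) ** 2) + rng.normal(0, 1.0 if noise is None else noise, n)
    else:
        y = rng.normal(0, 1.0, n) + C @ [0.3, 0.2]
    return x, y, C


class TestGamSmooth:
    def test_linear_relationship_gives_unit_edf(self):
        x, y, C = _sim(1000, "linear", 0)
        r = fit_gam_smooth(x, y, C)
        assert 1.0 <= r.edf <= 1.3
        assert r.converged

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_strong_curvature_detected(self, seed):
        x, y, C = _sim(500, "quadratic", seed)
        r = fit_gam_smooth(x, y, C)
        assert r.edf > 1.5 and r.p_value < 0.05

    def test_reml_matches_dense_mixed_model_oracle(self):
        """The profiled REML score equals the brute-force restricted
        likelihood computed from the marginal covariance I + ZZ'/lam."""
        x, y, C = _sim(150, "quadratic", 4)
        basis = _build_smooth_basis(x, C)
        Cmat = np.column_stack([basis.X_fixed, basis.Z])
        p, q = basis.n_fixed, basis.n_pen
        Xf, Z = basis.X_fixed, basis.Z
        n = len(y)
        for lam in (0.1, 1.0, 50.0):
            V = np.eye(n) + Z @ Z.T / lam
            Vi = np.linalg.inv(V)
            XtVX = Xf.T @ Vi @ Xf
            P = Vi - Vi @ Xf @ np.linalg.inv(XtVX) @ Xf.T @ Vi
            ypy = y @ P @ y
            s2 = ypy / (n - p)
            brute = (
                (n - p) * np.log(2 * np.pi * s2)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtVX)[1]
                + ypy / s2
            )
            assert _reml_score(Cmat, y, p, q, lam) == pytest.approx(brute, abs=1e-6)

    def test_infinite_penalty_equals_ordinary_linear_fit(self):
        x, y, C = _sim(400, "quadratic", 5)
        r = fit_gam_smooth(x, y, C, lam=1e12)
        X = np.column_stack([np.ones(len(y)), C, x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(r.fitted - X @ beta).max() < 1e-6
        assert r.edf == pytest.approx(1.0, abs=1e-6)

    def test_edf_monotone_in_smoothing_parameter(self):
        x, y, C = _sim(300, "quadratic", 6)
        edfs = [fit_gam_smooth(x, y, C, lam=l).edf for l in 10.0 ** np.arange(-4, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))
        assert edfs[0] <= 9.0 + 1e-9 and edfs[-1] >= 1.0 - 1e-9

    def test_null_pvalue_calibration(self):
        """With no exposure effect the smooth test rejects near its
        nominal 5% level (1000 seeded replicates)."""
        rej = 0
        for s in range(1000):
            x, y, C = _sim(201, "null", 100_000 + s)
            rej += fit_gam_smooth(x, y, C).p_value < 0.05
        assert 0.02 <= rej / 1000 <= 0.09

    def test_small_sample_rejected(self):
        x, y, C = _sim(40, "linear", 7)
        with pytest.raises(ValueError):
            fit_gam_smooth(x, y, C)


class TestRcs:
    def test_boundary_linearity(self):
        """The fitted curve is linear beyond the boundary knots: second
        differences on the prediction grid vanish there."""
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2, 400)  # continuous so boundary knots are interior
        C = rng.standard_normal((400, 2))
        y = np.sin(x) + rng.normal(0, 0.3, 400)
        r = fit_rcs(x, y, C, n_knots=4)
        g = r.curve
        for region in (g[g.exposure < r.knots[0]], g[g.exposure > r.knots[-1]]):
            if len(region) > 2:
                assert np.abs(np.diff(region["fit"].to_numpy(), 2)).max() < 1e-8

    def test_detects_curvature_and_respects_null(self):
        hits_quad = sum(
            fit_rcs(*_sim(500, "quadratic", 200 + s)).p_nonlinear < 0.05
            for s in range(20)
        )
        hits_lin = sum(
            fit_rcs(*_sim(500, "linear", 300 + s, noise=1.0)).p_nonlinear > 0.05
            for s in range(20)
        )
        assert hits_quad >= 19
        assert hits_lin >= 18

    def test_knot_count_options_and_validation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        C = rng.standard_normal((300, 1))
        for k in (3, 4, 5):
            r = fit_rcs(x, y, C, n_knots=k)
            assert len(r.knots) == k
            assert len(r.coefficients) == k - 1
        with pytest.raises(ValueError):
            fit_rcs(x, y, C, n_knots=6)

    def test_heavy_ties_degenerate_knots_rejected(self):
        x = np.r_[np.zeros(290), [1.0] * 10]
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="knots"):
            fit_rcs(x, rng.normal(size=300), rng.standard_normal((300, 1)))


class TestRunScreen:
    def test_grid_cardinality_and_structure(self, null_cohort):
        table = run_screen(null_cohort)
        assert len(table.records) == 14 * 11
        assert set(table.records.columns) >= {"metal", "outcome", "edf", "p_value", "flag"}

    def test_null_cohort_has_no_systematic_flags(self, null_cohort):
        table = run_screen(null_cohort)
        assert table.records["flag"].mean() < 0.15

    def test_quadratic_config_is_rederivable(self, null_cohort):
        table = run_screen(null_cohort)
        cfg = table.quadratic_config()
        from wqsmix.metals import ESSENTIAL_METALS

        flagged_ess = table.records[
            table.records["flag"] & table.records["metal"].isin(ESSENTIAL_METALS)
        ]
        for out_name, indices in cfg.items():
            expect = ("essential",) if out_name in set(flagged_ess["outcome"]) else ()
            assert indices == expect

    def test_quadratic_essential_signal_flagged(self):
        """An inverted-U essential-index effect concentrated on Mn is
        picked up by the screen and switches on the quadratic term."""
        truth = EffectTruth(
            weights_essential=(0.05, 0.05, 0.6, 0.1, 0.05, 0.05, 0.05, 0.05),
            beta1_ess=9.0,
            beta2_ess=-1.0,
            resid_sd=3.0,
        )
        hits = 0
        for seed in (21, 22, 23):
            cohort = generate_cohort(n=500, truth=truth, seed=seed)
            table = run_screen(cohort, outcomes=["FSIQ"])
            flagged = table.records[
                table.records["flag"] & (table.records["outcome"] == "FSIQ")
            ]
            if any(m in ("Mn",) for m in flagged["metal"]):
                hits += 1
                assert "FSIQ" in table.quadratic_outcomes
        assert hits >= 2

    def test_flagged_pairs_get_rcs_confirmation(self):
        truth = EffectTruth(
            weights_essential=(0.05, 0.05, 0.6, 0.1, 0.05, 0.05, 0.05, 0.05),
            beta1_ess=9.0,
            beta2_ess=-1.0,
            resid_sd=3.0,
        )
        cohort = generate_cohort(n=500, truth=truth, seed=24)
        table = run_screen(cohort, outcomes=["FSIQ"])
        flagged = table.records[table.records["flag"]]
        if len(flagged):
            assert flagged["p_nonlinear_rcs"].notna().any()
            assert len(table.rcs_results) > 0
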