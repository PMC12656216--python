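"""Non-linearity screen: penalized-spline additive fits plus RCS confirmation.

For each (metal, outcome) pair the screen fits

    outcome ~ smooth(exposure deciles) + linear covariates

where the smooth is a rank-10 cubic B-spline penalized by its integrated
squared second derivative, with the smoothing parameter chosen by
restricted maximum likelihood (REML).  The effective degrees of freedom
(edf) of the smooth and an approximate Wald test of the smooth against
the zero function decide a "curvilinear" flag; flagged pairs are
re-examined with a restricted cubic spline (RCS) whose non-linear basis
coefficients admit an exact joint F-test.  The flags feed the quadratic
term configuration of the weighted-index regression stage.

The penalty null space is exactly the affine functions of the exposure,
so an infinite penalty reproduces the ordinary linear fit and edf ranges
from 1 (linear) to basis dimension - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

from .metals import CANONICAL_METALS, ESSENTIAL_METALS
from .simulate import SyntheticCohort
from .study import COVARIATE_COLUMNS, OUTCOME_COLUMNS

__all__ = [
    "SmoothResult",
    "RCSResult",
    "ScreenTable",
    "fit_gam_smooth",
    "fit_rcs",
    "run_screen",
]

_LOG_LAMBDA_RANGE = (-10.0, 14.0)


@dataclass
class SmoothResult:
    """One penalized-smooth fit: complexity and significance of the smooth."""

    edf: float
    p_value: float
    converged: bool
    metal: str | None = None
    outcome: str | None = None
    lam: float = np.nan  # selected smoothing parameter
    edf_total: float = np.nan
    fitted: np.ndarray | None = field(default=None, repr=False)
    smooth_curve: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class RCSResult:
    """Restricted-cubic-spline confirmation fit."""

    knots: np.ndarray
    coefficients: np.ndarray  # linear + (k-2) non-linear terms
    p_nonlinear: float
    curve: pd.DataFrame  # grid, fit, lower, upper
    metal: str | None = None
    outcome: str | None = None


# ---------------------------------------------------------------------------
# penalized B-spline smooth with REML smoothing-parameter selection
# ---------------------------------------------------------------------------


def _bspline_knots(x: np.ndarray, k: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    interior = np.linspace(lo, hi, k - 2)[1:-1]
    return np.r_[[lo] * 4, interior, [hi] * 4]


def _bspline_design(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x = np.clip(x, t[3], t[-4])
    return BSpline.design_matrix(x, t, 3).toarray()


def _second_derivative_penalty(t: np.ndarray, k: int) -> np.ndarray:
    """Exact integral of products of second derivatives of the basis.

    B'' of a cubic B-spline is piecewise linear, so the products are
    piecewise quadratic and 2-point Gauss-Legendre per knot span is exact.
    """
    spans = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    S = np.zeros((k, k))
    eye = np.eye(k)
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        xs = (a + b) / 2.0 + half * gauss
        D2 = np.column_stack(
            [BSpline(t, eye[j], 3).derivative(2)(xs) for j in range(k)]
        )
        S += half * (D2.T @ D2)  # unit Gauss weights at 2 points
    return S


def _null_space(v: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of a single row vector."""
    q, _ = np.linalg.qr(np.column_stack([v, np.eye(len(v))]))
    return q[:, 1:]


@dataclass
class _SmoothBasis:
    X_fixed: np.ndarray  # [1, covariates, penalty-null smooth column]
    Z: np.ndarray  # penalized columns, penalty = identity
    n_fixed: int
    n_pen: int
    smooth_cols: np.ndarray  # indices of smooth columns in [X_fixed, Z]
    predict_fixed_col: np.ndarray  # per-grid values of the null column
    predict_Z: np.ndarray
    grid: np.ndarray


def _build_smooth_basis(
    x: np.ndarray, covariates: np.ndarray, basis_dim: int = 10, n_grid: int = 100
) -> _SmoothBasis:
    t = _bspline_knots(x, basis_dim)
    B = _bspline_design(x, t)
    S0 = _second_derivative_penalty(t, basis_dim)
    # centre the smooth (sum-to-zero over the sample) to free the intercept
    con = B.mean(axis=0)
    Zc = _null_space(con)
    Bc = B @ Zc
    Sc = (Zc.T @ S0 @ Zc + (Zc.T @ S0 @ Zc).T) / 2.0
    w, U = np.linalg.eigh(Sc)
    # eigenvalues sorted ascending; exactly one (the centred affine
    # function of x) is numerically zero
    null_mask = w < w[-1] * 1e-10
    U0, Up = U[:, null_mask], U[:, ~null_mask]
    scale = 1.0 / np.sqrt(w[~null_mask])
    Z = Bc @ (Up * scale)
    x_null = Bc @ U0  # exactly proportional to centred x
    n = len(x)
    X_fixed = np.column_stack([np.ones(n), covariates, x_null])
    p = X_fixed.shape[1]
    grid = np.linspace(x.min(), x.max(), n_grid)
    Bg = _bspline_design(grid, t)
    Bgz = Bg @ Zc
    return _SmoothBasis(
        X_fixed=X_fixed,
        Z=Z,
        n_fixed=p,
        n_pen=Z.shape[1],
        smooth_cols=np.r_[p - 1, p + np.arange(Z.shape[1])],
        predict_fixed_col=(Bgz @ U0).ravel(),
        predict_Z=Bgz @ (Up * scale),
        grid=grid,
    )


def _penalized_fit(C: np.ndarray, y: np.ndarray, p: int, q: int, lam: float):
    """Solve the penalized normal equations; return coefs and key traces."""
    G = C.T @ C
    M = G.copy()
    M[p:, p:] += lam * np.eye(q)
    Minv = np.linalg.inv(M)
    theta = Minv @ (C.T @ y)
    resid = y - C @ theta
    dev = float(resid @ resid + lam * (theta[p:] @ theta[p:]))
    F = Minv @ G
    return theta, dev, F, Minv, M


def _reml_score(C, y, p, q, lam: float) -> float:
    n = len(y)
    _, dev, _, _, M = _penalized_fit(C, y, p, q, lam)
    sigma2 = dev / (n - p)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:  # pragma: no cover - M is PD for lam > 0
        return np.inf
    return (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet - q * np.log(lam)


def fit_gam_smooth(
    exposure,
    outcome,
    covariates,
    basis_dim: int = 10,
    lam: float | None = None,
    metal: str | None = None,
    outcome_name: str | None = None,
) -> SmoothResult:
    """Fit outcome ~ smooth(exposure) + covariates with REML selection.

    ``lam`` fixes the smoothing parameter instead of selecting it by
    REML (used by diagnostics and tests).  ``edf`` counts the smooth's
    share of model complexity (1 = linear); ``p_value`` is the
    approximate Wald test of the whole smooth against the zero function
    at pseudo-inverse rank round(edf).
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    Cv = np.asarray(covariates, dtype=float)
    if Cv.ndim == 1:
        Cv = Cv[:, None]
    n = len(y)
    if n < 50:
        raise ValueError("need at least 50 subjects for the smooth screen")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Cv])) < Cv.shape[1] + 1:
        raise ValueError("covariate matrix is rank deficient")
    basis = _build_smooth_basis(x, Cv, basis_dim)
    C = np.column_stack([basis.X_fixed, basis.Z])
    p, q = basis.n_fixed, basis.n_pen

    converged = True
    if lam is None:
        res = minimize_scalar(
            lambda ll: _reml_score(C, y, p, q, np.exp(ll)),
            bounds=_LOG_LAMBDA_RANGE,
            method="bounded",
            options={"xatol": 1e-6},
        )
        converged = bool(res.success)
        lam = float(np.exp(res.x))

    theta, dev, F, Minv, _ = _penalized_fit(C, y, p, q, lam)
    edf_all = np.diag(F)
    edf_smooth = float(edf_all[basis.smooth_cols].sum())
    edf_total = float(edf_all.sum())
    sigma2 = dev / (n - p)

    # Wald test of the smooth term against the zero function, in fitted-
    # value space: f_hat' pinv_r(V_f) f_hat with V_f the Bayesian
    # covariance of the fitted smooth and pseudo-inverse rank ~ edf.
    sc = basis.smooth_cols
    theta_s = theta[sc]
    V_s = sigma2 * Minv[np.ix_(sc, sc)]
    Xs = C[:, sc]
    f_hat = Xs @ theta_s
    wv, Uv = np.linalg.eigh(V_s)
    L = Uv * np.sqrt(np.clip(wv, 0.0, None))
    Usv, sv, _ = np.linalg.svd(Xs @ L, full_matrices=False)
    r = int(min(len(sc), max(1, round(edf_smooth))))
    keep = sv[:r] ** 2
    proj = Usv[:, :r].T @ f_hat
    stat = float(np.sum(proj[keep > 0] ** 2 / keep[keep > 0]))
    df2 = max(n - edf_total, 1.0)
    p_value = float(stats.f.sf(stat / r, r, df2))

    curve = pd.DataFrame(
        {
            "exposure": basis.grid,
            "smooth": basis.predict_fixed_col * theta[p - 1]
            + basis.predict_Z @ theta[p:],
        }
    )
    fitted = C @ theta
    return SmoothResult(
        edf=edf_smooth,
        p_value=p_value,
        converged=converged,
        metal=metal,
        outcome=outcome_name,
        lam=lam,
        edf_total=edf_total,
        fitted=fitted,
        smooth_curve=curve,
    )


# ---------------------------------------------------------------------------
# restricted cubic splines (Harrell basis)
# ---------------------------------------------------------------------------

_RCS_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell's restricted cubic spline basis: linear + k-2 terms.

    The non-linear terms are combinations of truncated cubes chosen so
    the spline is linear beyond the boundary knots; the usual
    (t_k - t_1)^2 normalization keeps them on the scale of x.
    """
    t = knots
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def tp(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            tp(x - t[j])
            - tp(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + tp(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def fit_rcs(
    exposure,
    outcome,
    covariates,
    n_knots: int = 4,
    n_grid: int = 100,
    metal: str | None = None,
    outcome_name: str | None = None,
) -> RCSResult:
    """Restricted-cubic-spline fit with a joint test of non-linearity.

    Knots sit at the conventional quantiles for 3-5 knots; coincident
    knots (heavy ties) are deduplicated and fewer than 3 surviving knots
    rejects the fit as degenerate.  ``p_nonlinear`` is the joint F-test
    of the k-2 non-linear coefficients.
    """
    if n_knots not in _RCS_QUANTILES:
        raise ValueError("n_knots must be 3, 4 or 5")
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    Cv = np.asarray(covariates, dtype=float)
    if Cv.ndim == 1:
        Cv = Cv[:, None]
    knots = np.unique(np.quantile(x, _RCS_QUANTILES[n_knots]))
    if len(knots) < 3:
        raise ValueError(
            f"only {len(knots)} distinct knots available; exposure too heavily tied"
        )
    S = _rcs_basis(x, knots)
    n = len(y)
    X = np.column_stack([np.ones(n), Cv, S])
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    k_nl = len(knots) - 2
    R = np.zeros((k_nl, X.shape[1]))
    for i in range(k_nl):
        R[i, 1 + Cv.shape[1] + 1 + i] = 1.0
    p_nonlinear = float(fit.f_test(R).pvalue)

    grid = np.linspace(x.min(), x.max(), n_grid)
    Sg = _rcs_basis(grid, knots)
    Xg = np.column_stack([np.ones(n_grid), np.tile(Cv.mean(axis=0), (n_grid, 1)), Sg])
    pred = Xg @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.cov_params(), Xg))
    z = stats.norm.ppf(0.975)
    curve = pd.DataFrame(
        {"exposure": grid, "fit": pred, "lower": pred - z * se, "upper": pred + z * se}
    )
    coefs = fit.params[1 + Cv.shape[1]:]
    return RCSResult(
        knots=knots,
        coefficients=np.asarray(coefs),
        p_nonlinear=p_nonlinear,
        curve=curve,
        metal=metal,
        outcome=outcome_name,
    )


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenTable:
    """All smooth-term results plus the derived quadratic configuration.

    ``records`` has one row per metal x outcome with the smooth edf and
    p-value, the curvilinear flag, and (for flagged pairs) the RCS
    confirmation p-value.  ``quadratic_outcomes`` lists the outcomes for
    which the essential index receives a quadratic term downstream: those
    with at least one flagged essential metal.
    """

    records: pd.DataFrame
    edf_threshold: float
    alpha: float
    rcs_results: dict = field(default_factory=dict, repr=False)

    @property
    def quadratic_outcomes(self) -> tuple[str, ...]:
        flagged = self.records[
            self.records["flag"] & self.records["metal"].isin(ESSENTIAL_METALS)
        ]
        ordered = [o for o in self.records["outcome"].unique() if o in set(flagged["outcome"])]
        return tuple(ordered)

    def quadratic_config(self) -> dict[str, tuple[str, ...]]:
        """Map outcome -> indices that receive a quadratic term."""
        quad = set(self.quadratic_outcomes)
        return {
            o: (("essential",) if o in quad else ())
            for o in self.records["outcome"].unique()
        }


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def run_screen(
    cohort: SyntheticCohort | dict,
    outcomes: list[str] | None = None,
    edf_threshold: float = 1.5,
    alpha: float = 0.05,
    n_knots: int = 4,
    bh_adjust: bool = False,
    use_raw_exposures: bool = False,
) -> ScreenTable:
    """Screen every metal x outcome pair for non-linearity.

    Exposures enter as decile ranks by default (all modelling downstream
    is on the decile scale); ``use_raw_exposures`` switches to the
    concentration scale.  A failed fit leaves a recorded gap (NaN edf and
    p, converged False) rather than aborting the screen.  With
    ``bh_adjust`` the flag uses Benjamini-Hochberg adjusted p-values
    across all pairs (off by default; the primary analysis applies no
    multiplicity correction).
    """
    outcomes = list(outcomes) if outcomes is not None else list(OUTCOME_COLUMNS)
    covars = cohort.covariates.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    rows = []
    rcs_results: dict[tuple[str, str], RCSResult] = {}
    for out_name in outcomes:
        y = cohort.outcomes[out_name].to_numpy(dtype=float)
        for metal in CANONICAL_METALS:
            if use_raw_exposures:
                x = cohort.exposures[metal].to_numpy(dtype=float)
            else:
                x = cohort.deciles.ranks[metal].to_numpy(dtype=float)
            try:
                sr = fit_gam_smooth(
                    x, y, covars, metal=metal, outcome_name=out_name
                )
                rows.append((metal, out_name, sr.edf, sr.p_value, sr.converged))
            except Exception:
                rows.append((metal, out_name, np.nan, np.nan, False))
    records = pd.DataFrame(
        rows, columns=["metal", "outcome", "edf", "p_value", "converged"]
    )
    pcol = records["p_value"].to_numpy(dtype=float)
    if bh_adjust:
        ok = np.isfinite(pcol)
        padj = pcol.copy()
        padj[ok] = _bh_adjust(pcol[ok])
        records["p_adjusted"] = padj
        pcol = padj
    records["flag"] = (
        (records["edf"] >= edf_threshold) & (pcol < alpha) & records["converged"]
    )
    records["p_nonlinear_rcs"] = np.nan
    for i, row in records[records["flag"]].iterrows():
        x = (
            cohort.exposures[row["metal"]]
            if use_raw_exposures
            else cohort.deciles.ranks[row["metal"]]
        ).to_numpy(dtype=float)
        y = cohort.outcomes[row["outcome"]].to_numpy(dtype=float)
        try:
            rr = fit_rcs(
                x, y, covars, n_knots=n_knots,
                metal=row["metal"], outcome_name=row["outcome"],
            )
            rcs_results[(row["metal"], row["outcome"])] = rr
            records.loc[i, "p_nonlinear_rcs"] = rr.p_nonlinear
        except ValueError:
            pass  # degenerate knots: gap stays NaN
    return ScreenTable(
        records=records,
        edf_threshold=edf_threshold,
        alpha=alpha,
        rcs_results=rcs_results,
    )
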