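"""Two-index weighted quantile sum (WQS) regression with repeated holdout.

The estimator targets the joint effect of two exposure groups — essential
and toxic metals — on a continuous outcome.  Each group's decile-coded
exposures are combined into a weighted index ``S_g = sum_i w_i q_i`` with
non-negative weights summing to one.  Estimation proceeds in two steps
repeated over random 60/40 training/validation splits:

1. *training*: each index's weights are estimated separately (its own
   index plus covariates only) by bootstrap: for every bootstrap resample
   the penalized, sign-constrained profile likelihood is minimized over
   the weight simplex; converged bootstrap weight vectors are averaged,
   by default weighted by the squared Wald statistic of the index slope.
2. *validation*: both indices (plus configured quadratic terms and the
   covariates) enter one ordinary least squares model on the held-out
   rows; its coefficients and AIC are recorded.

Point estimates are means over holdout repetitions; 95% intervals are
the 2.5/97.5 percentiles of the holdout distribution.  The sign imposed
on each index slope during training is either fixed or chosen by mean
validation AIC over a reduced pre-pass (``auto_aic``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr as scipy_qr
from scipy.stats import norm as _norm

from ._solver import ProfiledProblem, reduce_problem, softmax_weights, solve_batch
from .exposure import DecileMatrix
from .metals import ESSENTIAL_METALS, TOXIC_METALS
from .simulate import SyntheticCohort
from .study import COVARIATE_COLUMNS

__all__ = [
    "WQSConfig",
    "IndexSpec",
    "BootstrapResult",
    "HoldoutEstimate",
    "WQSFit",
    "AnalysisData",
    "compute_wqs_index",
    "train_weights",
    "aggregate_weights",
    "validate_model",
    "repeated_holdout",
    "select_direction",
    "run_wqs",
    "wqs_significance",
]

_DIRECTIONS = {"positive": 1, "negative": -1, "auto_aic": None}


@dataclass(frozen=True)
class WQSConfig:
    """Tuning parameters of the two-index WQS procedure.

    Defaults follow the reference analysis: deciles, a 60/40 split, 100
    bootstrap samples, 100 holdout repetitions, and a weight-penalty
    multiplier of 100.  ``direction_*`` is ``"positive"``, ``"negative"``
    or ``"auto_aic"``; ``quadratic`` maps outcome name to the tuple of
    index names (``"essential"``/``"toxic"``) receiving a squared term in
    the validation model.  ``signal`` picks the bootstrap aggregation
    weighting.  Solver knobs (multi-starts, Adam steps, Newton polish
    iterations, gradient tolerance) trade precision against runtime.
    """

    n_quantiles: int = 10
    split_fraction: float = 0.6
    n_boot: int = 100
    n_holdout: int = 100
    penalty: float = 100.0
    direction_essential: str = "auto_aic"
    direction_toxic: str = "auto_aic"
    quadratic: dict = field(default_factory=dict)
    signal: str = "squared_t"
    seed: int = 0
    n_starts: int = 3
    adam_steps: int = 150
    newton_iters: int = 8
    grad_tol: float = 1e-8
    min_validation_n: int = 20
    direction_n_holdout: int = 20
    direction_n_boot: int = 20
    point_estimate: str = "mean"  # or "median"
    alpha: float = 0.05
    max_holdout_failure_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly between 0 and 1")
        if self.n_boot < 1 or self.n_holdout < 1:
            raise ValueError("n_boot and n_holdout must be at least 1")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        for d in (self.direction_essential, self.direction_toxic):
            if d not in _DIRECTIONS:
                raise ValueError(f"unknown direction mode {d!r}")
        if self.signal not in ("squared_t", "uniform"):
            raise ValueError("signal must be 'squared_t' or 'uniform'")
        if self.point_estimate not in ("mean", "median"):
            raise ValueError("point_estimate must be 'mean' or 'median'")


@dataclass(frozen=True)
class IndexSpec:
    """One exposure group: member metals and the slope sign constraint."""

    name: str
    members: tuple[str, ...]
    direction: int | None = None  # +1, -1, or None (unresolved)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("index members must be non-empty")
        if self.direction not in (None, 1, -1):
            raise ValueError("direction must be +1, -1 or None")


def default_index_specs() -> dict[str, IndexSpec]:
    return {
        "essential": IndexSpec("essential", ESSENTIAL_METALS),
        "toxic": IndexSpec("toxic", TOXIC_METALS),
    }


@dataclass
class BootstrapResult:
    """Per-bootstrap trained weights and index-slope statistics."""

    weights: np.ndarray  # (n_boot, m)
    beta1: np.ndarray
    tstat: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        ok = self.converged
        if ok.any():
            w = self.weights[ok]
            if np.any(w < -1e-12) or np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-8):
                raise ValueError("bootstrap weight rows must lie on the simplex")


@dataclass
class HoldoutEstimate:
    """Joint validation regression of one holdout split."""

    params: pd.Series
    bse: pd.Series
    aic: float
    weights: dict
    split_id: int


@dataclass
class WQSFit:
    """Aggregated repeated-holdout result for one outcome."""

    terms: pd.DataFrame  # estimate, lower, upper, wald_lower, wald_upper, significant
    final_weights: dict  # index name -> pd.Series over metals
    weights_iqr: dict  # index name -> pd.Series (holdout IQR per metal)
    directions: dict  # index name -> +1/-1
    holdout_estimates: pd.DataFrame  # term x holdout matrix
    n_failed: int
    aic_mean: float
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AnalysisData:
    """Model-ready view of a cohort: decile ranks, covariates, outcomes."""

    deciles: DecileMatrix
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    index_specs: dict = field(default_factory=default_index_specs)

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort) -> "AnalysisData":
        return cls(
            deciles=cohort.deciles,
            covariates=cohort.covariates.loc[:, list(COVARIATE_COLUMNS)],
            outcomes=cohort.outcomes,
        )

    @property
    def n(self) -> int:
        return self.deciles.n_subjects


def compute_wqs_index(deciles, weights) -> np.ndarray:
    """Weighted sum of decile ranks; bounded by [0, n_quantiles - 1].

    ``deciles`` is a DataFrame (or array) restricted to one index's
    member metals, columns aligned with ``weights``.
    """
    Q = deciles.to_numpy(dtype=float) if hasattr(deciles, "to_numpy") else np.asarray(deciles, float)
    w = np.asarray(weights, dtype=float)
    if Q.shape[1] != w.size:
        raise ValueError(f"{Q.shape[1]} decile columns vs {w.size} weights")
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be non-negative and sum to 1")
    return Q @ w


def _signal_start(problems: list[ProfiledProblem]) -> np.ndarray:
    """Logits proportional to each metal's marginal association strength."""
    starts = []
    for p in problems:
        diagB = np.clip(np.diag(p.B), 1e-12, None)
        score = np.abs(p.a) / np.sqrt(diagB)
        w0 = np.clip(score, 1e-3, None)
        w0 = w0 / w0.sum()
        z = np.log(w0[:-1] / w0[-1])
        starts.append(z)
    return np.stack(starts)


def train_weights(
    Q: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    config: WQSConfig,
    direction: int,
    rng: np.random.Generator,
) -> BootstrapResult:
    """Bootstrap-train penalized simplex weights for one index.

    For each of ``config.n_boot`` resamples (with replacement, same size
    as the training set) the profiled, sign-constrained, ridge-penalized
    likelihood is minimized over the weight simplex from three starts
    (uniform, marginal-prescreen, random).  Requires at least 10 rows
    per index member.
    """
    n, m = Q.shape
    if direction not in (1, -1):
        raise ValueError("direction must be resolved to +1 or -1 before training")
    if n < 10 * m:
        warnings.warn(
            f"training set has {n} rows for {m} metals (< 10 per member)",
            stacklevel=2,
        )
    A = np.column_stack([np.ones(n), covariates])
    idx = rng.integers(0, n, size=(config.n_boot, n))
    problems = [reduce_problem(Q[i], y[i], A[i]) for i in idx]
    d = m - 1
    starts = np.stack(
        [
            np.zeros((config.n_boot, d)),
            _signal_start(problems),
            rng.normal(scale=1.0, size=(config.n_boot, d)),
        ]
    )[: config.n_starts]
    W, beta1, tstat, conv = solve_batch(
        problems,
        lam=config.penalty,
        direction=direction,
        starts=starts,
        adam_steps=config.adam_steps,
        newton_iters=config.newton_iters,
        grad_tol=config.grad_tol,
    )
    if conv.sum() < max(1, 0.1 * config.n_boot):
        raise RuntimeError(
            f"weight training failed: only {int(conv.sum())}/{config.n_boot} "
            "bootstraps converged (check penalty, data scale, and solver settings)"
        )
    return BootstrapResult(weights=W, beta1=beta1, tstat=tstat, converged=conv)


def fit_weights_once(
    Q: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    penalty: float,
    direction: int,
    n_starts: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, float]:
    """Single penalized fit on the given rows (no resampling).

    Exposes the training optimizer directly; used for diagnostics and
    for oracle comparisons against grid search.
    Returns (weights, beta1, tstat).
    """
    n, m = Q.shape
    A = np.column_stack([np.ones(n), covariates]) if covariates is not None else np.ones((n, 1))
    prob = reduce_problem(Q, y, A)
    d = m - 1
    starts = [np.zeros((1, d)), _signal_start([prob])]
    if rng is not None:
        starts.append(rng.normal(size=(1, d)))
    starts = np.stack(starts[:n_starts]) if n_starts <= len(starts) else np.stack(starts)
    W, beta1, tstat, _ = solve_batch(
        [prob], lam=penalty, direction=direction, starts=starts,
        adam_steps=300, newton_iters=15,
    )
    return W[0], float(beta1[0]), float(tstat[0])


def aggregate_weights(boot: BootstrapResult, signal: str = "squared_t") -> np.ndarray:
    """Average converged bootstrap weight rows into one simplex vector.

    Default weighting is by the squared index-slope Wald statistic; if
    the total signal is zero (e.g. all bootstraps hit the sign
    constraint) aggregation falls back to a uniform average.
    """
    ok = boot.converged
    if not ok.any():
        raise ValueError("no converged bootstrap rows to aggregate")
    W = boot.weights[ok]
    if signal == "uniform":
        mix = np.ones(len(W))
    elif signal == "squared_t":
        mix = boot.tstat[ok] ** 2
        if mix.sum() <= 0:
            logging.getLogger(__name__).warning(
                "zero aggregation signal; falling back to uniform averaging"
            )
            mix = np.ones(len(W))
    else:
        raise ValueError(f"unknown signal {signal!r}")
    w = (W * (mix / mix.sum())[:, None]).sum(axis=0)
    return w / w.sum()


def _name_rank_deficiency(X: pd.DataFrame) -> str:
    _, R, piv = scipy_qr(X.to_numpy(), pivoting=True)
    diag = np.abs(np.diag(R))
    bad = piv[np.where(diag < diag.max() * 1e-10)[0]]
    return ", ".join(X.columns[bad]) if len(bad) else "<unknown>"


def validate_model(
    deciles_val: pd.DataFrame,
    y_val: np.ndarray,
    covariates_val: pd.DataFrame,
    weights: dict,
    quadratic: tuple[str, ...] = (),
    index_specs: dict | None = None,
    min_validation_n: int = 20,
    split_id: int = 0,
) -> HoldoutEstimate:
    """Joint validation regression on held-out rows.

    Ordinary least squares of the outcome on both indices (computed with
    the trained weights), optional squared index terms, and the
    covariates; Gaussian-likelihood AIC is recorded for direction
    selection.
    """
    index_specs = index_specs or default_index_specs()
    n = len(y_val)
    if n < min_validation_n:
        raise ValueError(f"validation set has {n} < {min_validation_n} rows")
    cols = {"beta0": np.ones(n)}
    for name, spec in index_specs.items():
        S = compute_wqs_index(deciles_val.loc[:, list(spec.members)], weights[name])
        cols[f"wqs_{name}"] = S
        if name in quadratic:
            cols[f"wqs_{name}_sq"] = S**2
    for c in covariates_val.columns:
        cols[c] = covariates_val[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"validation design is rank deficient (column(s): {_name_rank_deficiency(X)})"
        )
    fit = sm.OLS(np.asarray(y_val, dtype=float), X).fit()
    return HoldoutEstimate(
        params=fit.params,
        bse=fit.bse,
        aic=float(fit.aic),
        weights=weights,
        split_id=split_id,
    )


def _resolve_directions(config: WQSConfig) -> dict:
    return {
        "essential": _DIRECTIONS[config.direction_essential],
        "toxic": _DIRECTIONS[config.direction_toxic],
    }


def repeated_holdout(
    data: AnalysisData,
    outcome: str,
    config: WQSConfig,
    directions: dict | None = None,
) -> WQSFit:
    """The full repeated-holdout WQS estimate for one outcome.

    For each of ``config.n_holdout`` random 60/40 splits: train each
    index's weights by penalized bootstrap on the training rows,
    aggregate, validate jointly on the held-out rows; then summarize the
    holdout distribution (mean point estimates, 2.5/97.5-percentile
    intervals, mean weights).  Decile codes are those of the full
    analytic sample (coding precedes modelling; splits do not re-code).

    ``directions`` maps index name to +1/-1 and overrides the config;
    every direction must be resolved (use :func:`select_direction` or
    :func:`run_wqs` for ``auto_aic``).
    """
    directions = dict(directions or _resolve_directions(config))
    if any(d is None for d in directions.values()):
        raise ValueError(
            "auto_aic directions must be resolved before repeated_holdout; "
            "use select_direction or run_wqs"
        )
    y = data.outcomes[outcome].to_numpy(dtype=float)
    covars = data.covariates
    C = covars.to_numpy(dtype=float)
    n = data.n
    n_train = int(round(config.split_fraction * n))
    quadratic = tuple(config.quadratic.get(outcome, ()))

    streams = np.random.SeedSequence(config.seed).spawn(config.n_holdout)
    estimates: list[HoldoutEstimate] = []
    weight_rows: dict[str, list[np.ndarray]] = {k: [] for k in data.index_specs}
    n_failed = 0
    failures: list[str] = []
    for h, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        try:
            agg = {}
            for name, spec in data.index_specs.items():
                Q = data.deciles.restrict(spec.members).to_numpy(dtype=float)
                boot = train_weights(
                    Q[tr], y[tr], C[tr], config, directions[name], rng
                )
                agg[name] = aggregate_weights(boot, config.signal)
            est = validate_model(
                data.deciles.ranks.iloc[va],
                y[va],
                covars.iloc[va],
                agg,
                quadratic=quadratic,
                index_specs=data.index_specs,
                min_validation_n=config.min_validation_n,
                split_id=h,
            )
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            failures.append(f"holdout {h}: {exc}")
            continue
        estimates.append(est)
        for name in data.index_specs:
            weight_rows[name].append(agg[name])
    if n_failed > config.max_holdout_failure_rate * config.n_holdout:
        raise RuntimeError(
            f"{n_failed}/{config.n_holdout} holdouts failed; first failures: "
            + "; ".join(failures[:3])
        )

    est_mat = pd.concat([e.params for e in estimates], axis=1)
    est_mat.columns = [e.split_id for e in estimates]
    se_mat = pd.concat([e.bse for e in estimates], axis=1)
    point = est_mat.mean(axis=1) if config.point_estimate == "mean" else est_mat.median(axis=1)
    lo_q, hi_q = 100 * config.alpha / 2, 100 * (1 - config.alpha / 2)
    lower = est_mat.quantile(lo_q / 100, axis=1)
    upper = est_mat.quantile(hi_q / 100, axis=1)
    zcrit = float(_norm.ppf(1 - config.alpha / 2))
    wald_lower = point - zcrit * se_mat.mean(axis=1)
    wald_upper = point + zcrit * se_mat.mean(axis=1)
    terms = pd.DataFrame(
        {
            "estimate": point,
            "lower": lower,
            "upper": upper,
            "wald_lower": wald_lower,
            "wald_upper": wald_upper,
        }
    )
    terms["significant"] = (terms["lower"] > 0) | (terms["upper"] < 0)

    final_weights, weights_iqr = {}, {}
    for name, spec in data.index_specs.items():
        Wmat = np.stack(weight_rows[name])
        mean_w = Wmat.mean(axis=0)
        final_weights[name] = pd.Series(mean_w / mean_w.sum(), index=list(spec.members))
        q75, q25 = np.percentile(Wmat, [75, 25], axis=0)
        weights_iqr[name] = pd.Series(q75 - q25, index=list(spec.members))

    return WQSFit(
        terms=terms,
        final_weights=final_weights,
        weights_iqr=weights_iqr,
        directions=directions,
        holdout_estimates=est_mat,
        n_failed=n_failed,
        aic_mean=float(np.mean([e.aic for e in estimates])),
        provenance={
            "outcome": outcome,
            "seed": config.seed,
            "n_holdout": config.n_holdout,
            "n_boot": config.n_boot,
            "penalty": config.penalty,
            "quadratic": list(quadratic),
            "failures": failures,
        },
    )


def select_direction(
    data: AnalysisData,
    outcome: str,
    config: WQSConfig,
) -> tuple[dict, pd.DataFrame]:
    """Choose each auto index's slope sign by mean validation AIC.

    Runs the repeated-holdout procedure at reduced repetition counts
    (``direction_n_holdout`` x ``direction_n_boot``) for every
    combination of candidate signs of the ``auto_aic`` indices and keeps
    the combination with the lowest mean AIC.  Ties within 1e-6 prefer
    the negative direction (adverse-effect reading), and are recorded.
    """
    base = _resolve_directions(config)
    auto = [k for k, v in base.items() if v is None]
    if not auto:
        return base, pd.DataFrame()
    reduced = replace(
        config,
        n_holdout=config.direction_n_holdout,
        n_boot=config.direction_n_boot,
    )
    combos = [()]
    for _ in auto:
        combos = [c + (s,) for c in combos for s in (-1, 1)]
    rows = []
    for combo in combos:
        cand = dict(base)
        cand.update(dict(zip(auto, combo)))
        fit = repeated_holdout(data, outcome, reduced, directions=cand)
        rows.append({**{f"dir_{k}": v for k, v in cand.items()}, "mean_aic": fit.aic_mean})
    table = pd.DataFrame(rows).sort_values("mean_aic", kind="stable").reset_index(drop=True)
    best_aic = table["mean_aic"].iloc[0]
    ties = table[table["mean_aic"] <= best_aic + 1e-6]
    if len(ties) > 1:
        # deterministic preference: most negative combination among ties
        ties = ties.assign(_neg=ties[[f"dir_{k}" for k in auto]].sum(axis=1))
        best = ties.sort_values(["_neg", "mean_aic"], kind="stable").iloc[0]
        warnings.warn(f"AIC tie in direction selection for {outcome}; choosing negative")
    else:
        best = table.iloc[0]
    chosen = {k: int(best[f"dir_{k}"]) for k in base}
    return chosen, table


def run_wqs(data: AnalysisData, outcome: str, config: WQSConfig) -> WQSFit:
    """Resolve directions (AIC pre-pass if requested) then estimate."""
    directions, aic_table = select_direction(data, outcome, config)
    fit = repeated_holdout(data, outcome, config, directions=directions)
    if len(aic_table):
        fit.provenance["direction_aic_table"] = aic_table.to_dict(orient="records")
    return fit


def wqs_significance(fit: WQSFit, alpha: float = 0.05) -> pd.Series:
    """Per-term significance: the percentile interval excludes zero.

    A degenerate interval touching zero counts as not significant.  For
    ``alpha`` other than the fit's own level the flags are recomputed
    from the stored holdout distribution.
    """
    est = fit.holdout_estimates
    lo = est.quantile(alpha / 2, axis=1)
    hi = est.quantile(1 - alpha / 2, axis=1)
    return (lo > 0) | (hi < 0)
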