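"""Synthetic pregnancy-cohort generator.

Emulates the statistical structure the mixture analysis assumes, so every
downstream stage is testable without the (request-only) cohort data:

* correlated log-normal urinary exposures via a Gaussian copula on the
  log scale, calibrated per metal to the reference geometric means and
  interquartile ranges;
* limit-of-detection censoring applied on the unadjusted (µg/L) scale
  through a simulated creatinine round trip;
* maternal/child covariates drawn from the reference marginals;
* neurodevelopmental outcomes generated from a known two-index weighted
  quantile sum process (linear + quadratic index terms), whose generating
  parameters are retained as ground truth for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .exposure import DecileMatrix, decile_matrix
from .metals import (
    CANONICAL_METALS,
    ESSENTIAL_METALS,
    TOXIC_METALS,
    MetalSpec,
    default_metal_specs,
)
from .study import (
    COVARIATE_COLUMNS,
    DEFAULT_COVARIATE_MARGINALS,
    NEPSY_OUTCOMES,
    WPPSI_OUTCOMES,
    CovariateMarginals,
    analytic_sample_size,
)

__all__ = [
    "EffectTruth",
    "SyntheticCohort",
    "LOD_RULES",
    "default_rank_corr",
    "sample_exposures",
    "censor_at_lod",
    "sample_covariates",
    "generate_outcomes",
    "generate_cohort",
    "write_cohort",
    "write_truth",
    "read_truth",
]

LOD_RULES = ("zero", "lod_over_sqrt2", "lod_over_2")

# Outcome scale conventions: (population mean, population SD).
_SCALES = {"wppsi": (100.0, 15.0), "nepsy": (10.0, 3.0)}


@dataclass(frozen=True)
class EffectTruth:
    """Generating parameters of a synthetic cohort's outcome process.

    The outcome model is
    ``y = intercept + b1_ess*S_ess + b2_ess*S_ess^2 + b1_tox*S_tox
    + b2_tox*S_tox^2 + covariates @ phi + N(0, resid_sd^2)``
    where ``S_g`` is the weighted sum of the group's decile ranks.

    ``intercept`` / ``resid_sd`` of ``None`` mean "use the outcome
    scale's convention" (100/15 for WPPSI-type scores, 10/3 for
    NEPSY-type scores).  ``resid_sd = 0`` gives a noiseless cohort and is
    allowed for identifiability checks.
    """

    weights_essential: tuple[float, ...] = tuple([1.0 / 8] * 8)
    weights_toxic: tuple[float, ...] = tuple([1.0 / 6] * 6)
    beta1_ess: float = 0.0
    beta2_ess: float = 0.0
    beta1_tox: float = 0.0
    beta2_tox: float = 0.0
    covariate_coefs: tuple[float, ...] = tuple([0.0] * len(COVARIATE_COLUMNS))
    intercept: float | None = None
    resid_sd: float | None = None

    def __post_init__(self) -> None:
        for w, m in ((self.weights_essential, 8), (self.weights_toxic, 6)):
            w = np.asarray(w, dtype=float)
            if w.size != m:
                raise ValueError(f"expected {m} weights, got {w.size}")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("index weights must be non-negative and sum to 1")
        if len(self.covariate_coefs) != len(COVARIATE_COLUMNS):
            raise ValueError(
                f"covariate_coefs must have {len(COVARIATE_COLUMNS)} entries"
            )
        if self.resid_sd is not None and self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")

    def rescaled(self, factor: float) -> "EffectTruth":
        """Effect sizes multiplied by ``factor`` (used to map WPPSI-scale
        truth onto the NEPSY score scale)."""
        return EffectTruth(
            weights_essential=self.weights_essential,
            weights_toxic=self.weights_toxic,
            beta1_ess=self.beta1_ess * factor,
            beta2_ess=self.beta2_ess * factor,
            beta1_tox=self.beta1_tox * factor,
            beta2_tox=self.beta2_tox * factor,
            covariate_coefs=tuple(c * factor for c in self.covariate_coefs),
            intercept=None,
            resid_sd=None if self.resid_sd is None else self.resid_sd * factor,
        )


@dataclass(frozen=True)
class SyntheticCohort:
    """A fully generated cohort with its ground truth attached."""

    exposures: pd.DataFrame  # subjects x 14 metals, µg/g creatinine, post-LOD
    creatinine: pd.Series  # g/L
    covariates: pd.DataFrame  # subjects x 7
    outcomes: pd.DataFrame  # subjects x 11 scores
    deciles: DecileMatrix
    truth: EffectTruth
    seed: int

    def __post_init__(self) -> None:
        n = len(self.exposures)
        for part in (self.creatinine, self.covariates, self.outcomes, self.deciles.ranks):
            if len(part) != n:
                raise ValueError("cohort components must share one row count")
        vals = self.exposures.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("exposures must be finite and non-negative")
        if not np.all(np.isfinite(self.outcomes.to_numpy())):
            raise ValueError("outcomes must be finite")

    @property
    def n(self) -> int:
        return len(self.exposures)


def default_rank_corr(specs: list[MetalSpec] | None = None) -> np.ndarray:
    """Default cross-metal Spearman target: weak exchangeable structure.

    0.15 within the essential and toxic groups, 0.05 between groups —
    the reference cohort showed no strong cross-metal correlations, with
    only some pairs above 0.2 in absolute value.
    """
    specs = specs if specs is not None else default_metal_specs()
    groups = np.array([s.group for s in specs])
    same = groups[:, None] == groups[None, :]
    R = np.where(same, 0.15, 0.05)
    np.fill_diagonal(R, 1.0)
    return R


def _copula_correlation(rank_corr: np.ndarray) -> np.ndarray:
    """Latent normal correlation reproducing a Spearman target.

    For a Gaussian copula, Spearman's rho_s and the latent Pearson r obey
    r = 2*sin(pi*rho_s/6); the inverse map is applied entrywise.
    """
    R = 2.0 * np.sin(np.pi * rank_corr / 6.0)
    np.fill_diagonal(R, 1.0)
    return R


def _check_psd(R: np.ndarray, name: str) -> None:
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{name} must be a symmetric square matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have a unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite: smallest eigenvalue "
            f"{w.min():.6g}"
        )


def sample_exposures(
    specs: list[MetalSpec],
    rank_corr: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw raw (pre-censoring) exposures, µg/g creatinine.

    Gaussian copula on the log scale: latent correlated normals are
    mapped through each metal's log-normal marginal (median = GM target,
    log-SD solved from the IQR target), so empirical Spearman
    correlations converge to ``rank_corr``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rank_corr = np.asarray(rank_corr, dtype=float)
    _check_psd(rank_corr, "rank_corr")
    R = _copula_correlation(rank_corr)
    # The sine transform can nudge eigenvalues slightly; re-symmetrize and
    # clip tiny negatives before factorization.
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((n, len(specs))) @ L.T
    mu = np.log([s.gm_target for s in specs])
    sigma = np.array([s.log_sigma for s in specs])
    X = np.exp(mu + sigma * Z)
    return pd.DataFrame(X, columns=[s.name for s in specs])


def censor_at_lod(
    raw: pd.DataFrame,
    specs: list[MetalSpec],
    creatinine_g_per_l,
    rule: str = "lod_over_sqrt2",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Apply the limit-of-detection substitution rule.

    Each creatinine-adjusted value (µg/g) is converted back to µg/L by
    multiplying with the subject's creatinine (g/L), compared with the
    metal's LOD, and — if below — replaced by the rule's substitute
    (0, LOD/sqrt(2), or LOD/2, on the µg/L scale) then re-adjusted for
    creatinine.  Values at or above the LOD pass through unchanged.

    ``rng`` is accepted for interface symmetry with stochastic imputation
    rules; the three built-in rules are deterministic.
    """
    if rule not in LOD_RULES:
        raise ValueError(f"unknown LOD rule {rule!r}; choose one of {LOD_RULES}")
    crea = np.asarray(creatinine_g_per_l, dtype=float).reshape(-1)
    if np.any(crea <= 0):
        raise ValueError("creatinine must be strictly positive")
    if len(crea) != len(raw):
        raise ValueError("creatinine must align with the exposure rows")
    sub_factor = {"zero": 0.0, "lod_over_sqrt2": 1.0 / np.sqrt(2.0), "lod_over_2": 0.5}[rule]
    out = raw.copy()
    for spec in specs:
        col = out[spec.name].to_numpy(dtype=float)
        ug_per_l = col * crea
        below = ug_per_l < spec.lod
        col = np.where(below, (spec.lod * sub_factor) / crea, col)
        out[spec.name] = col
    return out


def sample_covariates(
    n: int,
    rng: np.random.Generator,
    marginals: CovariateMarginals = DEFAULT_COVARIATE_MARGINALS,
) -> pd.DataFrame:
    """Draw the seven model covariates from their reference marginals."""
    m = marginals
    a, b = (np.array(m.age_bounds) - m.age_mean) / m.age_sd
    age = truncnorm.rvs(a, b, loc=m.age_mean, scale=m.age_sd, size=n, random_state=rng)
    bmi = truncnorm.rvs(
        (0.0 - m.bmi_mean) / m.bmi_sd, np.inf, loc=m.bmi_mean, scale=m.bmi_sd,
        size=n, random_state=rng,
    )
    return pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "social_class": (rng.random(n) < m.p_social_class_high).astype(int),
            "smoking": (rng.random(n) < m.p_smoking_ever).astype(int),
            "meddiet": rng.normal(m.meddiet_mean, m.meddiet_sd, size=n),
            "child_sex": (rng.random(n) < m.p_child_female).astype(int),
            "feeding": (rng.random(n) < m.p_feeding_nonexclusive).astype(int),
        }
    )


def _index_values(deciles: DecileMatrix, metals: tuple[str, ...], weights) -> np.ndarray:
    Q = deciles.restrict(metals).to_numpy(dtype=float)
    return Q @ np.asarray(weights, dtype=float)


def generate_outcomes(
    deciles: DecileMatrix,
    covariates: pd.DataFrame,
    truth: EffectTruth,
    scale: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one outcome column from the two-index process.

    With all coefficients zero the marginal distribution follows the
    scale convention (mean 100 / SD 15 for ``"wppsi"``, 10 / 3 for
    ``"nepsy"``) unless the truth overrides intercept or residual SD.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown outcome scale {scale!r}")
    conv_mean, conv_sd = _SCALES[scale]
    intercept = conv_mean if truth.intercept is None else truth.intercept
    resid_sd = conv_sd if truth.resid_sd is None else truth.resid_sd
    s_ess = _index_values(deciles, ESSENTIAL_METALS, truth.weights_essential)
    s_tox = _index_values(deciles, TOXIC_METALS, truth.weights_toxic)
    C = covariates.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    y = (
        intercept
        + truth.beta1_ess * s_ess
        + truth.beta2_ess * s_ess**2
        + truth.beta1_tox * s_tox
        + truth.beta2_tox * s_tox**2
        + C @ np.asarray(truth.covariate_coefs, dtype=float)
    )
    if resid_sd > 0:
        y = y + rng.normal(0.0, resid_sd, size=len(y))
    return y


def generate_cohort(
    n: int | None = None,
    truth: EffectTruth | None = None,
    specs: list[MetalSpec] | None = None,
    rank_corr: np.ndarray | None = None,
    lod_rule: str = "lod_over_sqrt2",
    seed: int = 0,
    marginals: CovariateMarginals = DEFAULT_COVARIATE_MARGINALS,
    creatinine_log_sd: float = 0.4,
) -> SyntheticCohort:
    """Generate a complete cohort; deterministic under a fixed seed.

    Defaults: n equals the reference analytic sample (201), null truth
    (uniform weights, zero effects), calibrated metal specs, weak
    exchangeable rank correlations, LOD/sqrt(2) substitution, and a
    log-normal creatinine with median 1 g/L and log-SD 0.4 (a typical
    spot-urine dilution spread).
    """
    n = analytic_sample_size() if n is None else int(n)
    if n < 30:
        raise ValueError("n must be at least 30 (training/validation split infeasible)")
    truth = truth if truth is not None else EffectTruth()
    specs = specs if specs is not None else default_metal_specs()
    if [s.name for s in specs] != list(CANONICAL_METALS):
        raise ValueError("specs must cover the canonical 14-metal panel in order")
    rank_corr = default_rank_corr(specs) if rank_corr is None else rank_corr

    streams = np.random.SeedSequence(seed).spawn(4)
    rng_exp, rng_crea, rng_cov, rng_out = (np.random.default_rng(s) for s in streams)

    raw = sample_exposures(specs, rank_corr, n, rng_exp)
    creatinine = pd.Series(
        np.exp(rng_crea.normal(0.0, creatinine_log_sd, size=n)), name="creatinine"
    )
    exposures = censor_at_lod(raw, specs, creatinine, rule=lod_rule)
    covariates = sample_covariates(n, rng_cov, marginals)
    deciles = decile_matrix(exposures)

    outcomes = {}
    for col in WPPSI_OUTCOMES:
        outcomes[col] = generate_outcomes(deciles, covariates, truth, "wppsi", rng_out)
    nepsy_truth = truth.rescaled(3.0 / 15.0)
    for col in NEPSY_OUTCOMES:
        outcomes[col] = generate_outcomes(deciles, covariates, nepsy_truth, "nepsy", rng_out)

    return SyntheticCohort(
        exposures=exposures,
        creatinine=creatinine,
        covariates=covariates,
        outcomes=pd.DataFrame(outcomes),
        deciles=deciles,
        truth=truth,
        seed=seed,
    )


def cohort_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Flatten a cohort into the delimited-text table contract."""
    df = pd.concat(
        [cohort.exposures, cohort.covariates, cohort.outcomes], axis=1
    )
    df.insert(0, "subject_id", np.arange(1, cohort.n + 1))
    return df


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write the cohort as a comma-separated table with a header row."""
    cohort_frame(cohort).to_csv(path, index=False)


def write_truth(truth: EffectTruth, path: str | Path) -> None:
    """Write the generating truth as a structured key-value sidecar."""
    Path(path).write_text(json.dumps(asdict(truth), indent=2) + "\n")


def read_truth(path: str | Path) -> EffectTruth:
    raw = json.loads(Path(path).read_text())
    for key in ("weights_essential", "weights_toxic", "covariate_coefs"):
        raw[key] = tuple(raw[key])
    return EffectTruth(**raw)
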